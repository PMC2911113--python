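"""Parsing, gene-model validation and intron extraction."""

from __future__ import annotations

import io

import numpy as np
import pytest

from intron_constraint import genome_io as gio


# ---------------------------------------------------------------------------
# FASTA

def _reference_fasta_parser(text: str) -> dict[str, str]:
    """Independent line-by-line FASTA oracle."""
    records: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = ""
        elif name is not None:
            records[name] += line.strip().upper().replace("U", "T")
    return records


@pytest.mark.parametrize(
    "text",
    [
        ">c1\nACGT",
        ">c1\nac\ngt\n>c2\nTTTT",
        ">c1\nACGUacgu\n>c2\nGG\nGG\nGG",
    ],
)
def test_read_fasta_matches_reference_parser(text):
    assert gio.read_fasta(io.StringIO(text)) == _reference_fasta_parser(text)


def test_read_fasta_duplicate_id_is_hard_error():
    with pytest.raises(gio.AnnotationError, match="duplicate"):
        gio.read_fasta(io.StringIO(">c1\nACGT\n>c1\nAAAA"))


def test_read_fasta_empty_record_is_hard_error():
    with pytest.raises(gio.AnnotationError, match="empty"):
        gio.read_fasta(io.StringIO(">c1\n>c2\nAAAA"))


def test_read_fasta_flags_non_acgt_but_preserves_it():
    with pytest.warns(gio.AnnotationWarning, match="non-ACGT"):
        seqs = gio.read_fasta(io.StringIO(">c1\nACGTN"))
    assert seqs["c1"] == "ACGTN"


# ---------------------------------------------------------------------------
# GFF3 gene models

_GFF_HEADER = "##gff-version 3\n"


def _gff(body: str) -> str:
    return _GFF_HEADER + "\n".join(
        "\t".join(fields) for fields in (line.split() for line in body.strip().splitlines())
    )


def test_one_nt_first_coding_exon_parses():
    text = _gff(
        """
        chr1 t gene 101 300 . + . ID=gA
        chr1 t mRNA 101 300 . + . ID=gA.t1;Parent=gA
        chr1 t exon 101 101 . + . ID=e1;Parent=gA.t1
        chr1 t exon 200 300 . + . ID=e2;Parent=gA.t1
        chr1 t CDS 101 101 . + 0 ID=c1;Parent=gA.t1
        chr1 t CDS 200 300 . + 2 ID=c2;Parent=gA.t1
        """
    )
    ann = gio.read_gene_models(text, {"chr1": "A" * 400})
    (gene,) = ann.genes
    assert gene.coding_exons == ((101, 101), (200, 300))
    assert gene.coding_length == 102


def test_four_nt_internal_exon_parses_without_warning(recwarn):
    text = _gff(
        """
        chr1 t gene 1 200 . + . ID=gB
        chr1 t mRNA 1 200 . + . ID=gB.t1;Parent=gB
        chr1 t CDS 1 60 . + 0 ID=c;Parent=gB.t1
        chr1 t CDS 101 104 . + 0 ID=c;Parent=gB.t1
        chr1 t CDS 150 199 . + 2 ID=c;Parent=gB.t1
        """
    )
    ann = gio.read_gene_models(text, {"chr1": "A" * 300})
    assert ann.genes[0].coding_length == 60 + 4 + 50  # a multiple of 3
    assert not any(isinstance(w.message, gio.AnnotationWarning) for w in recwarn.list)


def test_cds_length_not_multiple_of_three_warns_and_flags():
    text = _gff(
        """
        chr1 t gene 1 100 . + . ID=gC
        chr1 t mRNA 1 100 . + . ID=gC.t1;Parent=gC
        chr1 t CDS 1 100 . + 0 ID=c;Parent=gC.t1
        """
    )
    with pytest.warns(gio.AnnotationWarning, match="not a multiple of 3"):
        ann = gio.read_gene_models(text, {"chr1": "A" * 300})
    assert gio.FLAG_BAD_CDS_LENGTH in ann.genes[0].flags  # flagged, not dropped


def test_unresolved_parent_is_hard_error():
    text = _gff(
        """
        chr1 t mRNA 1 99 . + . ID=gD.t1;Parent=missing
        chr1 t CDS 1 99 . + 0 ID=c;Parent=gD.t1
        """
    )
    with pytest.raises(gio.AnnotationError, match="unresolved Parent"):
        gio.read_gene_models(text, {"chr1": "A" * 300})


def test_utr5_exon_gap_becomes_utr_intron():
    text = _gff(
        """
        chr1 t gene 1 300 . + . ID=gE
        chr1 t mRNA 1 300 . + . ID=gE.t1;Parent=gE
        chr1 t exon 1 40 . + . ID=e1;Parent=gE.t1
        chr1 t exon 121 300 . + . ID=e2;Parent=gE.t1
        chr1 t five_prime_UTR 1 40 . + . ID=u1;Parent=gE.t1
        chr1 t five_prime_UTR 121 150 . + . ID=u2;Parent=gE.t1
        chr1 t CDS 151 300 . + 0 ID=c;Parent=gE.t1
        """
    )
    ann = gio.read_gene_models(text, {"chr1": "A" * 400})
    assert ann.genes[0].utr5_introns == ((41, 120),)
    introns = gio.extract_introns(ann)
    (utr_intron,) = introns
    assert utr_intron.compartment == gio.UTR5
    assert utr_intron.phase is None


# ---------------------------------------------------------------------------
# Intron extraction

def test_extract_simple_plus_strand_intron():
    chrom = "".join("ACGT"[i % 4] for i in range(202))
    gene = gio.GeneModel(
        id="g1", chromosome="chr1", strand="+", coding_exons=((1, 4), (105, 202))
    )
    ann = gio.GenomeAnnotation(sequences={"chr1": chrom}, genes=[gene])
    (intron,) = gio.extract_introns(ann)
    assert (intron.start, intron.end) == (5, 104)
    assert intron.length_nt == 100
    assert intron.phase == 1  # 4 coding nt upstream
    assert intron.sequence == chrom[4:104]


def test_minus_strand_mirror_has_same_phase_and_sequence():
    """A coordinate-mirrored minus-strand gene yields the identical intron."""
    rng = np.random.default_rng(5)
    chrom_plus = "".join("ACGT"[i] for i in rng.integers(0, 4, 202))
    gene_plus = gio.GeneModel(
        id="gp", chromosome="chr1", strand="+", coding_exons=((1, 4), (105, 202))
    )
    plus = gio.extract_introns(
        gio.GenomeAnnotation({"chr1": chrom_plus}, [gene_plus])
    )[0]

    chrom_minus = gio.reverse_complement(chrom_plus)
    # mirrored interval of (s, e) in a 202-nt chromosome is (203-e, 203-s)
    gene_minus = gio.GeneModel(
        id="gm", chromosome="chr1", strand="-", coding_exons=((1, 98), (199, 202))
    )
    minus = gio.extract_introns(
        gio.GenomeAnnotation({"chr1": chrom_minus}, [gene_minus])
    )[0]

    assert minus.length_nt == plus.length_nt
    assert minus.phase == plus.phase == 1
    assert minus.sequence == plus.sequence


def test_zero_length_gap_is_hard_error():
    gene = gio.GeneModel(
        id="g1", chromosome="chr1", strand="+", coding_exons=((1, 3), (4, 9))
    )
    ann = gio.GenomeAnnotation(sequences={"chr1": "A" * 20}, genes=[gene])
    with pytest.raises(gio.AnnotationError, match="zero-length gap"):
        gio.extract_introns(ann)


def test_gene_model_invariants():
    with pytest.raises(gio.AnnotationError, match="start > end"):
        gio.GeneModel(id="g", chromosome="c", strand="+", coding_exons=((5, 2),))
    with pytest.raises(gio.AnnotationError, match="overlap"):
        gio.GeneModel(id="g", chromosome="c", strand="+", coding_exons=((1, 10), (5, 20)))
    with pytest.raises(gio.AnnotationError, match="multiple of 3"):
        gio.GeneModel(id="g", chromosome="c", strand="+", coding_exons=((1, 10),))
    with pytest.raises(gio.AnnotationError, match="phase"):
        gio.Intron(
            gene_id="g", ordinal=1, start=1, end=4, sequence="ACGT",
            phase=None, compartment=gio.CDS,
        )


def test_filter_introns_min_length_and_compartment(mk):
    introns = [
        mk("A" * 29),
        mk("A" * 30),
        mk("A" * 100, phase=None, compartment=gio.UTR5),
    ]
    kept = gio.filter_introns(introns)
    assert [i.length_nt for i in kept] == [30]
    both = gio.filter_introns(introns, compartments=(gio.CDS, gio.UTR5))
    assert len(both) == 2


# ---------------------------------------------------------------------------
# Properties on synthetic genomes

def test_round_trip_recovers_generator_truth_exactly(stranded_genome):
    """Introns extracted from emitted FASTA+GFF3 equal the truth table."""
    genome = stranded_genome
    sequences = gio.read_fasta(io.StringIO(genome.fasta_text))
    annotation = gio.read_gene_models(genome.gff_text, sequences)
    assert len(annotation.genes) == len(genome.annotation.genes)

    frame = gio.introns_to_frame(gio.extract_introns(annotation))
    truth = genome.truth
    assert len(frame) == len(truth)
    merged = truth.merge(
        frame, on=["gene_id", "compartment", "ordinal"], suffixes=("_truth", "")
    )
    assert len(merged) == len(truth)
    for column in ("start", "end", "length", "sequence"):
        assert (merged[f"{column}_truth"] == merged[column]).all()
    assert merged["phase_truth"].astype("Int64").equals(merged["phase"])


def test_coding_length_conservation(stranded_genome, stranded_introns):
    """Exon lengths plus CDS intron lengths tile the genomic CDS span."""
    by_gene: dict[str, int] = {}
    for intron in stranded_introns:
        if intron.compartment == gio.CDS:
            by_gene[intron.gene_id] = by_gene.get(intron.gene_id, 0) + intron.length_nt
    for gene in stranded_genome.annotation.genes:
        span = gene.coding_exons[-1][1] - gene.coding_exons[0][0] + 1
        assert gene.coding_length + by_gene.get(gene.id, 0) == span
        n_introns = sum(
            1
            for i in stranded_introns
            if i.gene_id == gene.id and i.compartment == gio.CDS
        )
        assert n_introns == gene.n_cds_introns


def test_phase_chain_invariant():
    """phase_k == (phase_{k-1} + intervening exon length) mod 3."""
    from intron_constraint import synthetic_data as sd

    # intron-dense configuration so multi-intron genes are plentiful
    genome = sd.generate(
        sd.SimulationConfig(
            seed=23,
            n_genes=60,
            intron_fraction_of_genes=1.0,
            introns_per_gene_probs=(0.2, 0.5, 0.2, 0.05, 0.05),
            minus_strand_fraction=0.5,
        )
    )
    introns = gio.extract_introns(genome.annotation)
    genes = {g.id: g for g in genome.annotation.genes}
    per_gene: dict[str, list] = {}
    for intron in introns:
        if intron.compartment == gio.CDS:
            per_gene.setdefault(intron.gene_id, []).append(intron)
    checked = 0
    for gene_id, introns in per_gene.items():
        if len(introns) < 2:
            continue
        gene = genes[gene_id]
        exon_lengths = [e - s + 1 for s, e in gene.coding_exons]
        if gene.strand == "-":
            exon_lengths = exon_lengths[::-1]
        introns.sort(key=lambda i: i.ordinal)
        for prev, nxt in zip(introns, introns[1:]):
            assert nxt.phase == (prev.phase + exon_lengths[nxt.ordinal - 1]) % 3
            checked += 1
    assert checked > 0  # the fixture must actually exercise multi-intron genes
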
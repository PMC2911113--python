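"""FASTA/GFF3 input, validated gene models, and intron extraction.

All coordinates are 1-based and inclusive, following GFF3; the span of an
interval ``(start, end)`` is ``end - start + 1``.  Genomic intervals are always
stored in ascending order regardless of strand; transcript-level quantities
(intron ordinal, phase, sequence) are computed in transcript orientation, so a
minus-strand intron's ``sequence`` is the reverse complement of the genomic
slice.

Intron phase follows the usual convention: a phase 0 intron falls between two
codons; phase 1 and 2 introns split a codon after its first or second
nucleotide.  Introns located in the 5' UTR carry no phase.  Intron ordinals are
numbered per compartment: CDS introns 1..k in transcript order, 5' UTR introns
1..m separately, so that "first intron" statistics always refer to the first
intron of the coding sequence.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

CDS = "CDS"
UTR5 = "UTR5"

#: extra validation flag set on genes whose CDS length is not a codon multiple
FLAG_BAD_CDS_LENGTH = "cds_length_not_multiple_of_3"

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Structurally invalid FASTA/GFF3 input."""


class AnnotationWarning(UserWarning):
    """Recoverable oddity in the input annotation."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source) -> dict[str, str]:
    """Read a (multi-record) FASTA into a mapping chromosome-id -> sequence.

    Sequences are uppercased and U is converted to T.  Letters outside
    {A, C, G, T} are preserved but reported with an :class:`AnnotationWarning`.
    Duplicate record ids and empty records are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(source, "fasta"):
        if record.id in sequences:
            raise AnnotationError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise AnnotationError(f"empty FASTA record {record.id!r}")
        unexpected = set(seq) - set("ACGT")
        if unexpected:
            warnings.warn(
                f"record {record.id!r} contains non-ACGT letters: "
                f"{''.join(sorted(unexpected))}",
                AnnotationWarning,
                stacklevel=2,
            )
        sequences[record.id] = seq
    if not sequences:
        raise AnnotationError("no FASTA records found")
    return sequences


# ---------------------------------------------------------------------------
# Gene models

def _check_intervals(ivals: Sequence[Interval], what: str, gene_id: str) -> None:
    for s, e in ivals:
        if s > e:
            raise AnnotationError(f"{gene_id}: {what} interval ({s}, {e}) has start > end")
    for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            raise AnnotationError(
                f"{gene_id}: {what} intervals ({s1},{e1}) and ({s2},{e2}) "
                "overlap or are out of ascending order"
            )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene's coding structure on one strand of a chromosome.

    ``coding_exons`` holds the CDS intervals in ascending genomic order; a
    coding exon may be as short as 1 nt (no minimum-exon filter is applied).
    ``utr5_introns`` holds explicitly annotated intron intervals located wholly
    within the 5' UTR.
    """

    id: str
    chromosome: str
    strand: str
    coding_exons: tuple[Interval, ...]
    utr5_introns: tuple[Interval, ...] = ()
    pseudo: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.id}: strand must be '+' or '-'")
        if not self.coding_exons:
            raise AnnotationError(f"{self.id}: gene has no coding exons")
        _check_intervals(self.coding_exons, "coding exon", self.id)
        _check_intervals(self.utr5_introns, "UTR5 intron", self.id)
        if self.coding_length < 3:
            raise AnnotationError(f"{self.id}: total coding length < 3")
        if self.coding_length % 3 and not self.pseudo and FLAG_BAD_CDS_LENGTH not in self.flags:
            raise AnnotationError(
                f"{self.id}: coding length {self.coding_length} not a multiple of 3"
            )

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_exons)

    @property
    def span(self) -> Interval:
        starts = [self.coding_exons[0][0]] + [s for s, _ in self.utr5_introns]
        ends = [self.coding_exons[-1][1]] + [e for _, e in self.utr5_introns]
        return min(starts), max(ends)

    @property
    def n_cds_introns(self) -> int:
        return len(self.coding_exons) - 1


@dataclass(frozen=True)
class Intron:
    """One spliceosomal intron in transcript orientation.

    ``start``/``end`` are genomic (ascending); ``sequence`` is the
    transcript-strand sequence, i.e. reverse-complemented for minus-strand
    genes.  ``phase`` is ``None`` exactly when ``compartment == "UTR5"``.
    """

    gene_id: str
    ordinal: int
    start: int
    end: int
    sequence: str
    phase: int | None
    compartment: str
    chromosome: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"intron ({self.start},{self.end}) has start > end")
        if len(self.sequence) != self.end - self.start + 1:
            raise AnnotationError(
                f"{self.gene_id} intron {self.ordinal}: sequence length "
                f"{len(self.sequence)} != interval span {self.end - self.start + 1}"
            )
        if (self.phase is None) != (self.compartment == UTR5):
            raise AnnotationError(
                f"{self.gene_id} intron {self.ordinal}: phase must be None "
                "iff the intron lies in the 5' UTR"
            )
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise AnnotationError(f"invalid phase {self.phase!r}")
        if self.ordinal < 1:
            raise AnnotationError("ordinal must be >= 1")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def length_class(self) -> int:
        """Length modulo 3: 0 for 3n, 1 for 3n+1, 2 for 3n+2 introns."""
        return self.length_nt % 3


@dataclass
class GenomeAnnotation:
    """A genome's sequences plus its validated gene models."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.id in seen:
                raise AnnotationError(f"duplicate gene id {gene.id!r}")
            seen.add(gene.id)
            if gene.chromosome not in self.sequences:
                raise AnnotationError(
                    f"{gene.id}: unknown chromosome {gene.chromosome!r}"
                )
            lo, hi = gene.span
            if lo < 1 or hi > len(self.sequences[gene.chromosome]):
                raise AnnotationError(
                    f"{gene.id}: coordinates ({lo},{hi}) outside chromosome "
                    f"{gene.chromosome!r} of length {len(self.sequences[gene.chromosome])}"
                )

    def non_pseudo(self) -> list[GeneModel]:
        return [g for g in self.genes if not g.pseudo]

    def get_gene(self, gene_id: str) -> GeneModel:
        for gene in self.genes:
            if gene.id == gene_id:
                return gene
        raise KeyError(gene_id)


def _looks_like_gff_text(source: str) -> bool:
    return "\n" in source or source.startswith("##")


def read_gene_models(gff_source, sequences: Mapping[str, str]) -> GenomeAnnotation:
    """Assemble one :class:`GeneModel` per mRNA from GFF3 text.

    ``gff_source`` may be raw GFF3 text, a text handle, or a file path.
    Coding exons are taken from CDS features; 5' UTR introns are inferred as
    gaps between consecutive exon features lying wholly 5' of the first CDS
    base in transcript orientation.  A CDS length that is not a multiple of 3
    on a non-pseudo gene produces a warning and flags the gene rather than
    dropping it; unresolved Parent references are a hard error.
    """
    if hasattr(gff_source, "read"):
        text = gff_source.read()
    elif isinstance(gff_source, (str, os.PathLike)) and not _looks_like_gff_text(str(gff_source)):
        with open(gff_source) as handle:
            text = handle.read()
    else:
        text = str(gff_source)

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return GenomeAnnotation(sequences=dict(sequences), genes=[])

    for feature in db.all_features():
        for parent_id in feature.attributes.get("Parent", []):
            try:
                db[parent_id]
            except gffutils.FeatureNotFoundError:
                raise AnnotationError(
                    f"unresolved Parent reference {parent_id!r} on feature "
                    f"{feature.id or feature.featuretype!r}"
                ) from None

    mrna_per_gene = Counter(
        pid
        for m in db.features_of_type("mRNA")
        for pid in m.attributes.get("Parent", [])
    )

    def _is_pseudo(feature) -> bool:
        if feature.featuretype == "pseudogene":
            return True
        value = feature.attributes.get("pseudo", ["false"])[0]
        return value.lower() in {"true", "1", "yes"}

    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        cds = sorted(
            db.children(mrna, featuretype="CDS", order_by="start"),
            key=lambda f: f.start,
        )
        if not cds:
            warnings.warn(
                f"mRNA {mrna.id!r} has no CDS features; skipped",
                AnnotationWarning,
                stacklevel=2,
            )
            continue
        exons = sorted(
            db.children(mrna, featuretype="exon", order_by="start"),
            key=lambda f: f.start,
        )
        parents = list(db.parents(mrna, featuretype=("gene", "pseudogene"), level=1))
        pseudo = _is_pseudo(mrna) or any(_is_pseudo(p) for p in parents)
        if len(parents) == 1 and mrna_per_gene[parents[0].id] == 1:
            gene_id = parents[0].id
        else:
            gene_id = mrna.id

        coding_exons = tuple((f.start, f.end) for f in cds)
        flags: tuple[str, ...] = ()
        coding_length = sum(e - s + 1 for s, e in coding_exons)
        if coding_length % 3 and not pseudo:
            warnings.warn(
                f"{gene_id}: CDS length {coding_length} is not a multiple of 3",
                AnnotationWarning,
                stacklevel=2,
            )
            flags = (FLAG_BAD_CDS_LENGTH,)

        # 5' UTR introns: exon-feature gaps wholly upstream of the first CDS base
        utr5: list[Interval] = []
        if mrna.strand == "+":
            first_cds = coding_exons[0][0]
            for e1, e2 in zip(exons, exons[1:]):
                gap = (e1.end + 1, e2.start - 1)
                if gap[0] <= gap[1] and gap[1] < first_cds:
                    utr5.append(gap)
        else:
            first_cds = coding_exons[-1][1]
            for e1, e2 in zip(exons, exons[1:]):
                gap = (e1.end + 1, e2.start - 1)
                if gap[0] <= gap[1] and gap[0] > first_cds:
                    utr5.append(gap)

        genes.append(
            GeneModel(
                id=gene_id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                coding_exons=coding_exons,
                utr5_introns=tuple(utr5),
                pseudo=pseudo,
                flags=flags,
            )
        )

    return GenomeAnnotation(sequences=dict(sequences), genes=genes)


# ---------------------------------------------------------------------------
# Intron extraction

def spliced_cds(gene: GeneModel, sequences: Mapping[str, str]) -> str:
    """The gene's spliced coding sequence in transcript orientation."""
    chrom = sequences[gene.chromosome]
    joined = "".join(chrom[s - 1 : e] for s, e in gene.coding_exons)
    return reverse_complement(joined) if gene.strand == "-" else joined


def upstream_coding_length(gene: GeneModel, intron: Intron) -> int:
    """Coding nucleotides upstream (in the transcript) of a CDS intron."""
    if intron.compartment != CDS:
        raise ValueError("upstream coding length is defined for CDS introns only")
    if gene.strand == "+":
        return sum(e - s + 1 for s, e in gene.coding_exons if e < intron.start)
    return sum(e - s + 1 for s, e in gene.coding_exons if s > intron.end)


def _gene_introns(gene: GeneModel, chrom: str) -> list[Intron]:
    minus = gene.strand == "-"

    gaps: list[Interval] = []
    for (s1, e1), (s2, e2) in zip(gene.coding_exons, gene.coding_exons[1:]):
        if s2 == e1 + 1:
            raise AnnotationError(
                f"{gene.id}: zero-length gap between coding exons ({s1},{e1}) and "
                f"({s2},{e2}); adjacent exons must be merged upstream"
            )
        gaps.append((e1 + 1, s2 - 1))

    exon_lengths = [e - s + 1 for s, e in gene.coding_exons]
    if minus:
        gaps = gaps[::-1]
        exon_lengths = exon_lengths[::-1]

    introns: list[Intron] = []
    upstream = 0
    for ordinal, (gs, ge) in enumerate(gaps, start=1):
        upstream += exon_lengths[ordinal - 1]
        seq = chrom[gs - 1 : ge]
        if minus:
            seq = reverse_complement(seq)
        introns.append(
            Intron(
                gene_id=gene.id,
                ordinal=ordinal,
                start=gs,
                end=ge,
                sequence=seq,
                phase=upstream % 3,
                compartment=CDS,
                chromosome=gene.chromosome,
                strand=gene.strand,
            )
        )

    utr_intervals = list(gene.utr5_introns)
    if minus:
        utr_intervals = utr_intervals[::-1]
    for ordinal, (gs, ge) in enumerate(utr_intervals, start=1):
        seq = chrom[gs - 1 : ge]
        if minus:
            seq = reverse_complement(seq)
        introns.append(
            Intron(
                gene_id=gene.id,
                ordinal=ordinal,
                start=gs,
                end=ge,
                sequence=seq,
                phase=None,
                compartment=UTR5,
                chromosome=gene.chromosome,
                strand=gene.strand,
            )
        )
    return introns


def extract_introns(
    annotation: GenomeAnnotation, include_pseudo: bool = True
) -> list[Intron]:
    """Extract every intron of every gene model.

    CDS introns are the gaps between consecutive coding exons; 5' UTR introns
    come from explicitly annotated UTR intervals and carry no phase.  The
    extractor applies no length filter (see :func:`filter_introns`).
    """
    introns: list[Intron] = []
    for gene in annotation.genes:
        if gene.pseudo and not include_pseudo:
            continue
        introns.extend(_gene_introns(gene, annotation.sequences[gene.chromosome]))
    return introns


def filter_introns(
    introns: Iterable[Intron],
    min_length: int = 30,
    compartments: tuple[str, ...] = (CDS,),
) -> list[Intron]:
    """Downstream-statistics filter: minimum length and compartment selection.

    The default minimum of 30 nt is a conservative floor below the shortest
    intron expected in a compact fungal genome; the extractor itself imposes
    no minimum.
    """
    return [
        i
        for i in introns
        if i.length_nt >= min_length and i.compartment in compartments
    ]


# ---------------------------------------------------------------------------
# Tabular output

INTRON_TABLE_COLUMNS = [
    "gene_id",
    "chromosome",
    "strand",
    "ordinal",
    "start",
    "end",
    "length",
    "phase",
    "compartment",
    "sequence",
]


def introns_to_frame(introns: Iterable[Intron]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": i.gene_id,
            "chromosome": i.chromosome,
            "strand": i.strand,
            "ordinal": i.ordinal,
            "start": i.start,
            "end": i.end,
            "length": i.length_nt,
            "phase": i.phase,
            "compartment": i.compartment,
            "sequence": i.sequence,
        }
        for i in introns
    ]
    frame = pd.DataFrame(rows, columns=INTRON_TABLE_COLUMNS)
    frame["phase"] = frame["phase"].astype("Int64")
    return frame


def write_intron_table(introns: Iterable[Intron], path) -> None:
    introns_to_frame(introns).to_csv(path, sep="\t", index=False)
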
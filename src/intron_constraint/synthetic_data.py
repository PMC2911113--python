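"""Synthetic genomes with planted intron statistics.

Generates FASTA + GFF3 + a per-intron truth table so every pipeline stage can
be tested without external downloads.  The generator emulates the statistical
structure of a compact, intron-poor hemiascomycete genome: per-gene intron
counts heavily skewed to one intron, a short-intron-dominated length mixture
with a 41-60 nt peak and a lognormal long tail, phase probabilities of about
(0.40, 0.38, 0.22), a 5' positional bias of introns within the CDS, donor
hexamers dominated by GTGAGT with GTAAGT secondary, a branch point CTAAC
juxtaposed to a (C|T)AG acceptor with a small spacer, and a configurable
stop-free intron fraction.

Stop content is enforced in both directions: introns flagged stop-free are
rejection-sampled until they contain no in-frame stop, and unflagged introns
until they contain at least one, so the planted stop-free fraction is exactly
the Bernoulli flag rate.  Without the second constraint short random introns
would frequently be stop-free by chance and the configured fraction would not
be recoverable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeAnnotation, reverse_complement

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Planted parameters of a synthetic genome.

    Probability vectors must sum to 1.  Defaults describe the study
    conditions: an intron-poor genome at 49% GC where ~15% of genes carry
    introns (85-90% of them mono-intronic), phases ~(0.40, 0.38, 0.22), a 3n
    length-class deficit (0.294, 0.355, 0.351), donor GTGAGT at 70%, acceptor
    TAG at 10.5%, branch-point spacer concentrated at one nucleotide, ~8%
    stop-free introns, and a 60% bias of introns into the first CDS decile.
    """

    seed: int
    n_genes: int = 500
    n_chromosomes: int = 1
    pseudo_fraction: float = 0.021
    intron_fraction_of_genes: float = 0.15
    introns_per_gene_probs: tuple[float, ...] = (0.8854, 0.0978, 0.0116, 0.0031, 0.0021)
    phase_probs: tuple[float, float, float] = (0.402, 0.380, 0.218)
    length_class_probs: tuple[float, float, float] = (0.294, 0.355, 0.351)
    short_length_weight: float = 0.25
    short_length_range: tuple[int, int] = (41, 60)
    long_length_offset: int = 61
    long_length_mu: float = 5.33
    long_length_sigma: float = 0.85
    min_intron_length: int = 41
    max_intron_length: int = 3478
    stopfree_target_fraction: float = 0.081
    five_ss_probs: tuple[tuple[str, float], ...] = (
        ("GTGAGT", 0.70),
        ("GTAAGT", 0.10),
        ("*", 0.20),  # random GT-initial hexamer
    )
    bp_motif: str = "CTAAC"
    s2_probs: tuple[tuple[int, float], ...] = ((0, 0.05), (1, 0.80), (2, 0.10), (3, 0.05))
    three_ss_probs: tuple[tuple[str, float], ...] = (
        ("CAG", 0.89),
        ("TAG", 0.105),
        ("AAG", 0.005),
    )
    utr5_intron_rate: float = 0.0056
    utr5_length_factor: float = 2.0
    gc_content: float = 0.49
    first_decile_bias: float = 0.60
    cds_codons_log_mu: float = 5.86
    cds_codons_log_sigma: float = 0.45
    cds_codons_range: tuple[int, int] = (60, 1500)
    intergenic_range: tuple[int, int] = (200, 2000)
    minus_strand_fraction: float = 0.0
    max_rejection_retries: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        vectors = {
            "introns_per_gene_probs": self.introns_per_gene_probs,
            "phase_probs": self.phase_probs,
            "length_class_probs": self.length_class_probs,
            "five_ss_probs": tuple(p for _, p in self.five_ss_probs),
            "s2_probs": tuple(p for _, p in self.s2_probs),
            "three_ss_probs": tuple(p for _, p in self.three_ss_probs),
        }
        for name, vec in vectors.items():
            if abs(sum(vec) - 1.0) > 1e-6:
                raise SimulationError(f"{name} sums to {sum(vec)}, not 1")
        for frac in (
            self.pseudo_fraction,
            self.intron_fraction_of_genes,
            self.stopfree_target_fraction,
            self.first_decile_bias,
            self.minus_strand_fraction,
            self.utr5_intron_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"fraction {frac} outside [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise SimulationError("gc_content must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


TRUTH_COLUMNS = [
    "gene_id",
    "chromosome",
    "strand",
    "compartment",
    "ordinal",
    "start",
    "end",
    "length",
    "phase",
    "length_class",
    "decile",
    "upstream_coding_nt",
    "five_ss",
    "bp_motif",
    "bp_start",
    "s1_nt",
    "s2_nt",
    "three_ss",
    "stop_free",
    "n_stops",
    "sequence",
]


@dataclass
class SyntheticGenome:
    """Generator output: sequences, annotation, emitted text, truth table."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    fasta_text: str
    gff_text: str
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff": outdir / "annotation.gff3",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.json",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff"].write_text(self.gff_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["config"].write_text(self.config.to_json() + "\n")
        return paths


def truth_table(genome: SyntheticGenome) -> pd.DataFrame:
    """Per-intron truth records of a generated genome (one row per intron)."""
    return genome.truth


# ---------------------------------------------------------------------------
# Low-level sampling

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n-2) random non-stop codons + a random stop codon."""
    body = _random_seq(rng, (n_codons - 2) * 3, gc)
    arr = np.frombuffer(body.encode(), dtype=np.uint8).copy().reshape(-1, 3)
    while True:
        is_stop = np.zeros(arr.shape[0], dtype=bool)
        for stop in _STOPS:
            is_stop |= (arr == np.frombuffer(stop.encode(), np.uint8)).all(axis=1)
        k = int(is_stop.sum())
        if k == 0:
            break
        replacement = np.frombuffer(_random_seq(rng, 3 * k, gc).encode(), np.uint8)
        arr[is_stop] = replacement.reshape(k, 3)
    stop = _STOPS[rng.integers(3)]
    return "ATG" + arr.tobytes().decode() + stop


def _stop_positions(seq: str, phase: int) -> list[int]:
    first = ((3 - phase) % 3) + 1
    return [
        p for p in range(first, len(seq) - 1, 3) if seq[p - 1 : p + 2] in _STOPS
    ]


def _sample_categorical(rng, pairs):
    values = [v for v, _ in pairs]
    probs = np.array([p for _, p in pairs])
    return values[rng.choice(len(values), p=probs / probs.sum())]


def _sample_length(rng, cfg: SimulationConfig) -> int:
    if rng.random() < cfg.short_length_weight:
        length = int(rng.integers(cfg.short_length_range[0], cfg.short_length_range[1] + 1))
    else:
        length = cfg.long_length_offset + int(
            rng.lognormal(cfg.long_length_mu, cfg.long_length_sigma)
        )
    return int(min(max(length, cfg.min_intron_length), cfg.max_intron_length))


def _adjust_length_class(length: int, target_class: int, cfg: SimulationConfig) -> int:
    for delta in (0, 1, -1, 2, -2):
        cand = length + delta
        if cand % 3 == target_class and cfg.min_intron_length <= cand <= cfg.max_intron_length:
            return cand
    raise SimulationError(f"cannot adjust length {length} to class {target_class}")


def _scrub_stops(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    seq: str,
    phase: int,
    mutable: np.ndarray,
) -> str | None:
    """Remove all in-frame stops by resampling mutable stop-codon bases.

    Returns the scrubbed sequence, or None when some stop lies wholly within
    fixed motif positions (the motif combination forces a stop).
    """
    chars = list(seq)
    for _ in range(100):
        stops = _stop_positions("".join(chars), phase)
        if not stops:
            return "".join(chars)
        progress = False
        for p in stops:
            candidates = [i for i in range(p - 1, p + 2) if mutable[i]]
            if candidates:
                i = candidates[int(rng.integers(len(candidates)))]
                chars[i] = _random_seq(rng, 1, cfg.gc_content)
                progress = True
        if not progress:
            return None
    return None


def _build_intron(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    phase: int | None,
    length: int,
    want_stop_free: bool | None,
) -> dict:
    """One intron: donor + interior + branch point + spacer + acceptor.

    ``want_stop_free`` of True/False enforces absence/presence of in-frame
    stops by rejection sampling: motif combinations are redrawn up to the
    retry bound, and for stop-free introns the offending stop-codon bases in
    the interior/spacer are resampled codon-wise (so enforcement converges
    for introns of any length).  None (UTR introns) accepts the first draw.
    """
    for _ in range(cfg.max_rejection_retries):
        five = _sample_categorical(rng, cfg.five_ss_probs)
        if five == "*":
            five = "GT" + _random_seq(rng, 4, cfg.gc_content)
        s2 = _sample_categorical(rng, cfg.s2_probs)
        three = _sample_categorical(rng, cfg.three_ss_probs)
        interior_len = length - 6 - len(cfg.bp_motif) - s2 - 3
        if interior_len < 0:
            raise SimulationError(
                f"intron length {length} too short for the motif layout"
            )
        seq = (
            five
            + _random_seq(rng, interior_len, cfg.gc_content)
            + cfg.bp_motif
            + _random_seq(rng, s2, cfg.gc_content)
            + three
        )
        if phase is None or want_stop_free is None:
            stops: list[int] = []
            ok = True
            if phase is not None:
                stops = _stop_positions(seq, phase)
        elif want_stop_free:
            mutable = np.zeros(length, dtype=bool)
            mutable[6 : 6 + interior_len] = True  # interior
            mutable[6 + interior_len + len(cfg.bp_motif) : length - 3] = True  # spacer
            scrubbed = _scrub_stops(rng, cfg, seq, phase, mutable)
            ok = scrubbed is not None
            if ok:
                seq = scrubbed
                stops = []
        else:
            stops = _stop_positions(seq, phase)
            ok = bool(stops)
        if ok:
            return {
                "sequence": seq,
                "length": length,
                "five_ss": five,
                "bp_motif": cfg.bp_motif,
                "bp_start": 6 + interior_len + 1,
                "s1_nt": interior_len,
                "s2_nt": s2,
                "three_ss": three,
                "stop_free": not stops,
                "n_stops": len(stops),
            }
    raise SimulationError(
        f"could not build a {'stop-free' if want_stop_free else 'stop-containing'} "
        f"intron for phase {phase}, length class {length % 3}: the configured "
        "splice motifs force the opposite stop content"
    )


# ---------------------------------------------------------------------------
# Gene assembly

@dataclass
class _GeneDraft:
    gene_id: str
    strand: str
    pseudo: bool
    block: str  # transcript-orientation genomic block
    coding_exons_t: list[tuple[int, int]]  # transcript-space, 1-based
    exon_features_t: list[tuple[int, int]]
    utr5_features_t: list[tuple[int, int]]
    utr5_introns_t: list[tuple[int, int]]
    intron_truth: list[dict]  # transcript-space coords in 'start_t'/'end_t'


def _draw_gene(rng, cfg: SimulationConfig, gene_id: str) -> _GeneDraft:
    pseudo = rng.random() < cfg.pseudo_fraction
    strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
    n_codons = int(
        min(
            max(
                round(rng.lognormal(cfg.cds_codons_log_mu, cfg.cds_codons_log_sigma)),
                cfg.cds_codons_range[0],
            ),
            cfg.cds_codons_range[1],
        )
    )
    cds = _random_cds(rng, n_codons, cfg.gc_content)
    coding_length = 3 * n_codons

    n_introns = 0
    if not pseudo and rng.random() < cfg.intron_fraction_of_genes:
        n_introns = 1 + int(
            rng.choice(
                len(cfg.introns_per_gene_probs), p=np.array(cfg.introns_per_gene_probs)
            )
        )

    # insertion points: upstream coding nt counts, congruent to the drawn phase
    insertion_points: list[int] = []
    for _ in range(50):
        draws = []
        for _ in range(n_introns):
            decile = 1 if rng.random() < cfg.first_decile_bias else int(rng.integers(2, 11))
            lo = max(1, math.ceil((decile - 1) * coding_length / 10))
            hi = min(coding_length - 3, math.ceil(decile * coding_length / 10) - 1)
            if hi < lo:
                lo, hi = 1, coding_length - 3
            u = int(rng.integers(lo, hi + 1))
            phase = int(rng.choice(3, p=np.array(cfg.phase_probs)))
            u += (phase - u) % 3
            if u > coding_length - 3:
                u -= 3
            u = max(1, u)
            draws.append(u)
        if len(set(draws)) == n_introns:
            insertion_points = sorted(draws)
            break
    else:
        raise SimulationError(f"{gene_id}: could not place {n_introns} distinct introns")

    introns = []
    for u in insertion_points:
        phase = u % 3
        target_class = int(rng.choice(3, p=np.array(cfg.length_class_probs)))
        length = _adjust_length_class(_sample_length(rng, cfg), target_class, cfg)
        want_stop_free = rng.random() < cfg.stopfree_target_fraction
        built = _build_intron(rng, cfg, phase, length, want_stop_free)
        built["upstream_coding_nt"] = u
        built["phase"] = phase
        introns.append(built)

    # optional 5' UTR intron
    utr1 = utr2 = ""
    utr_intron: dict | None = None
    if not pseudo and rng.random() < cfg.utr5_intron_rate:
        utr1 = _random_seq(rng, int(rng.integers(20, 81)), cfg.gc_content)
        utr2 = _random_seq(rng, int(rng.integers(10, 51)), cfg.gc_content)
        raw = _sample_length(rng, cfg)
        length = int(
            min(
                max(round(raw * cfg.utr5_length_factor), cfg.min_intron_length),
                cfg.max_intron_length,
            )
        )
        utr_intron = _build_intron(rng, cfg, None, length, None)

    # assemble transcript-space block
    parts: list[str] = []
    cursor = 0

    def _push(seq: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor + 1
        cursor += len(seq)
        parts.append(seq)
        return start, cursor

    utr5_features: list[tuple[int, int]] = []
    utr5_introns: list[tuple[int, int]] = []
    if utr_intron is not None:
        utr5_features.append(_push(utr1))
        utr5_introns.append(_push(utr_intron["sequence"]))
        utr5_features.append(_push(utr2))
        utr_intron["start_t"], utr_intron["end_t"] = utr5_introns[0]

    coding_exons: list[tuple[int, int]] = []
    prev = 0
    for built in introns:
        u = built["upstream_coding_nt"]
        coding_exons.append(_push(cds[prev:u]))
        built["start_t"], built["end_t"] = _push(built["sequence"])
        prev = u
    coding_exons.append(_push(cds[prev:]))

    # exon features merge contiguous UTR tail with the first coding exon
    exon_features: list[tuple[int, int]] = []
    if utr_intron is not None:
        exon_features.append(utr5_features[0])
        exon_features.append((utr5_features[1][0], coding_exons[0][1]))
    else:
        exon_features.append(coding_exons[0])
    exon_features.extend(coding_exons[1:])

    if utr_intron is not None:
        utr_intron.update(
            {
                "phase": None,
                "upstream_coding_nt": None,
                "stop_free": None,
                "n_stops": None,
            }
        )
        introns = introns + [utr_intron]

    for built in introns:
        built["coding_length"] = coding_length

    return _GeneDraft(
        gene_id=gene_id,
        strand=strand,
        pseudo=pseudo,
        block="".join(parts),
        coding_exons_t=coding_exons,
        exon_features_t=exon_features,
        utr5_features_t=utr5_features,
        utr5_introns_t=utr5_introns,
        intron_truth=introns,
    )


def _map_interval(t_ivl, offset: int, block_len: int, strand: str) -> tuple[int, int]:
    a, b = t_ivl
    if strand == "+":
        return offset + a, offset + b
    return offset + block_len - b + 1, offset + block_len - a + 1


def _wrap_fasta(name: str, seq: str, width: int = 70) -> str:
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def _gff_line(seqid, ftype, start, end, strand, attrs, frame=".") -> str:
    return f"{seqid}\tsim\t{ftype}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}"


def generate(config: SimulationConfig) -> SyntheticGenome:
    """Generate a synthetic genome honouring the configured intron statistics.

    Deterministic: the same configuration (including seed) yields byte-
    identical FASTA/GFF3/truth outputs.
    """
    rng = np.random.default_rng(config.seed)

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_cursor: dict[str, int] = {c: 0 for c in chrom_names}

    genes: list[GeneModel] = []
    gff_records: list[str] = []
    truth_rows: list[dict] = []

    for i in range(config.n_genes):
        gene_id = f"g{i + 1:05d}"
        chrom = chrom_names[i * config.n_chromosomes // max(config.n_genes, 1)]
        draft = _draw_gene(rng, config, gene_id)

        spacer = _random_seq(
            rng,
            int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1)),
            config.gc_content,
        )
        chrom_parts[chrom].append(spacer)
        chrom_cursor[chrom] += len(spacer)
        offset = chrom_cursor[chrom]

        block_len = len(draft.block)
        genomic_block = (
            reverse_complement(draft.block) if draft.strand == "-" else draft.block
        )
        chrom_parts[chrom].append(genomic_block)
        chrom_cursor[chrom] += block_len

        def gmap(ivl):
            return _map_interval(ivl, offset, block_len, draft.strand)

        coding_exons = sorted(gmap(ivl) for ivl in draft.coding_exons_t)
        utr5_introns = sorted(gmap(ivl) for ivl in draft.utr5_introns_t)
        genes.append(
            GeneModel(
                id=gene_id,
                chromosome=chrom,
                strand=draft.strand,
                coding_exons=tuple(coding_exons),
                utr5_introns=tuple(utr5_introns),
                pseudo=draft.pseudo,
            )
        )

        # GFF3 features
        mrna_id = f"{gene_id}.t1"
        gene_ivl = gmap((1, block_len))
        pseudo_attr = ";pseudo=true" if draft.pseudo else ""
        gff_records.append(
            _gff_line(chrom, "gene", *gene_ivl, draft.strand, f"ID={gene_id}{pseudo_attr}")
        )
        gff_records.append(
            _gff_line(
                chrom, "mRNA", *gene_ivl, draft.strand,
                f"ID={mrna_id};Parent={gene_id}{pseudo_attr}",
            )
        )
        for j, ivl in enumerate(draft.exon_features_t, start=1):
            gff_records.append(
                _gff_line(
                    chrom, "exon", *gmap(ivl), draft.strand,
                    f"ID={mrna_id}.exon{j};Parent={mrna_id}",
                )
            )
        for j, ivl in enumerate(draft.utr5_features_t, start=1):
            gff_records.append(
                _gff_line(
                    chrom, "five_prime_UTR", *gmap(ivl), draft.strand,
                    f"ID={mrna_id}.utr{j};Parent={mrna_id}",
                )
            )
        upstream = 0
        for j, ivl in enumerate(draft.coding_exons_t, start=1):
            frame = (3 - upstream % 3) % 3
            upstream += ivl[1] - ivl[0] + 1
            gff_records.append(
                _gff_line(
                    chrom, "CDS", *gmap(ivl), draft.strand,
                    f"ID={mrna_id}.cds;Parent={mrna_id}", frame=frame,
                )
            )

        # truth records (CDS introns in transcript order, then UTR5)
        cds_ordinal = 0
        utr_ordinal = 0
        for built in draft.intron_truth:
            g_start, g_end = gmap((built["start_t"], built["end_t"]))
            is_utr = built["phase"] is None
            if is_utr:
                utr_ordinal += 1
            else:
                cds_ordinal += 1
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": chrom,
                    "strand": draft.strand,
                    "compartment": "UTR5" if is_utr else "CDS",
                    "ordinal": utr_ordinal if is_utr else cds_ordinal,
                    "start": g_start,
                    "end": g_end,
                    "length": built["length"],
                    "phase": built["phase"],
                    "length_class": built["length"] % 3,
                    "decile": None
                    if is_utr
                    else min(
                        10,
                        10 * built["upstream_coding_nt"] // built["coding_length"] + 1,
                    ),
                    "upstream_coding_nt": built["upstream_coding_nt"],
                    "five_ss": built["five_ss"],
                    "bp_motif": built["bp_motif"],
                    "bp_start": built["bp_start"],
                    "s1_nt": built["s1_nt"],
                    "s2_nt": built["s2_nt"],
                    "three_ss": built["three_ss"],
                    "stop_free": built["stop_free"],
                    "n_stops": built["n_stops"],
                    "sequence": built["sequence"],
                }
            )

    for chrom in chrom_names:
        tail = _random_seq(
            rng,
            int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1)),
            config.gc_content,
        )
        chrom_parts[chrom].append(tail)
        chrom_cursor[chrom] += len(tail)

    sequences = {c: "".join(chrom_parts[c]) for c in chrom_names}
    annotation = GenomeAnnotation(sequences=sequences, genes=genes)

    fasta_text = "".join(_wrap_fasta(c, sequences[c]) for c in chrom_names)
    header = ["##gff-version 3"] + [
        f"##sequence-region {c} 1 {len(sequences[c])}" for c in chrom_names
    ]
    gff_text = "\n".join(header + gff_records) + "\n"

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    for col in ("phase", "length_class", "decile", "upstream_coding_nt", "bp_start",
                "s1_nt", "s2_nt", "n_stops"):
        truth[col] = truth[col].astype("Int64")

    return SyntheticGenome(
        config=config,
        annotation=annotation,
        fasta_text=fasta_text,
        gff_text=gff_text,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Worked-example gene builders

def build_exon_skip_example(
    seed: int = 0,
    protein_aa: int = 502,
    skip_exon_aa: int = 13,
    first_exon_aa: int = 100,
    gc: float = 0.49,
) -> tuple[GenomeAnnotation, GeneModel]:
    """A three-exon gene whose internal exon is in-frame and skippable.

    The fully spliced product has ``protein_aa`` residues; the internal exon
    encodes ``skip_exon_aa`` of them (codon-aligned, phase-0 introns), so
    skipping it shortens the protein by exactly that many amino acids without
    a frameshift or a new stop.
    """
    rng = np.random.default_rng(seed)
    n_codons = protein_aa + 1  # annotated stop codon included
    cds = _random_cds(rng, n_codons, gc)
    u1, u2 = 3 * first_exon_aa, 3 * (first_exon_aa + skip_exon_aa)
    intron1 = _canonical_intron(rng, 50, gc)
    intron2 = _canonical_intron(rng, 53, gc)
    flank = _random_seq(rng, 200, gc)
    block = cds[:u1] + intron1 + cds[u1:u2] + intron2 + cds[u2:]
    chrom_seq = flank + block + _random_seq(rng, 200, gc)

    base = len(flank)
    e1 = (base + 1, base + u1)
    i1_end = e1[1] + len(intron1)
    e2 = (i1_end + 1, i1_end + (u2 - u1))
    i2_end = e2[1] + len(intron2)
    e3 = (i2_end + 1, i2_end + (3 * n_codons - u2))
    gene = GeneModel(
        id="demo_skip",
        chromosome="chr1",
        strand="+",
        coding_exons=(e1, e2, e3),
    )
    return GenomeAnnotation(sequences={"chr1": chrom_seq}, genes=[gene]), gene


def build_alt_tss_example(
    seed: int = 0,
    upstream_exon_aa: int = 102,
    downstream_aa: int = 1322,
    intron_length: int = 900,
    tss_upstream_nt: int = 179,
    gc: float = 0.49,
) -> tuple[GenomeAnnotation, GeneModel, int]:
    """A two-exon gene with a long first intron and an internal start codon.

    The annotated transcript splices the intron and translates from the first
    exon's ATG; a downstream TSS inside the intron yields a single-exon
    transcript whose first ATG opens the second exon, giving a shorter
    protein.  Returns (annotation, gene, downstream TSS coordinate).
    """
    rng = np.random.default_rng(seed)
    exon1 = _random_cds(rng, upstream_exon_aa + 1, gc)[:-3]  # ATG + codons, no stop
    exon2 = _random_cds(rng, downstream_aa + 1, gc)  # ATG ... stop
    interior_len = intron_length - 6 - 5 - 1 - 3
    while True:
        intron = (
            "GTGAGT" + _random_seq(rng, interior_len, gc) + "CTAAC" + "T" + "CAG"
        )
        if "ATG" not in intron[-tss_upstream_nt:]:
            break
    flank = _random_seq(rng, 150, gc)
    chrom_seq = flank + exon1 + intron + exon2 + _random_seq(rng, 150, gc)
    base = len(flank)
    e1 = (base + 1, base + len(exon1))
    e2 = (e1[1] + len(intron) + 1, e1[1] + len(intron) + len(exon2))
    gene = GeneModel(
        id="demo_tss", chromosome="chr1", strand="+", coding_exons=(e1, e2)
    )
    tss2 = e2[0] - tss_upstream_nt
    return GenomeAnnotation(sequences={"chr1": chrom_seq}, genes=[gene]), gene, tss2


def _canonical_intron(rng, length: int, gc: float) -> str:
    interior = _random_seq(rng, length - 6 - 5 - 1 - 3, gc)
    return "GTGAGT" + interior + "CTAAC" + "T" + "CAG"
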
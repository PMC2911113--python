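"""Genome-wide intron statistics.

Phase and length-class distributions with chi-square goodness-of-fit tests
against a uniform null, codon-position base frequencies over all coding
sequences, positional (decile) profiles of introns along the CDS, summary
tables of intron-containing genes per chromosome, intron density, and binned
size histograms.  Unless stated otherwise the statistics cover CDS introns of
non-pseudo genes; 5' UTR introns are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import CDS, GenomeAnnotation, Intron, upstream_coding_length

LENGTH_CLASS_LABELS = ("3n", "3n+1", "3n+2")
PHASE_LABELS = (0, 1, 2)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported figures)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CountTable:
    labels: tuple
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty count table has no fractions")
        return np.asarray(self.counts, dtype=float) / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.labels), name="count")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chisq_uniform(table: CountTable) -> ChiSquareResult:
    """Pearson chi-square goodness of fit against equal expected counts.

    No continuity correction; degrees of freedom are k - 1.
    """
    k = len(table.counts)
    if k < 2:
        raise ValueError("chi-square test needs at least 2 categories")
    if table.total == 0:
        raise ValueError("chi-square test on an all-zero table")
    statistic, p_value = sps.chisquare(np.asarray(table.counts, dtype=float))
    return ChiSquareResult(statistic=float(statistic), df=k - 1, p_value=float(p_value))


# ---------------------------------------------------------------------------
# Distributions

def _select(introns: Iterable[Intron], selector: str) -> list[Intron]:
    cds = [i for i in introns if i.compartment == CDS]
    if selector == "all":
        return cds
    if selector == "first_only":
        return [i for i in cds if i.ordinal == 1]
    if selector == "non_first":
        return [i for i in cds if i.ordinal > 1]
    raise ValueError(f"unknown selector {selector!r}")


def phase_distribution(introns: Iterable[Intron], selector: str = "all") -> CountTable:
    """Counts of CDS introns by phase (0, 1, 2)."""
    selected = _select(introns, selector)
    if not selected:
        raise ValueError("no CDS introns selected for the phase distribution")
    counts = [0, 0, 0]
    for intron in selected:
        counts[intron.phase] += 1
    return CountTable(labels=PHASE_LABELS, counts=tuple(counts))


def length_class_distribution(
    introns: Iterable[Intron], max_length: int | None = None, selector: str = "all"
) -> CountTable:
    """Counts of CDS introns by length class (3n, 3n+1, 3n+2).

    ``max_length`` restricts to introns of at most that length (inclusive).
    """
    selected = _select(introns, selector)
    if max_length is not None:
        selected = [i for i in selected if i.length_nt <= max_length]
    counts = [0, 0, 0]
    for intron in selected:
        counts[intron.length_class] += 1
    return CountTable(labels=LENGTH_CLASS_LABELS, counts=tuple(counts))


def counts_from_percentages(total: int, percentages: Sequence[float]) -> tuple[int, ...]:
    """Reconstruct integer counts from printed percentages of a known total.

    Each count is the nearest integer of ``total * pct / 100``; residual drift
    of +-1 per category is assigned to the categories with the largest rounding
    remainders so the counts sum to the total.
    """
    pct = np.asarray(percentages, dtype=float)
    if abs(pct.sum() - 100.0) > 0.5:
        raise ValueError(f"percentages sum to {pct.sum():.2f}, not 100 +- 0.5")
    raw = total * pct / 100.0
    counts = np.floor(raw + 0.5).astype(int)
    drift = total - int(counts.sum())
    if abs(drift) > len(counts):
        raise ValueError(f"irreconcilable rounding drift of {drift} counts")
    remainders = raw - counts
    order = np.argsort(-remainders) if drift > 0 else np.argsort(remainders)
    step = 1 if drift > 0 else -1
    for i in range(abs(drift)):
        counts[order[i]] += step
    return tuple(int(c) for c in counts)


# ---------------------------------------------------------------------------
# Codon-position base frequencies

_STOPS = (b"TAA", b"TAG", b"TGA")


def codon_position_base_freq(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Base frequencies at codon positions 1-3 over all non-pseudo CDSs.

    Stop codons are excluded.  Rows (positions) sum to 1.
    """
    from .genome_io import spliced_cds

    genes = annotation.non_pseudo()
    if not genes:
        raise ValueError("no non-pseudo genes in the annotation")
    base_index = np.full(256, -1, dtype=np.int64)
    for j, b in enumerate(b"ACGT"):
        base_index[b] = j
    counts = np.zeros((3, 4), dtype=np.int64)
    for gene in genes:
        cds = spliced_cds(gene, annotation.sequences)
        arr = np.frombuffer(cds.encode(), dtype=np.uint8)
        n_codons = len(arr) // 3
        codons = arr[: n_codons * 3].reshape(n_codons, 3)
        is_stop = np.zeros(n_codons, dtype=bool)
        for stop in _STOPS:
            target = np.frombuffer(stop, dtype=np.uint8)
            is_stop |= (codons == target).all(axis=1)
        kept = codons[~is_stop]
        idx = base_index[kept]
        for pos in range(3):
            col = idx[:, pos]
            counts[pos] += np.bincount(col[col >= 0], minlength=4)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(freqs, columns=list("ACGT"))
    frame.index = pd.Index([1, 2, 3], name="codon_position")
    return frame


# ---------------------------------------------------------------------------
# Positional profile

def positional_profile(
    introns: Iterable[Intron], annotation: GenomeAnnotation, selector: str = "all"
) -> pd.Series:
    """Fraction of CDS introns per 10%-decile of the CDS.

    An intron after ``u`` coding nucleotides of a CDS of length ``L`` falls in
    decile ``floor(10 u / L) + 1``.  Fractions sum to 1.
    """
    selected = _select(introns, selector)
    if not selected:
        raise ValueError("no CDS introns selected for the positional profile")
    genes = {g.id: g for g in annotation.genes}
    counts = np.zeros(10, dtype=int)
    for intron in selected:
        gene = genes[intron.gene_id]
        upstream = upstream_coding_length(gene, intron)
        decile = min(10, 10 * upstream // gene.coding_length + 1)
        counts[decile - 1] += 1
    series = pd.Series(counts / counts.sum(), index=pd.RangeIndex(1, 11, name="decile"))
    series.name = "fraction"
    return series


def intron_decile(gene, upstream: int) -> int:
    """Decile (1-10) of an intron after ``upstream`` coding nt of a gene's CDS."""
    return min(10, 10 * upstream // gene.coding_length + 1)


# ---------------------------------------------------------------------------
# Summary table and density

SUMMARY_COLUMNS = [
    "genes",
    "pseudogenes",
    "1_intron",
    "2_introns",
    "3_introns",
    "4_introns",
    "5plus_introns",
    "intron_genes",
    "introns",
    "utr5_introns",
]


def summary_table(
    annotation: GenomeAnnotation, introns: Iterable[Intron] | None = None
) -> pd.DataFrame:
    """Per-chromosome summary of genes, pseudogenes and intron-containing genes.

    Counts cover non-pseudo genes; the final ``genome`` row holds column sums.
    """
    from .genome_io import extract_introns

    if introns is None:
        introns = extract_introns(annotation, include_pseudo=False)
    cds_count: dict[str, int] = {}
    utr_count: dict[str, int] = {}
    for intron in introns:
        if intron.compartment == CDS:
            cds_count[intron.gene_id] = cds_count.get(intron.gene_id, 0) + 1
        else:
            utr_count[intron.gene_id] = utr_count.get(intron.gene_id, 0) + 1

    chromosomes = sorted(annotation.sequences)
    rows = {}
    for chrom in chromosomes:
        genes = [g for g in annotation.genes if g.chromosome == chrom]
        non_pseudo = [g for g in genes if not g.pseudo]
        by_count = [0] * 5  # 1, 2, 3, 4, >=5 introns
        for gene in non_pseudo:
            k = cds_count.get(gene.id, 0)
            if k >= 1:
                by_count[min(k, 5) - 1] += 1
        rows[chrom] = [
            len(non_pseudo),
            sum(g.pseudo for g in genes),
            *by_count,
            sum(by_count),
            sum(cds_count.get(g.id, 0) for g in non_pseudo),
            sum(utr_count.get(g.id, 0) for g in non_pseudo),
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=SUMMARY_COLUMNS)
    frame.loc["genome"] = frame.sum(axis=0)
    frame.index.name = "chromosome"
    return frame


def total_introns_from_counts(genes_by_intron_count: Mapping[int, int]) -> int:
    """Total introns implied by a {introns-per-gene: gene-count} distribution."""
    return sum(k * n for k, n in genes_by_intron_count.items())


def intron_density(n_introns: int, n_genes: int, ndigits: int = 2) -> float:
    """Introns per protein-coding gene, rounded to the report precision."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round_half_away(n_introns / n_genes, ndigits)


# ---------------------------------------------------------------------------
# Size histogram

def size_histogram(
    introns: Iterable[Intron],
    bin_width: int = 20,
    start: int = 41,
    overflow: int = 1000,
) -> pd.DataFrame:
    """Binned intron counts per length class.

    Bins of ``bin_width`` nt run from ``start`` to ``overflow``; lengths above
    ``overflow`` fall into a single overflow bin, lengths below ``start`` into
    an underflow bin (present only when occupied).  Cell counts sum to the
    number of CDS introns.
    """
    selected = _select(introns, "all")
    n_bins = (overflow - start + 1 + bin_width - 1) // bin_width
    labels = [
        f"{start + i * bin_width}-{min(start + (i + 1) * bin_width - 1, overflow)}"
        for i in range(n_bins)
    ]
    under_label, over_label = f"<{start}", f">{overflow}"
    counts = {label: [0, 0, 0] for label in [under_label, *labels, over_label]}
    for intron in selected:
        length = intron.length_nt
        if length < start:
            label = under_label
        elif length > overflow:
            label = over_label
        else:
            label = labels[(length - start) // bin_width]
        counts[label][intron.length_class] += 1
    if not any(counts[under_label]):
        del counts[under_label]
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=LENGTH_CLASS_LABELS)
    frame.index.name = "length_bin"
    frame["total"] = frame.sum(axis=1)
    return frame
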
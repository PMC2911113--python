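"""Premature termination codons (PTCs) in retained introns.

When an intron is retained in the mature mRNA, the ribosome reads into it in a
frame set by the intron's phase: the first codon lying wholly inside the
intron starts at intron position ``((3 - phase) mod 3) + 1``.  This module
scans retained introns for in-frame stops (TAA/TAG/TGA on the transcript
strand), attributes each stop to the conserved splice motifs it overlaps
(donor hexamer, branch point, acceptor trimer), derives the combinatorial
phase x length-class rule table those motifs imply, and compares observed stop
content with a stop-free null model for unconstrained codon strings.

Codons straddling the exon/intron junction are deliberately out of scope here
(they need flanking exon sequence and are handled by full-transcript
translation in :mod:`intron_constraint.as_consequence`): the motif rules are
expressible purely intron-internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_io import CDS, Intron
from .intron_stats import CountTable, LENGTH_CLASS_LABELS
from .splice_motifs import SpliceSignals, detect_signals

STOP_CODONS = ("TAA", "TAG", "TGA")

FIVE_SS = "five_ss"
BP = "bp"
THREE_SS = "three_ss"
OTHER = "other"


def first_inframe_start(phase: int) -> int:
    """Intron position (1-based) of the first codon wholly inside the intron.

    Equals 1, 3, 2 for phases 0, 1, 2 respectively.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"invalid phase {phase!r}")
    return ((3 - phase) % 3) + 1


@dataclass(frozen=True)
class RetentionOutcome:
    """In-frame stops of one retained intron, with optional motif attribution."""

    intron: Intron
    frameshifting: bool
    stop_positions: tuple[int, ...]
    first_stop_codon: str | None
    attributions: tuple[frozenset, ...] | None = None

    @property
    def stop_free(self) -> bool:
        return not self.stop_positions


@dataclass(frozen=True)
class NullModel:
    """Per-codon stop probability for unconstrained codon strings."""

    stop_probability_per_codon: float = 3 / 64
    mode: str = "uniform_codon"

    def __post_init__(self) -> None:
        if not 0.0 <= self.stop_probability_per_codon <= 1.0:
            raise ValueError("stop probability must lie in [0, 1]")
        if self.mode not in {"uniform_codon", "codon_usage"}:
            raise ValueError(f"unknown null-model mode {self.mode!r}")


def null_from_base_frequencies(freqs) -> NullModel:
    """Codon-usage null: stop probability from independent per-position base
    frequencies (a 3x4 table over A, C, G, T as produced by
    :func:`intron_stats.codon_position_base_freq`)."""
    table = pd.DataFrame(freqs)
    p = 0.0
    for stop in STOP_CODONS:
        term = 1.0
        for pos, base in enumerate(stop):
            term *= float(table.iloc[pos][base])
        p += term
    return NullModel(stop_probability_per_codon=p, mode="codon_usage")


# ---------------------------------------------------------------------------
# Scanning and attribution

def scan_retained_stops(intron: Intron) -> RetentionOutcome:
    """All in-frame stop codons lying wholly inside a retained CDS intron."""
    if intron.compartment != CDS or intron.phase is None:
        raise ValueError("retained-stop scanning is defined for CDS introns only")
    seq = intron.sequence
    length = intron.length_nt
    stops = []
    for pos in range(first_inframe_start(intron.phase), length - 1, 3):
        if seq[pos - 1 : pos + 2] in STOP_CODONS:
            stops.append(pos)
    return RetentionOutcome(
        intron=intron,
        frameshifting=length % 3 != 0,
        stop_positions=tuple(stops),
        first_stop_codon=seq[stops[0] - 1 : stops[0] + 2] if stops else None,
    )


def attribute_stops(outcome: RetentionOutcome, signals: SpliceSignals) -> RetentionOutcome:
    """Label each stop with every conserved motif interval it overlaps.

    A stop overlapping none of the donor hexamer (positions 1-6), the detected
    branch-point motif, or the acceptor trimer is labelled OTHER.
    """
    length = outcome.intron.length_nt
    attributions = []
    for pos in outcome.stop_positions:
        lo, hi = pos, pos + 2
        labels = set()
        if lo <= 6:
            labels.add(FIVE_SS)
        if hi >= length - 2:
            labels.add(THREE_SS)
        if signals.bp_start is not None and lo <= signals.bp_end and hi >= signals.bp_start:
            labels.add(BP)
        if not labels:
            labels.add(OTHER)
        attributions.append(frozenset(labels))
    return replace(outcome, attributions=tuple(attributions))


RULE_COLUMNS = (
    "five_ss_GTGAGT",
    "five_ss_GTAAGT",
    "bp_CTAAC_s2_1",
    "three_ss_TAG",
)


def bp_stop_in_frame(phase: int, length_class: int, s2: int) -> bool:
    """Does the TAA inside CTAAC land in frame, given the BP-to-3'ss spacing?

    With the acceptor trimer at the last three positions and ``s2`` spacer
    nucleotides, the branch point occupies positions L-7-s2 .. L-3-s2 and its
    internal TAA starts at L-6-s2.
    """
    return (length_class - s2) % 3 == first_inframe_start(phase) % 3


def rule_table() -> pd.DataFrame:
    """Predicted motif-generated PTCs for each (phase, length-class) cell.

    Pure combinatorics over the conserved motifs: donor GTGAGT/GTAAGT place a
    stop at intron positions 2-4 (in frame only for phase 2, whatever the
    length); the branch point CTAAC at the canonical S2 = 1 spacing and the
    acceptor TAG place stops whose frame depends on length class.
    """
    rows = []
    for phase, cls in product((0, 1, 2), range(3)):
        f = first_inframe_start(phase)
        rows.append(
            {
                "phase": phase,
                "length_class": LENGTH_CLASS_LABELS[cls],
                "five_ss_GTGAGT": phase == 2,
                "five_ss_GTAAGT": phase == 2,
                "bp_CTAAC_s2_1": bp_stop_in_frame(phase, cls, 1),
                "three_ss_TAG": (cls + 1) % 3 == f % 3,
            }
        )
    return pd.DataFrame(rows).set_index(["phase", "length_class"])


# ---------------------------------------------------------------------------
# Stop-free null model

def stopfree_probability(length_codons: int, null: NullModel | None = None) -> float:
    """Probability that a string of ``length_codons`` unconstrained codons
    contains no stop: (1 - p_stop)^length."""
    if length_codons < 0:
        raise ValueError("codon-string length must be nonnegative")
    null = null or NullModel()
    return (1.0 - null.stop_probability_per_codon) ** length_codons


def largest_stopfree_length(
    threshold: float = 0.05, null: NullModel | None = None, max_codons: int = 100_000
) -> int:
    """Largest codon-string length whose stop-free probability stays >= threshold."""
    null = null or NullModel()
    q = 1.0 - null.stop_probability_per_codon
    if not 0.0 < q < 1.0:
        raise ValueError("stop probability must lie strictly in (0, 1)")
    p, length = 1.0, 0
    while length < max_codons:
        if p * q < threshold:
            return length
        p *= q
        length += 1
    raise RuntimeError("threshold not reached within max_codons")


def usable_codons(intron: Intron) -> int:
    """Number of fully-intronic in-frame codons of a retained CDS intron."""
    if intron.phase is None:
        raise ValueError("usable codons are defined for CDS introns only")
    return (intron.length_nt - ((3 - intron.phase) % 3)) // 3


def stop_content_summary(
    introns: Iterable[Intron],
    null: NullModel | None = None,
    max_length: int | None = 186,
    bin_width: int = 20,
    start: int = 41,
) -> pd.DataFrame:
    """Observed vs expected stop-containing fractions per (class, length-bin).

    Expected fraction for each intron is ``1 - stopfree_probability(c)`` with
    ``c`` its count of fully-intronic in-frame codons; cell expectations are
    means over member introns.  The comparison is restricted to introns
    shorter than ``max_length`` nucleotides (pass ``None`` for no restriction).
    """
    null = null or NullModel()
    rows = []
    for intron in introns:
        if intron.compartment != CDS:
            continue
        if max_length is not None and intron.length_nt >= max_length:
            continue
        outcome = scan_retained_stops(intron)
        rows.append(
            {
                "length_class": LENGTH_CLASS_LABELS[intron.length_class],
                "length_bin": f"{start + (intron.length_nt - start) // bin_width * bin_width}"
                if intron.length_nt >= start
                else f"<{start}",
                "has_stop": not outcome.stop_free,
                "expected": 1.0 - stopfree_probability(usable_codons(intron), null),
            }
        )
    if not rows:
        raise ValueError("no CDS introns to summarize")
    frame = pd.DataFrame(rows)
    grouped = frame.groupby(["length_class", "length_bin"]).agg(
        n=("has_stop", "size"),
        observed_fraction=("has_stop", "mean"),
        expected_fraction=("expected", "mean"),
    )
    return grouped.reset_index()


def stopfree_catalog(introns: Iterable[Intron]) -> CountTable:
    """Counts of stop-free introns over the 9 (phase, length-class) cells."""
    cells = {(phase, cls): 0 for phase in (0, 1, 2) for cls in range(3)}
    for intron in introns:
        if intron.compartment != CDS:
            continue
        if scan_retained_stops(intron).stop_free:
            cells[(intron.phase, intron.length_class)] += 1
    labels = tuple(
        (phase, LENGTH_CLASS_LABELS[cls]) for phase in (0, 1, 2) for cls in range(3)
    )
    counts = tuple(cells[(phase, cls)] for phase in (0, 1, 2) for cls in range(3))
    return CountTable(labels=labels, counts=counts)


def catalog_frame(catalog: CountTable) -> pd.DataFrame:
    """Pivot a 9-cell (phase, class) catalog into a 3x3 table."""
    frame = pd.DataFrame(
        {"phase": [p for p, _ in catalog.labels],
         "length_class": [c for _, c in catalog.labels],
         "count": list(catalog.counts)}
    )
    return frame.pivot(index="phase", columns="length_class", values="count")


# ---------------------------------------------------------------------------
# Per-intron outcome table and motif attribution summary

def outcome_table(introns: Iterable[Intron], bp_window: int = 60) -> pd.DataFrame:
    """Per-intron retention outcomes with motif attributions."""
    rows = []
    for intron in introns:
        if intron.compartment != CDS:
            continue
        outcome = attribute_stops(
            scan_retained_stops(intron), detect_signals(intron, bp_window=bp_window)
        )
        labels = sorted({label for attr in outcome.attributions or () for label in attr})
        rows.append(
            {
                "gene_id": intron.gene_id,
                "ordinal": intron.ordinal,
                "length": intron.length_nt,
                "phase": intron.phase,
                "length_class": LENGTH_CLASS_LABELS[intron.length_class],
                "frameshifting": outcome.frameshifting,
                "n_stops": len(outcome.stop_positions),
                "first_stop_pos": outcome.stop_positions[0]
                if outcome.stop_positions
                else None,
                "first_stop_codon": outcome.first_stop_codon,
                "attributions": ",".join(labels),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["first_stop_pos"] = frame["first_stop_pos"].astype("Int64")
    return frame


def attribution_summary(
    introns: Iterable[Intron], bp_window: int = 60
) -> dict[str, int]:
    """Counts of introns and stops attributed to each conserved motif.

    Intron-level counts tally introns with at least one stop overlapping the
    motif; an intron can appear under several motifs.  Stop-level counts are
    also reported because the fraction "of stop codons" and the fraction "of
    stop-containing introns" attributable to motifs differ.
    """
    counts = {
        "introns": 0,
        "stop_containing_introns": 0,
        f"introns_{FIVE_SS}": 0,
        f"introns_{BP}": 0,
        f"introns_{THREE_SS}": 0,
        "introns_motif_any": 0,
        "introns_other_only": 0,
        "stops_total": 0,
        "stops_motif": 0,
    }
    for intron in introns:
        if intron.compartment != CDS:
            continue
        counts["introns"] += 1
        outcome = attribute_stops(
            scan_retained_stops(intron), detect_signals(intron, bp_window=bp_window)
        )
        if outcome.stop_free:
            continue
        counts["stop_containing_introns"] += 1
        seen = set()
        for attr in outcome.attributions:
            seen |= attr
            counts["stops_total"] += 1
            if attr & {FIVE_SS, BP, THREE_SS}:
                counts["stops_motif"] += 1
        for motif in (FIVE_SS, BP, THREE_SS):
            if motif in seen:
                counts[f"introns_{motif}"] += 1
        if seen & {FIVE_SS, BP, THREE_SS}:
            counts["introns_motif_any"] += 1
        else:
            counts["introns_other_only"] += 1
    return counts
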
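"""Splice-signal detection and motif summaries.

The donor (5'ss) is taken as the first six intron nucleotides and the acceptor
(3'ss) as the last three.  The branch point is located by searching for the
exact pentamer CTAAC in a window immediately upstream of the acceptor trimer,
falling back to the degenerate pattern CT(A|G)AC; the rightmost match wins by
default because in genomes with a combined BP-3'ss element the branch point
sits next to the acceptor.  S1 is the number of nucleotides between the donor
hexamer and the branch-point motif, S2 the number between the branch-point
motif and the acceptor trimer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_io import Intron

BP_EXACT = "CTAAC"
_BP_DEGENERATE = re.compile(r"(?=(CT[AG]AC))")
_CANONICAL_3SS = re.compile(r"[CT]AG")

BASES = "ACGT"


@dataclass(frozen=True)
class SpliceSignals:
    """Detected splice signals of one intron (positions are intron-relative, 1-based)."""

    five_ss: str
    three_ss: str
    bp_motif: str | None
    bp_start: int | None
    s1_nt: int | None
    s2_nt: int | None
    bp_degenerate: bool
    canonical_3ss: bool

    def __post_init__(self) -> None:
        if len(self.five_ss) != 6 or len(self.three_ss) != 3:
            raise ValueError("five_ss must be 6 nt and three_ss 3 nt")
        if self.bp_motif is not None and self.s2_nt is not None and self.s2_nt < 0:
            raise ValueError("branch point must lie upstream of the acceptor trimer")

    @property
    def bp_end(self) -> int | None:
        if self.bp_start is None:
            return None
        return self.bp_start + len(self.bp_motif) - 1


def detect_signals(intron, bp_window: int = 60, tie: str = "rightmost") -> SpliceSignals:
    """Detect 5'ss, branch point and 3'ss in one intron (or raw sequence).

    The branch-point search window covers ``bp_window`` nucleotides upstream of
    the acceptor trimer; a candidate motif must lie wholly inside the window.
    If no exact CTAAC is found, the rightmost (or leftmost, per ``tie``)
    degenerate CT(A|G)AC match is used and ``bp_degenerate`` is set; if that
    also fails the branch-point fields are ``None`` with ``bp_degenerate``
    still true.
    """
    seq = intron.sequence if isinstance(intron, Intron) else str(intron)
    length = len(seq)
    if length < 15:
        raise ValueError(f"intron of {length} nt is too short for signal detection")
    if tie not in {"rightmost", "leftmost"}:
        raise ValueError("tie must be 'rightmost' or 'leftmost'")

    five_ss = seq[:6]
    three_ss = seq[-3:]

    lo0 = max(0, length - 3 - bp_window)  # 0-based window start
    region = seq[lo0 : length - 3]

    bp_start: int | None = None
    bp_motif: str | None = None
    degenerate = False
    idx = region.rfind(BP_EXACT) if tie == "rightmost" else region.find(BP_EXACT)
    if idx >= 0:
        bp_start = lo0 + idx + 1
    else:
        degenerate = True
        matches = [m.start(1) for m in _BP_DEGENERATE.finditer(region)]
        if matches:
            pos = matches[-1] if tie == "rightmost" else matches[0]
            bp_start = lo0 + pos + 1
    if bp_start is not None:
        bp_motif = seq[bp_start - 1 : bp_start + 4]

    s1 = bp_start - 7 if bp_start is not None else None
    s2 = length - bp_start - 7 if bp_start is not None else None

    return SpliceSignals(
        five_ss=five_ss,
        three_ss=three_ss,
        bp_motif=bp_motif,
        bp_start=bp_start,
        s1_nt=s1,
        s2_nt=s2,
        bp_degenerate=degenerate,
        canonical_3ss=bool(_CANONICAL_3SS.fullmatch(three_ss)),
    )


# ---------------------------------------------------------------------------
# Position probability matrices

@dataclass(frozen=True)
class PositionMatrix:
    """Per-position probabilities over A, C, G, T for a fixed-width window."""

    probs: np.ndarray  # shape (W, 4), rows sum to 1
    n: int

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probs.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.probs, columns=list(BASES))
        frame.index = pd.RangeIndex(1, self.width + 1, name="position")
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_pwm(sequences: Iterable[str]) -> PositionMatrix:
    """Position probability matrix from equal-length ACGT strings."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot build a PWM from zero sequences")
    width = len(seqs[0])
    index = {b: j for j, b in enumerate(BASES)}
    counts = np.zeros((width, 4), dtype=float)
    for seq in seqs:
        if len(seq) != width:
            raise ValueError(
                f"sequence length mismatch: expected {width}, got {len(seq)}"
            )
        for pos, base in enumerate(seq):
            try:
                counts[pos, index[base]] += 1
            except KeyError:
                raise ValueError(f"non-ACGT letter {base!r} in PWM input") from None
    return PositionMatrix(probs=counts / len(seqs), n=len(seqs))


# ---------------------------------------------------------------------------
# Motif frequency tables

def _frequency_frame(motifs: list[str]) -> pd.DataFrame:
    series = pd.Series(motifs, dtype=str).value_counts()
    frame = series.rename_axis("motif").reset_index(name="count")
    frame["fraction"] = frame["count"] / frame["count"].sum()
    return frame.sort_values(["count", "motif"], ascending=[False, True]).reset_index(
        drop=True
    )


def motif_frequency_table(introns: Iterable[Intron]) -> dict[str, pd.DataFrame]:
    """Count/fraction tables of 5'ss hexamers and 3'ss trimers.

    Fractions sum to 1 within each table.
    """
    introns = list(introns)
    if not introns:
        raise ValueError("motif_frequency_table requires at least one intron")
    fives, threes = [], []
    for intron in introns:
        signals = detect_signals(intron)
        fives.append(signals.five_ss)
        threes.append(signals.three_ss)
    return {"five_ss": _frequency_frame(fives), "three_ss": _frequency_frame(threes)}


def signals_table(introns: Iterable[Intron], bp_window: int = 60) -> pd.DataFrame:
    """Per-intron table of detected splice signals."""
    rows = []
    for intron in introns:
        sig = detect_signals(intron, bp_window=bp_window)
        rows.append(
            {
                "gene_id": intron.gene_id,
                "ordinal": intron.ordinal,
                "compartment": intron.compartment,
                "length": intron.length_nt,
                "phase": intron.phase,
                "five_ss": sig.five_ss,
                "bp_motif": sig.bp_motif,
                "bp_start": sig.bp_start,
                "s1_nt": sig.s1_nt,
                "s2_nt": sig.s2_nt,
                "bp_degenerate": sig.bp_degenerate,
                "three_ss": sig.three_ss,
                "canonical_3ss": sig.canonical_3ss,
            }
        )
    frame = pd.DataFrame(rows)
    for col in ("phase", "bp_start", "s1_nt", "s2_nt"):
        if col in frame:
            frame[col] = frame[col].astype("Int64")
    return frame
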
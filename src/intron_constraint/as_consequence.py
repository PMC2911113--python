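"""Protein-level consequences of alternative-splicing events.

Builds mature-mRNA variants from splice events (intron retention, exon
skipping, alternative 5'/3' splice sites, alternative transcription start)
and predicts protein length, PTC presence and position by translating the
variant from its start codon.  The mRNA modelled here is the coding region
(concatenated coding exons); an alternative TSS re-anchors the transcript's
5' end at a genomic coordinate and translation then starts at the first
downstream AUG.

Codons straddling an exon/intron junction under retention are handled here
naturally, because the full variant transcript is translated; this
complements the intron-internal scan of :mod:`intron_constraint.ptc_analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome_io import GeneModel, reverse_complement

RETENTION = "retention"
EXON_SKIP = "exon_skip"
ALT5SS = "alt5ss"
ALT3SS = "alt3ss"
ALT_TSS = "alt_tss"

_KINDS = {RETENTION, EXON_SKIP, ALT5SS, ALT3SS, ALT_TSS}


class EventError(ValueError):
    """Invalid or mutually incompatible splice events."""


@dataclass(frozen=True)
class SpliceEvent:
    """One splice event on a gene model.

    ``target`` is the intron ordinal (retention/alt5ss/alt3ss) or exon ordinal
    (exon_skip), both in transcript order.  ``offset_nt`` is the number of
    intron nucleotides transferred to the flanking exon for alt5ss/alt3ss
    (negative values shorten the exon instead), or the new genomic start
    coordinate for alt_tss.
    """

    kind: str
    target: int = 0
    offset_nt: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise EventError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class VariantProtein:
    length_aa: int
    has_ptc: bool
    ptc_codon_index: int | None
    frame_preserving: bool | None = None
    stop_found: bool = True


# ---------------------------------------------------------------------------
# Transcript assembly

@dataclass(frozen=True)
class _Piece:
    kind: str  # "exon" | "intron"
    index: int  # 1-based ordinal in transcript order
    gstart: int
    gend: int


def _transcript_pieces(gene: GeneModel) -> list[_Piece]:
    exons = list(gene.coding_exons)
    introns = [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    if gene.strand == "-":
        exons = exons[::-1]
        introns = introns[::-1]
    pieces: list[_Piece] = []
    for i, (s, e) in enumerate(exons, start=1):
        pieces.append(_Piece("exon", i, s, e))
        if i <= len(introns):
            ivl = introns[i - 1]
            pieces.append(_Piece("intron", i, ivl[0], ivl[1]))
    return pieces


def _piece_seq(piece: _Piece, chrom: str, strand: str) -> str:
    seq = chrom[piece.gstart - 1 : piece.gend]
    return reverse_complement(seq) if strand == "-" else seq


def apply_event(
    gene: GeneModel, events: Sequence[SpliceEvent], sequences: Mapping[str, str]
) -> tuple[str, int]:
    """Build the mature mRNA of a variant and return (mRNA, start offset).

    With no events the mRNA equals the annotated spliced coding sequence and
    the start offset is 0.  Events must be mutually compatible: at most one
    per intron or exon, skipping the first or last coding exon is unsupported,
    and retention cannot be combined with alternative splice-site usage on the
    same intron.  The start offset is 0-based.
    """
    chrom = sequences[gene.chromosome]
    pieces = _transcript_pieces(gene)
    n_exons = len(gene.coding_exons)
    n_introns = n_exons - 1

    intron_mode: dict[int, SpliceEvent] = {}
    skipped: set[int] = set()
    tss_event: SpliceEvent | None = None
    for event in events:
        if event.kind == ALT_TSS:
            if tss_event is not None:
                raise EventError("at most one alternative-TSS event per variant")
            tss_event = event
            continue
        if event.kind == EXON_SKIP:
            if not 1 <= event.target <= n_exons:
                raise EventError(f"exon ordinal {event.target} out of range")
            if event.target in (1, n_exons):
                raise EventError("skipping the first or last coding exon is unsupported")
            if event.target in skipped:
                raise EventError(f"duplicate skip of exon {event.target}")
            skipped.add(event.target)
            continue
        if not 1 <= event.target <= n_introns:
            raise EventError(f"intron ordinal {event.target} out of range")
        if event.target in intron_mode:
            raise EventError(
                f"incompatible events on intron {event.target}: "
                f"{intron_mode[event.target].kind} and {event.kind}"
            )
        intron_mode[event.target] = event

    intron_lengths = {
        p.index: p.gend - p.gstart + 1 for p in pieces if p.kind == "intron"
    }
    for ordinal, event in intron_mode.items():
        if event.kind in (ALT5SS, ALT3SS) and abs(event.offset_nt) > intron_lengths[ordinal]:
            raise EventError(
                f"{event.kind} offset {event.offset_nt} exceeds intron "
                f"{ordinal} length {intron_lengths[ordinal]}"
            )

    parts: list[str] = []
    for pos, piece in enumerate(pieces):
        seq = _piece_seq(piece, chrom, gene.strand)
        if piece.kind == "exon":
            if piece.index in skipped:
                continue
            # alternative splice sites trim the exon when offsets are negative
            up_intron = pieces[pos - 1] if pos > 0 else None
            down_intron = pieces[pos + 1] if pos + 1 < len(pieces) else None
            if up_intron is not None:
                ev = intron_mode.get(up_intron.index)
                if ev is not None and ev.kind == ALT3SS and ev.offset_nt < 0:
                    seq = seq[-ev.offset_nt :]
            if down_intron is not None:
                ev = intron_mode.get(down_intron.index)
                if ev is not None and ev.kind == ALT5SS and ev.offset_nt < 0:
                    seq = seq[: ev.offset_nt]
            parts.append(seq)
        else:
            ev = intron_mode.get(piece.index)
            if ev is None:
                continue
            if ev.kind == RETENTION:
                parts.append(seq)
            elif ev.kind == ALT5SS and ev.offset_nt > 0:
                parts.append(seq[: ev.offset_nt])
            elif ev.kind == ALT3SS and ev.offset_nt > 0:
                parts.append(seq[-ev.offset_nt :])

    mrna = "".join(parts)
    start_offset = 0

    if tss_event is not None:
        mrna, start_offset = _apply_alt_tss(gene, tss_event, chrom, pieces, intron_mode, skipped)
    return mrna, start_offset


def _apply_alt_tss(gene, event, chrom, pieces, intron_mode, skipped) -> tuple[str, int]:
    """Re-anchor the transcript 5' end at a genomic coordinate.

    Pieces wholly upstream of the new TSS are dropped; a piece containing the
    TSS is clipped.  If the TSS falls inside an intron, the intron's remainder
    is carried into the transcript (its donor site is gone).  Translation
    starts at the first downstream AUG.
    """
    tss = event.offset_nt
    lo, hi = gene.span
    if not lo <= tss <= hi:
        raise EventError(f"alt_tss coordinate {tss} outside gene span ({lo},{hi})")

    parts: list[str] = []
    started = False
    for pos, piece in enumerate(pieces):
        if gene.strand == "+":
            upstream_of_tss = piece.gend < tss
            contains = piece.gstart <= tss <= piece.gend
            clipped = (tss, piece.gend)
        else:
            upstream_of_tss = piece.gstart > tss
            contains = piece.gstart <= tss <= piece.gend
            clipped = (piece.gstart, tss)
        if not started:
            if upstream_of_tss:
                continue
            if contains:
                started = True
                clipped_piece = _Piece(piece.kind, piece.index, clipped[0], clipped[1])
                parts.append(_piece_seq(clipped_piece, chrom, gene.strand))
                continue
            started = True  # TSS fell in an intergenic gap inside the span
        if piece.kind == "exon":
            if piece.index in skipped:
                continue
            parts.append(_piece_seq(piece, chrom, gene.strand))
        else:
            ev = intron_mode.get(piece.index)
            if ev is not None and ev.kind == RETENTION:
                parts.append(_piece_seq(piece, chrom, gene.strand))
    mrna = "".join(parts)
    start_offset = mrna.find("ATG")
    if start_offset < 0:
        raise EventError("no start codon downstream of the alternative TSS")
    return mrna, start_offset


# ---------------------------------------------------------------------------
# Translation

def predict_protein(
    mrna: str, start_offset: int = 0, annotated_length_aa: int | None = None
) -> VariantProtein:
    """Translate a variant mRNA from its start codon.

    Translation uses the standard nuclear code and terminates at the first
    in-frame stop; the reported length excludes the stop.  The transcript's
    final in-frame codon is the annotated terminator (the mRNA modelled here
    is the coding region), so the stop is premature (``has_ptc``) exactly
    when codons remain downstream of it.  A transcript with no in-frame stop
    before the sequence end is flagged (``stop_found=False``), not an error.
    """
    if mrna[start_offset : start_offset + 3] != "ATG":
        raise ValueError(f"no ATG at start offset {start_offset}")
    tail = mrna[start_offset:]
    tail = tail[: len(tail) // 3 * 3]
    protein = str(Seq(tail).translate())
    stop_index = protein.find("*")
    stop_found = stop_index >= 0
    length_aa = stop_index if stop_found else len(protein)
    has_ptc = stop_found and stop_index < len(protein) - 1
    if has_ptc and annotated_length_aa is not None and length_aa >= annotated_length_aa:
        # a stop at or beyond the annotated length is not premature
        has_ptc = False
    return VariantProtein(
        length_aa=length_aa,
        has_ptc=has_ptc,
        ptc_codon_index=length_aa + 1 if has_ptc else None,
        stop_found=stop_found,
    )


def annotated_protein_length(gene: GeneModel, sequences: Mapping[str, str]) -> int:
    """Protein length of the fully spliced annotated transcript."""
    mrna, offset = apply_event(gene, [], sequences)
    return predict_protein(mrna, offset).length_aa


# ---------------------------------------------------------------------------
# Reports

def consequence_report(
    gene: GeneModel,
    event_sets: Sequence[tuple[str, Sequence[SpliceEvent]]],
    sequences: Mapping[str, str],
) -> pd.DataFrame:
    """One row per variant: mRNA length, protein size, PTC flag and position.

    ``event_sets`` pairs a variant label with its events; an empty list yields
    the single fully-spliced row.  ``frame_preserving`` compares the variant's
    mRNA length with the annotated one and is undefined (None) for variants
    re-anchoring the TSS.
    """
    baseline_mrna, baseline_offset = apply_event(gene, [], sequences)
    baseline = predict_protein(baseline_mrna, baseline_offset)
    sets = list(event_sets) or [("fully_spliced", [])]

    rows = []
    for label, events in sets:
        mrna, offset = apply_event(gene, events, sequences)
        protein = predict_protein(mrna, offset, annotated_length_aa=baseline.length_aa)
        has_tss = any(e.kind == ALT_TSS for e in events)
        frame_preserving = (
            None if has_tss else (len(mrna) - len(baseline_mrna)) % 3 == 0
        )
        rows.append(
            {
                "variant": label,
                "events": ";".join(
                    f"{e.kind}:{e.target}"
                    + (f":{e.offset_nt:+d}" if e.kind in (ALT5SS, ALT3SS) else "")
                    + (f"@{e.offset_nt}" if e.kind == ALT_TSS else "")
                    for e in events
                )
                or "none",
                "mrna_nt": len(mrna),
                "protein_aa": protein.length_aa,
                "has_ptc": protein.has_ptc,
                "ptc_codon_index": protein.ptc_codon_index,
                "frame_preserving": frame_preserving,
                "stop_found": protein.stop_found,
            }
        )
    frame = pd.DataFrame(rows)
    frame["ptc_codon_index"] = frame["ptc_codon_index"].astype("Int64")
    return frame
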
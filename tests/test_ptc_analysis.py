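"""Retained-intron stop scanning, motif attribution and the stop-free null."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq

from intron_constraint import genome_io as gio
from intron_constraint import ptc_analysis as ptc
from intron_constraint import splice_motifs as sm


# ---------------------------------------------------------------------------
# Frame arithmetic

@pytest.mark.parametrize("phase,expected", [(0, 1), (1, 3), (2, 2)])
def test_first_inframe_start(phase, expected):
    assert ptc.first_inframe_start(phase) == expected


def test_first_inframe_start_rejects_bad_phase():
    with pytest.raises(ValueError):
        ptc.first_inframe_start(3)


# ---------------------------------------------------------------------------
# Stop scanning

def test_phase2_gtgagt_intron_has_stop_at_position_two(mk):
    intron = mk("GTGAGT" + "C" * 30 + "CTAACTCAG", phase=2)
    outcome = ptc.scan_retained_stops(intron)
    assert 2 in outcome.stop_positions
    assert outcome.first_stop_codon == "TGA"


def test_phase0_3n_intron_ending_tag_has_terminal_stop(mk):
    seq = "GTGAGT" + "C" * 33 + "TAG"  # 42 nt, 3n, no other stops
    intron = mk(seq, phase=0)
    outcome = ptc.scan_retained_stops(intron)
    assert outcome.stop_positions == (len(seq) - 2,)
    assert not outcome.frameshifting


def test_utr_intron_is_rejected(mk):
    with pytest.raises(ValueError):
        ptc.scan_retained_stops(mk("A" * 50, phase=None, compartment=gio.UTR5))


def test_scan_equals_brute_force_translation_oracle(mk):
    """Stops found by the scanner equal '*' positions from translating the
    phase-shifted sequence with the standard code (independent route)."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        length = int(rng.integers(15, 121))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        phase = int(rng.integers(0, 3))
        intron = mk(seq, phase=phase)
        outcome = ptc.scan_retained_stops(intron)

        first = ptc.first_inframe_start(phase)
        tail = seq[first - 1 :]
        tail = tail[: len(tail) // 3 * 3]
        protein = str(Seq(tail).translate())
        expected = tuple(first + 3 * i for i, aa in enumerate(protein) if aa == "*")
        assert outcome.stop_positions == expected


# ---------------------------------------------------------------------------
# Attribution

def test_bp_stop_attributed_for_phase0_3n2_intron(mk):
    # phase 0, length 3n+2, acceptor TAG after a 1-nt spacer: the TAA inside
    # CTAAC is in frame and overlaps the branch point
    seq = "GTCCCC" + "C" * 29 + "CTAAC" + "T" + "TAG"  # 44 nt
    assert len(seq) % 3 == 2
    intron = mk(seq, phase=0)
    outcome = ptc.attribute_stops(
        ptc.scan_retained_stops(intron), sm.detect_signals(intron)
    )
    bp_positions = [
        pos
        for pos, attr in zip(outcome.stop_positions, outcome.attributions)
        if ptc.BP in attr
    ]
    assert bp_positions == [len(seq) - 7]


def test_five_ss_stop_attributed_for_phase2_gtaagt(mk):
    intron = mk("GTAAGT" + "C" * 30 + "CTAACTCAG", phase=2)
    outcome = ptc.attribute_stops(
        ptc.scan_retained_stops(intron), sm.detect_signals(intron)
    )
    assert ptc.FIVE_SS in outcome.attributions[0]
    assert outcome.stop_positions[0] == 2


def test_mid_intron_stop_is_other(mk):
    seq = "GTCCCC" + "C" * 12 + "TAA" + "C" * 12 + "CTAAC" + "T" + "CAG"
    intron = mk(seq, phase=0)
    outcome = ptc.attribute_stops(
        ptc.scan_retained_stops(intron), sm.detect_signals(intron)
    )
    by_pos = dict(zip(outcome.stop_positions, outcome.attributions))
    assert by_pos[19] == frozenset({ptc.OTHER})


# ---------------------------------------------------------------------------
# Rule table

def test_rule_table_nine_cells():
    """The combinatorial motif rules over all phase x length-class cells."""
    table = ptc.rule_table()
    # donor hexamers create a stop only in phase 2, whatever the length class
    for cls in ("3n", "3n+1", "3n+2"):
        for phase in (0, 1, 2):
            assert table.loc[(phase, cls), "five_ss_GTGAGT"] == (phase == 2)
            assert table.loc[(phase, cls), "five_ss_GTAAGT"] == (phase == 2)
    # branch point at S2 = 1: (0, 3n+2), (1, 3n+1), (2, 3n)
    bp_true = {(0, "3n+2"), (1, "3n+1"), (2, "3n")}
    # acceptor TAG: (0, 3n), (1, 3n+2), (2, 3n+1)
    tag_true = {(0, "3n"), (1, "3n+2"), (2, "3n+1")}
    for cell in product((0, 1, 2), ("3n", "3n+1", "3n+2")):
        assert table.loc[cell, "bp_CTAAC_s2_1"] == (cell in bp_true)
        assert table.loc[cell, "three_ss_TAG"] == (cell in tag_true)


def test_rule_table_is_implied_by_scanning_motif_bearing_introns(mk):
    """Construct one motif-bearing intron per cell (C-filled elsewhere) and
    check the scanner finds a stop at the motif exactly when the table says."""
    table = ptc.rule_table()
    for phase, cls in product((0, 1, 2), range(3)):
        length = 36 + cls  # keeps the class while staying comfortably long
        label = ("3n", "3n+1", "3n+2")[cls]

        for motif in ("GTGAGT", "GTAAGT"):
            seq = motif + "C" * (length - 9) + "CAG"
            stops = ptc.scan_retained_stops(mk(seq, phase=phase)).stop_positions
            assert (2 in stops) == table.loc[(phase, label), f"five_ss_{motif}"]

        seq = "GTCCCC" + "C" * (length - 15) + "CTAAC" + "T" + "CAG"  # S2 = 1
        stops = ptc.scan_retained_stops(mk(seq, phase=phase)).stop_positions
        assert (length - 7 in stops) == table.loc[(phase, label), "bp_CTAAC_s2_1"]

        seq = "GTCCCC" + "C" * (length - 9) + "TAG"
        stops = ptc.scan_retained_stops(mk(seq, phase=phase)).stop_positions
        assert (length - 2 in stops) == table.loc[(phase, label), "three_ss_TAG"]


def test_bp_stop_in_frame_generalizes_over_s2():
    # the YRA1-like geometry: S2 = 3 shifts the in-frame cells by one class
    assert ptc.bp_stop_in_frame(0, 2, 1)
    assert not ptc.bp_stop_in_frame(0, 2, 2)
    assert ptc.bp_stop_in_frame(0, 0, 2)


# ---------------------------------------------------------------------------
# Stop-free null model

def test_stopfree_probability_single_codon():
    assert ptc.stopfree_probability(1) == pytest.approx(61 / 64)


def test_stopfree_probability_matches_exhaustive_enumeration():
    """Closed form vs brute-force counting over all codon strings (L <= 3)."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["".join(c) for c in product("ACGT", repeat=3)]
    non_stop = sum(1 for c in codons if c not in stops)
    for length in (0, 1, 2, 3):
        expected = (non_stop / 64) ** length
        assert ptc.stopfree_probability(length) == pytest.approx(expected, abs=1e-12)


def test_stopfree_probability_strictly_decreasing():
    values = [ptc.stopfree_probability(n) for n in range(0, 200, 10)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_largest_stopfree_length_uniform_null():
    assert ptc.largest_stopfree_length(threshold=0.05) == 62


def test_null_from_base_frequencies_uniform_recovers_3_of_64():
    import pandas as pd

    uniform = pd.DataFrame(
        0.25, index=[1, 2, 3], columns=list("ACGT")
    )
    null = ptc.null_from_base_frequencies(uniform)
    assert null.stop_probability_per_codon == pytest.approx(3 / 64)


# ---------------------------------------------------------------------------
# Stop-content summary and stop-free catalog

def test_stop_content_single_stop_containing_intron(mk):
    intron = mk("GTGAGT" + "C" * 12 + "TAA" + "C" * 12 + "CTAACTCAG", phase=0)
    summary = ptc.stop_content_summary([intron], max_length=None)
    assert summary["observed_fraction"].iloc[0] == pytest.approx(1.0)


def test_stop_content_random_introns_match_expected_curve(mk):
    """Uniform-random introns: observed stop-containing fraction within 3 SE
    of the closed-form expectation."""
    rng = np.random.default_rng(2024)
    introns = []
    for _ in range(500):
        length = int(rng.integers(60, 121))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        introns.append(mk(seq, phase=int(rng.integers(0, 3))))
    summary = ptc.stop_content_summary(introns, max_length=None)
    n = summary["n"].sum()
    observed = (summary["observed_fraction"] * summary["n"]).sum() / n
    expected = (summary["expected_fraction"] * summary["n"]).sum() / n
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) <= 3 * se


def test_stopfree_catalog_cells_and_conservation(mk, default_introns):
    free = mk("GTCCCC" + "C" * 30 + "CAG", phase=0)  # 3n, phase 0, no stops
    catalog = ptc.stopfree_catalog([free])
    frame = ptc.catalog_frame(catalog)
    assert frame.loc[0, "3n"] == 1
    assert catalog.total == 1

    assert ptc.stopfree_catalog([]).total == 0

    cds = [i for i in default_introns if i.compartment == gio.CDS]
    genome_catalog = ptc.stopfree_catalog(cds)
    n_with_stop = sum(
        1 for i in cds if ptc.scan_retained_stops(i).stop_positions
    )
    assert genome_catalog.total + n_with_stop == len(cds)


def test_attribution_summary_counts_are_consistent(default_introns):
    cds = [i for i in default_introns if i.compartment == gio.CDS]
    counts = ptc.attribution_summary(cds)
    assert counts["introns"] == len(cds)
    assert (
        counts["introns_motif_any"] + counts["introns_other_only"]
        == counts["stop_containing_introns"]
    )
    assert counts["stops_motif"] <= counts["stops_total"]
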
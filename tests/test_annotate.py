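"""Candidate detection, greedy overlap resolution and positional classes."""

import numpy as np
import pytest

from helpers import exhaustive_resolution, random_candidates, random_proteome
from lcrscape.annotate import (
    LCRegion,
    ProteomeAnnotation,
    annotate_proteome,
    classify_position,
    detect_lcrs,
    position_metrics,
    resolve_overlaps,
)
from lcrscape.entropy import ProteinRecord, ProteomeScan, build_calibration
from lcrscape.simulate import SyntheticConfig, generate_proteome


def region(start, end, z=-1.0, pid="P1"):
    return LCRegion(protein_id=pid, start=start, end=end, H=1.0, Z=z)


class TestResolveOverlaps:
    def test_most_extreme_z_wins(self):
        a = region(10, 40, -3.0)
        b = region(30, 60, -5.0)
        assert resolve_overlaps([a, b]) == [b]

    def test_disjoint_candidates_both_retained(self):
        a = region(10, 40, -3.0)
        b = region(50, 60, -5.0)
        assert resolve_overlaps([a, b]) == [a, b]

    def test_chain_keeps_single_best(self):
        a = region(10, 40, -4.0)
        b = region(35, 70, -6.0)
        c = region(65, 90, -5.0)
        resolved = resolve_overlaps([a, b, c])
        assert resolved == [b]
        assert resolved == exhaustive_resolution([a, b, c])

    def test_literal_z_retains_most_positive(self):
        a = region(10, 40, -3.0)
        b = region(30, 60, -5.0)
        assert resolve_overlaps([a, b], literal_z=True) == [a]

    def test_tie_breaking_longer_then_leftmost(self):
        short = region(10, 20, -4.0)
        long = region(15, 40, -4.0)
        assert resolve_overlaps([short, long]) == [long]
        left = region(10, 20, -4.0)
        right = region(12, 22, -4.0)
        assert resolve_overlaps([left, right]) == [left]

    def test_idempotent(self, rng):
        cands = random_candidates(rng, 8)
        once = resolve_overlaps(cands)
        assert resolve_overlaps(once) == once

    def test_rejects_mixed_proteins(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            resolve_overlaps([region(1, 5, -1, "A"), region(1, 5, -1, "B")])

    def test_matches_exhaustive_search(self, rng):
        """Greedy equals enumeration over all disjoint subsets, with ties."""
        for _ in range(60):
            cands = random_candidates(rng, int(rng.integers(1, 11)))
            assert resolve_overlaps(cands) == exhaustive_resolution(cands)


class TestPositionMetrics:
    def test_normalised_centre(self):
        centre, folded = position_metrics(region(1, 21), 100)
        assert centre == pytest.approx(0.11)
        assert folded == pytest.approx(0.11)

    def test_whole_protein_folds_to_centre(self):
        L = 100
        centre, folded = position_metrics(region(1, L), L)
        assert centre == pytest.approx((1 + L) / (2 * L))
        assert folded == pytest.approx(0.5, abs=1 / (2 * L) + 1e-12)

    def test_folding_is_symmetric(self):
        _, folded = position_metrics(region(171, 189), 200)  # centre 0.9
        assert folded == pytest.approx(0.1)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            position_metrics(region(90, 120), 100)


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "start,end,L,expected",
        [
            (10, 40, 500, "terminal"),  # 9 aa from the N-terminus
            (60, 120, 500, "central"),  # margins 59 and 380
            (31, 170, 200, "intermediate"),  # margins 30 and 30: buffer zone
            (26, 100, 500, "terminal"),  # N-margin exactly 25 counts as terminal
            (51, 450, 500, "central"),  # both margins exactly 50
        ],
    )
    def test_examples(self, start, end, L, expected):
        assert classify_position(region(start, end), L) == expected

    def test_exhaustive_and_exclusive(self, rng):
        classes = set()
        for _ in range(300):
            L = int(rng.integers(60, 400))
            s = int(rng.integers(1, L))
            e = int(rng.integers(s, L + 1))
            cls = classify_position(region(s, e), L)
            assert cls in {"terminal", "central", "intermediate"}
            classes.add(cls)
        assert classes == {"terminal", "central", "intermediate"}


def test_single_lcr_filter_counts():
    lengths = {f"P{i}": 200 for i in range(6)}
    regions = {
        "P0": [],  # zero LCRs
        "P1": [region(1, 20, -3, "P1")],
        "P2": [region(1, 20, -3, "P2"), region(100, 130, -4, "P2")],
        "P3": [region(5, 30, -2, "P3")],
    }
    ann = ProteomeAnnotation(regions=regions, protein_lengths=lengths)
    assert ann.n_proteins == 6
    assert ann.n_with_lcr == 3
    assert ann.n_single_lcr == 2
    single = ann.single_lcr_filter()
    assert set(single.regions) == {"P1", "P3"}
    assert single.n_single_lcr == 2


def test_homopolymer_run_yields_candidates(rng):
    """A 40-aa poly-A run inside a random protein must produce candidates
    entirely inside the run (H = 0 beats any non-degenerate threshold)."""
    proteome = random_proteome(rng, 40, 300, 400)
    seq = proteome[0].sequence
    planted = seq[:150] + "A" * 40 + seq[190:]
    proteome[0] = ProteinRecord(id="P0000", sequence=planted)
    cal = build_calibration(proteome, windows=range(16, 41))
    cands = detect_lcrs(proteome, cal, windows=range(16, 41))
    inside = [
        c for c in cands if c.protein_id == "P0000" and c.start >= 151 and c.end <= 190
    ]
    assert inside, "no candidate window inside the planted run"
    for c in cands:
        assert c.H < cal.stats[c.length].t


def test_detection_skips_uncalibrated_windows(rng, caplog):
    proteome = random_proteome(rng, 20, 100, 150)
    cal = build_calibration(proteome, windows=[16])
    cands = detect_lcrs(proteome, cal, windows=[16, 300])
    assert all(c.length == 16 for c in cands)


def test_annotated_regions_disjoint_and_classified(rng):
    config = SyntheticConfig(
        seed=7, n_proteins=150, length_min=150, length_max=400,
        fraction_with_lcr=0.4, lcr_len_min=20, lcr_len_max=50,
    )
    proteome, _ = generate_proteome(config)
    ann = annotate_proteome(proteome, windows=range(16, 51))
    for pid, regs in ann.regions.items():
        for i, r in enumerate(regs):
            assert r.pos_class in {"terminal", "central", "intermediate"}
            assert 0.0 <= r.folded <= 0.5
            assert r.folded == pytest.approx(min(r.centre_norm, 1 - r.centre_norm))
            for other in regs[i + 1 :]:
                assert not r.overlaps(other)


def test_planted_run_recall(rng):
    """>= 95% of planted homopolymer runs of length >= 30 are recovered."""
    config = SyntheticConfig(
        seed=11, n_proteins=300, length_min=250, length_max=500,
        fraction_with_lcr=0.1, lcr_len_min=30, lcr_len_max=60,
        n_dominant_min=1, n_dominant_max=1, dominant_mass=1.0,
    )
    proteome, truth = generate_proteome(config)
    ann = annotate_proteome(proteome, windows=range(16, 61))
    recovered = 0
    for pid, planted in truth.planted.items():
        regs = ann.regions.get(pid, [])
        if any(r.start <= planted.end and planted.start <= r.end for r in regs):
            recovered += 1
    assert recovered / len(truth.planted) >= 0.95
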
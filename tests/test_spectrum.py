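"""Pileup building, per-position frequencies, and windowed spectrum statistics."""

import math

import numpy as np
import pytest

from deamtools.spectrum import (
    FrequencyProfile,
    PileupMatrix,
    background_subtract,
    build_pileup,
    detect_onset,
    fold_enrichment,
    mean_spb,
    moving_average,
    position_frequencies,
)
from deamtools.simulate import MutagenesisProfileConfig, simulate_reads


def make_pileup(ref, counts):
    return PileupMatrix(
        positions=np.arange(1, len(ref) + 1),
        ref=ref,
        counts=np.asarray(counts),
    )


class TestBuildPileup:
    def test_single_high_quality_read(self):
        reads = [(1, "ACGT", [40, 40, 40, 40])]
        p = build_pileup(reads, "ACGT", qmin=35)
        assert np.array_equal(p.counts, np.eye(4, dtype=int))
        assert np.array_equal(p.coverage, [1, 1, 1, 1])

    def test_low_quality_call_dropped(self):
        reads = [(1, "ACGT", [40, 30, 40, 40])]
        p = build_pileup(reads, "ACGT", qmin=35)
        assert p.coverage[1] == 0
        assert np.array_equal(p.coverage, [1, 0, 1, 1])

    def test_overhanging_read_trimmed_with_warning(self):
        reads = [(3, "GTAA", [40] * 4)]
        with pytest.warns(UserWarning, match="overhung"):
            p = build_pileup(reads, "ACGT", qmin=35)
        assert p.coverage[2] == 1 and p.coverage[3] == 1
        assert p.coverage.sum() == 2

    def test_read_order_permutation_invariant(self, rng):
        reads = [
            (1, "ACGT", [40, 40, 40, 40]),
            (2, "CGT", [40, 36, 40]),
            (1, "ACTT", [40, 40, 40, 40]),
        ]
        a = build_pileup(reads, "ACGT")
        b = build_pileup(reads[::-1], "ACGT")
        assert np.array_equal(a.counts, b.counts)

    def test_sam_roundtrip_with_indel_rejection(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:ref\tLN:4\n"
            "r0\t0\tref\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\n"
            "r1\t0\tref\t1\t255\t2M1I1M\t*\t0\t0\tACCG\tIIII\n"
        )
        with pytest.warns(UserWarning, match="indel"):
            p = build_pileup(str(sam), "ACGT", qmin=35)
        assert np.array_equal(p.counts, np.eye(4, dtype=int))

    def test_generator_bookkeeping_matches(self):
        cfg = MutagenesisProfileConfig(
            length=120,
            tss=30,
            coverage=60,
            error_rate=5e-3,
            q_below_fraction=0.2,
            plateau_rates={"C>T": 0.05, "A>G": 0.01, "T>C": 0.01},
            seed=11,
        )
        reads, expected, _ = simulate_reads(cfg, qmin=35)
        built = build_pileup(reads, expected.ref, qmin=35)
        assert np.array_equal(built.counts, expected.counts)


class TestFrequencies:
    def test_direct_formula(self):
        p = make_pileup("A", [[90, 0, 0, 10]])
        f = position_frequencies(p)
        assert f.freqs[0, 3] == pytest.approx(0.10)
        assert f.substitution_frequency("A>T")[0] == pytest.approx(0.10)

    def test_zero_coverage_masked(self):
        p = make_pileup("AC", [[0, 0, 0, 0], [1, 1, 1, 1]])
        f = position_frequencies(p)
        assert f.freqs[0].mask.all()
        assert np.allclose(f.freqs[1], 0.25)

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(0, 50, size=(30, 4))
        counts[5] = 0
        f = position_frequencies(make_pileup("ACGT" * 7 + "AC", counts))
        sums = f.freqs.sum(axis=1)
        covered = f.coverage > 0
        assert np.allclose(sums[covered], 1.0)

    def test_pseudocount_gives_finite_everywhere(self):
        p = make_pileup("AC", [[0, 0, 0, 0], [10, 0, 0, 0]])
        f = position_frequencies(p, pseudocount=True)
        assert not f.freqs.mask.any()
        assert f.freqs[0].sum() == pytest.approx(1.0)


class TestMovingAverage:
    def test_constant_profile_unchanged(self):
        sm = moving_average(np.full(50, 0.3), w=10, k=3)
        assert np.allclose(sm.trend.compressed(), 0.3)

    def test_single_outlier_excluded(self):
        vals = np.full(50, 1e-4)
        vals[25] = 0.5
        sm = moving_average(vals, w=10, k=3)
        assert np.allclose(sm.trend.compressed(), 1e-4)
        assert sm.n_excluded.max() == 1

    def test_linear_ramp_interior_equals_ramp(self):
        ramp = np.linspace(0.0, 1.0, 101)
        sm = moving_average(ramp, w=10, k=3)
        interior = slice(10, 91)
        assert np.allclose(sm.trend[interior], ramp[interior], atol=1e-12)

    def test_window_shrinks_at_edges(self):
        ramp = np.linspace(0.0, 1.0, 101)
        sm = moving_average(ramp, w=10, k=3)
        # edge window is one-sided: mean of first 11 values
        assert sm.trend[0] == pytest.approx(ramp[:11].mean())

    def test_small_window_masked(self):
        vals = np.ma.masked_all(5)
        vals[2] = 0.5
        sm = moving_average(vals, w=1, k=3)
        assert sm.trend.mask.all()

    def test_global_sd_flag_runs(self):
        vals = np.full(30, 1e-4)
        vals[10] = 0.4
        sm = moving_average(vals, w=10, k=3, global_sd=True)
        assert np.allclose(sm.trend.compressed(), 1e-4, atol=1e-6)


class TestWindowedStats:
    def test_mean_spb_over_matching_ref(self):
        p = make_pileup("CACG", [[0, 999, 0, 1], [100, 0, 0, 0], [0, 997, 0, 3], [0, 0, 100, 0]])
        f = position_frequencies(p)
        assert mean_spb(f, (1, 4), "C>T") == pytest.approx((0.001 + 0.003) / 2)

    def test_mean_spb_no_matching_ref_undefined(self):
        p = make_pileup("AG", [[100, 0, 0, 0], [0, 0, 100, 0]])
        f = position_frequencies(p)
        assert math.isnan(mean_spb(f, (1, 2), "C>T"))

    def test_fold_enrichment_self_is_identity(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 1000, size=(40, 4))
        f = position_frequencies(make_pileup("ACGT" * 10, counts))
        summary = fold_enrichment(f, f, (1, 40), offset=0)
        for sub, ratio in summary.fold.items():
            if not math.isnan(ratio):
                assert ratio == 1.0

    def test_fold_enrichment_known_ratio(self):
        t = position_frequencies(make_pileup("CC", [[0, 998, 0, 2], [0, 998, 0, 2]]))
        c = position_frequencies(
            make_pileup("CC", [[0, 99999, 0, 1], [0, 99999, 0, 1]])
        )
        summary = fold_enrichment(t, c, (1, 2), offset=0)
        assert summary.fold["C>T"] == pytest.approx(200.0)

    def test_offset_shifts_control_coordinates(self):
        # control position 1 must line up with target position 24 at offset 23
        t_counts = np.full((30, 4), 0)
        t_counts[:, 1] = 990
        t_counts[:, 3] = 10  # C>T at 1%
        t = position_frequencies(make_pileup("C" * 30, t_counts))
        c_counts = np.zeros((7, 4), dtype=int)
        c_counts[:, 1] = 999
        c_counts[:, 3] = 1  # 0.1%
        c = position_frequencies(make_pileup("C" * 7, c_counts))
        summary = fold_enrichment(t, c, (24, 30), offset=23)
        assert summary.fold["C>T"] == pytest.approx(10.0)

    def test_zero_control_undefined(self):
        t = position_frequencies(make_pileup("C", [[0, 99, 0, 1]]))
        c = position_frequencies(make_pileup("C", [[0, 100, 0, 0]]))
        summary = fold_enrichment(t, c, (1, 1), offset=0)
        assert math.isnan(summary.fold["C>T"])

    def test_background_subtract_identity_undefined(self):
        f = position_frequencies(make_pileup("C", [[0, 99, 0, 1]]))
        summary = background_subtract(f, f, (1, 1))
        assert summary.corrected["C>T"] == 0.0
        assert all(math.isnan(v) for v in summary.fractions.values())

    def test_background_subtract_fractions_normalize(self):
        # corrected {C>T: 3e-4, G>A: 1e-4, A>G: 1e-4, T>C: 1e-4} -> {0.5, 1/6, 1/6, 1/6}
        ref = "CGAT"
        t_counts = [
            [0, 100000 - 30, 0, 30],
            [10, 0, 100000 - 10, 0],
            [100000 - 10, 0, 10, 0],
            [0, 10, 0, 100000 - 10],
        ]
        t = position_frequencies(make_pileup(ref, t_counts))
        c_counts = [
            [0, 100000, 0, 0],
            [0, 0, 100000, 0],
            [100000, 0, 0, 0],
            [0, 0, 0, 100000],
        ]
        c = position_frequencies(make_pileup(ref, c_counts))
        summary = background_subtract(t, c, (1, 4))
        assert summary.fractions["C>T"] == pytest.approx(0.5)
        assert summary.fractions["G>A"] == pytest.approx(1 / 6)
        assert summary.fractions["A>G"] == pytest.approx(1 / 6)
        assert summary.fractions["T>C"] == pytest.approx(1 / 6)
        total = sum(v for v in summary.fractions.values() if not math.isnan(v))
        assert total == pytest.approx(1.0)
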
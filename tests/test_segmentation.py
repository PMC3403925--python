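"""CBS: breakpoint recovery, exhaustive-arc oracle agreement, calling rules."""

import itertools
import math

import numpy as np
import pytest

from wgaqc.segmentation import (
    call_cnv,
    cbs_segment,
    max_arc_statistic,
    smooth_profile,
)

from conftest import make_profile


def exhaustive_arc_oracle(x, min_width=2):
    """Brute-force max t-like arc statistic over all (i, j) pairs."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = np.std(x, ddof=1)
    best = (0.0, 0, n)
    for k in range(min_width, n - min_width + 1):
        for i in range(0, n - k + 1):
            arc = x[i : i + k]
            rest = np.concatenate([x[:i], x[i + k :]])
            t = abs(arc.mean() - rest.mean()) / (s * math.sqrt(1 / k + 1 / (n - k)))
            if t > best[0] + 1e-12:
                best = (t, i, i + k)
    return best


class TestArcStatistic:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        x = rng.normal(0, 1, n)
        fast = max_arc_statistic(x, min_width=2)
        slow = exhaustive_arc_oracle(x, min_width=2)
        assert fast[0] == pytest.approx(slow[0])
        assert fast[1:] == slow[1:]

    def test_step_profile_breakpoint(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        _, i, j = max_arc_statistic(x)
        assert {i, j} <= {0, 20, 40} and 20 in (i, j)


class TestCbsSegment:
    def test_constant_profile_single_segment(self):
        segs = cbs_segment(make_profile(np.full(60, 0.25)), n_permutations=100, seed=0)
        assert len(segs) == 1
        assert segs.segments.loc[0, "mean"] == pytest.approx(0.25)

    def test_noiseless_step_exact_breakpoint(self):
        prof = make_profile(np.concatenate([np.zeros(20), np.ones(20)]))
        segs = cbs_segment(prof, n_permutations=200, seed=0)
        df = segs.segments
        assert len(df) == 2
        assert df["last_probe"].tolist() == [19, 39]
        assert df["mean"].tolist() == pytest.approx([0.0, 1.0])

    def test_noisy_three_segment_recovery(self):
        rng = np.random.default_rng(42)
        truth = np.concatenate(
            [np.zeros(30), np.full(15, -1.2), np.zeros(25), np.full(12, 1.0), np.zeros(18)]
        )
        prof = make_profile(truth + rng.normal(0, 0.15, truth.size))
        segs = cbs_segment(prof, alpha=0.01, n_permutations=500, seed=1)
        breakpoints = set(segs.segments["last_probe"][:-1] + 1)
        for true_bp in (30, 45, 70, 82):
            assert any(abs(true_bp - bp) <= 1 for bp in breakpoints)

    def test_pure_noise_split_rate_bounded(self):
        rng = np.random.default_rng(3)
        alpha, n_chrom = 0.05, 40
        splits = 0
        for _ in range(n_chrom):
            prof = make_profile(rng.normal(0, 1, 50))
            segs = cbs_segment(prof, alpha=alpha, n_permutations=200, seed=0, undo_sd=0)
            splits += len(segs) > 1
        # binomial tolerance: alpha + 3 sd at n_chrom trials
        assert splits / n_chrom <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_chrom)

    def test_segments_tile_each_chromosome(self):
        rng = np.random.default_rng(17)
        values = rng.normal(0, 0.3, 160)
        values[40:60] -= 1.5
        prof = make_profile(values, chrom=["chr1"] * 80 + ["chr2"] * 80)
        df = cbs_segment(prof, n_permutations=100, seed=9).segments
        covered = []
        for row in df.itertuples():
            covered.extend(range(row.first_probe, row.last_probe + 1))
            assert row.n_probes == row.last_probe - row.first_probe + 1
        assert covered == list(range(len(prof)))
        # no segment spans a chromosome boundary
        chrom = prof.probes["chrom"].to_numpy()
        for row in df.itertuples():
            assert chrom[row.first_probe] == chrom[row.last_probe] == row.chrom

    def test_fixed_seed_determinism(self):
        rng = np.random.default_rng(5)
        prof = make_profile(rng.normal(0, 0.3, 120))
        a = cbs_segment(prof, n_permutations=150, seed=4).segments
        b = cbs_segment(prof, n_permutations=150, seed=4).segments
        assert a.equals(b)

    def test_short_chromosome_single_segment(self):
        prof = make_profile([0.0, 5.0, 0.0], chrom=["chr1"] * 3)
        segs = cbs_segment(prof, n_permutations=100, min_width=2, seed=0)
        assert len(segs) == 1

    def test_invalid_inputs_rejected(self):
        prof = make_profile(np.zeros(10))
        with pytest.raises(ValueError):
            cbs_segment(make_profile(np.zeros(10), smoothed=True))
        with pytest.raises(ValueError):
            cbs_segment(prof, alpha=1.5)
        with pytest.raises(ValueError):
            cbs_segment(prof, n_permutations=10)


class TestSmoothAndCall:
    def test_single_segment_smooths_to_global_mean(self):
        prof = make_profile(np.array([0.0, 1.0, 2.0, 3.0] * 10))
        segs = cbs_segment(prof, n_permutations=100, seed=0, undo_sd=2.0)
        if len(segs) == 1:
            sm = smooth_profile(prof, segs)
            assert np.allclose(sm.log2_ratio, prof.log2_ratio.mean())

    def test_two_level_step_profile(self):
        prof = make_profile(np.concatenate([np.zeros(20), np.ones(20)]))
        segs = cbs_segment(prof, n_permutations=200, seed=0)
        sm = smooth_profile(prof, segs)
        assert np.allclose(sm.log2_ratio[:20], 0.0)
        assert np.allclose(sm.log2_ratio[20:], 1.0)
        assert sm.smoothed

    def test_smoothing_noiseless_step_is_fixed_point(self):
        prof = make_profile(np.concatenate([np.zeros(20), np.ones(20)]))
        segs = cbs_segment(prof, n_permutations=200, seed=0)
        sm = smooth_profile(prof, segs)
        segs2 = cbs_segment(
            make_profile(sm.log2_ratio), n_permutations=200, seed=1
        )
        sm2 = smooth_profile(make_profile(sm.log2_ratio), segs2)
        assert np.allclose(sm.log2_ratio, sm2.log2_ratio)

    @pytest.mark.parametrize(
        "mean,cutoff,called", [(-1.3, 2.0, 1), (-1.3, 2.5, 0), (0.0, 2.0, 0)]
    )
    def test_call_cnv_fold_rule(self, mean, cutoff, called):
        sm = make_profile(np.full(10, mean), smoothed=True)
        calls = call_cnv(sm, fold_cutoff=cutoff)
        assert np.all(calls.calls == called)

    def test_call_requires_smoothed_and_valid_cutoff(self):
        with pytest.raises(ValueError):
            call_cnv(make_profile(np.zeros(5), smoothed=False))
        with pytest.raises(ValueError):
            call_cnv(make_profile(np.zeros(5), smoothed=True), fold_cutoff=1.0)
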
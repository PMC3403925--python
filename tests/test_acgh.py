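"""Ratio computation, DLRS, threshold tables, replicate combination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wgaqc.acgh import (
    combine_replicates,
    compute_log2_ratios,
    dlrs,
    fold_change,
    read_probe_table,
    threshold_table,
)
from wgaqc.simulate import BiasModel, simulate_hybridization

from conftest import make_profile


@pytest.fixture
def probe_tsv(tmp_path):
    path = tmp_path / "probes.tsv"
    path.write_text(
        "probe_id\tchrom\tstart\tend\ttest_intensity\tref_intensity\n"
        "P3\tchr1\t3000\t3060\t900\t1000\n"
        "P1\tchr1\t1000\t1060\t1100\t1000\n"
        "P2\tchr1\t2000\t2060\t1000\t1000\n"
        "P4\tchr2\t500\t560\t1000\t1000\n"
        "P5\tchr2\t1500\t1560\t1200\t1000\n"
    )
    return path


class TestReadProbeTable:
    def test_well_formed_table(self, probe_tsv):
        arr = read_probe_table(probe_tsv)
        assert len(arr) == 5

    def test_sorted_on_read(self, probe_tsv):
        arr = read_probe_table(probe_tsv)
        assert arr.probes["probe_id"].tolist() == ["P1", "P2", "P3", "P4", "P5"]

    def test_nonpositive_intensity_dropped_with_warning(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "probe_id\tchrom\tstart\tend\ttest_intensity\tref_intensity\n"
            "P1\tchr1\t0\t60\t100\t100\n"
            "P2\tchr1\t100\t160\t0\t100\n"
        )
        with pytest.warns(UserWarning, match="non-positive"):
            arr = read_probe_table(path)
        assert len(arr) == 1

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "missing.tsv"
        path.write_text("probe_id\tchrom\tstart\ttest_intensity\n" "P1\tchr1\t0\t100\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_probe_table(path)


class TestLog2Ratios:
    def test_equal_channels_give_zero(self, probe_tsv):
        arr = read_probe_table(probe_tsv)
        arr.test = arr.ref.copy()
        assert np.allclose(compute_log2_ratios(arr).log2_ratio, 0.0)

    def test_constant_doubling_without_normalization(self, probe_tsv):
        arr = read_probe_table(probe_tsv)
        arr.test = 2 * arr.ref
        assert np.allclose(compute_log2_ratios(arr, normalize=False).log2_ratio, 1.0)

    def test_constant_doubling_median_centered(self, probe_tsv):
        arr = read_probe_table(probe_tsv)
        arr.test = 2 * arr.ref
        assert np.allclose(compute_log2_ratios(arr, normalize=True).log2_ratio, 0.0)

    def test_normalization_idempotent(self, small_genome):
        arr = simulate_hybridization(small_genome, BiasModel(noise_sd=0.3), 8)
        once = compute_log2_ratios(arr, normalize=True)
        twice = once.log2_ratio - np.median(once.log2_ratio)
        assert np.allclose(once.log2_ratio, twice)


class TestFoldChange:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 2.0), (-1.0, 2.0), (0.585, 1.500), (0.0, 1.0)]
    )
    def test_known_values(self, r, expected):
        assert fold_change(r) == pytest.approx(expected, abs=1e-3)

    @given(st.floats(-10, 10))
    def test_symmetry(self, r):
        assert fold_change(r) == fold_change(-r)
        assert fold_change(r) >= 1.0


class TestDlrs:
    def test_constant_profile_zero(self):
        assert dlrs(make_profile([0.3] * 50)) == 0.0

    def test_iid_gaussian_sd_recovered(self):
        rng = np.random.default_rng(0)
        prof = make_profile(rng.normal(0, 0.165, size=100_000))
        assert 0.160 <= dlrs(prof) <= 0.170

    def test_alternating_profile_closed_form(self):
        # diffs alternate -0.2/+0.2: IQR of {-0.2, +0.2} spans 0.4
        prof = make_profile([0.1, -0.1] * 20)
        assert dlrs(prof) == pytest.approx(0.4 / (1.349 * np.sqrt(2)))

    def test_smoothed_profile_rejected(self):
        prof = make_profile(np.arange(10.0), smoothed=True)
        with pytest.raises(ValueError, match="raw"):
            dlrs(prof)

    def test_chromosome_boundaries_excluded(self):
        # A level shift between chromosomes must not inflate the estimate.
        values = np.concatenate([np.zeros(50), np.full(50, 5.0)])
        prof = make_profile(values, chrom=["chr1"] * 50 + ["chr2"] * 50)
        assert dlrs(prof) == 0.0


class TestThresholdTable:
    def test_all_zero_profiles(self):
        t = threshold_table([make_profile(np.zeros(100))])
        assert np.allclose(t.percentages, 0.0)

    def test_direct_count(self):
        values = np.zeros(1000)
        values[:10] = 1.1
        t = threshold_table([make_profile(values)], cutoffs=[2.0])
        assert t.percentages[0] == pytest.approx(1.000)

    def test_percentages_non_increasing(self, small_genome):
        arr = simulate_hybridization(small_genome, BiasModel(noise_sd=0.5), 3)
        t = threshold_table([compute_log2_ratios(arr)])
        assert np.all(np.diff(t.percentages) <= 0)

    def test_probe_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="probe set"):
            threshold_table([make_profile(np.zeros(10)), make_profile(np.zeros(11))])


class TestCombineReplicates:
    def test_identical_profiles_unchanged(self):
        prof = make_profile(np.linspace(-1, 1, 30))
        combined = combine_replicates([prof, prof, prof])
        assert np.allclose(combined.log2_ratio, prof.log2_ratio)

    def test_explicit_zero_weight_ignores_profile(self):
        a, b = make_profile(np.zeros(20)), make_profile(np.ones(20))
        combined = combine_replicates([a, b], weights=[1, 0])
        assert np.allclose(combined.log2_ratio, 0.0)

    def test_equal_weights_are_arithmetic_mean(self):
        a, b = make_profile(np.zeros(20)), make_profile(np.ones(20))
        combined = combine_replicates([a, b], weights=[1, 1])
        assert np.allclose(combined.log2_ratio, 0.5)

    def test_default_weights_favor_low_noise(self):
        rng = np.random.default_rng(1)
        quiet = make_profile(rng.normal(0, 0.05, 2000))
        loud = make_profile(rng.normal(1, 0.5, 2000))
        combined = combine_replicates([quiet, loud])
        # inverse-variance weights pull the mean toward the quiet profile
        assert combined.log2_ratio.mean() < 0.05

    def test_all_zero_weights_rejected(self):
        prof = make_profile(np.zeros(10))
        with pytest.raises(ValueError, match="weights"):
            combine_replicates([prof, prof], weights=[0, 0])
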
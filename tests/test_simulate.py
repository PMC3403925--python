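"""Generator behavior: determinism, bias linearity, noise calibration."""

import numpy as np
import pandas as pd
import pytest

from wgaqc.acgh import compute_log2_ratios, dlrs
from wgaqc.simulate import (
    BiasModel,
    GenomeConfig,
    simulate_bidirectional_reads,
    simulate_ct_table,
    simulate_genome,
    simulate_hybridization,
)
from wgaqc.simulate import expected_log2_ratio


class TestSimulateGenome:
    def test_seed_determinism(self):
        cfg = GenomeConfig(chromosomes=(("chr1", 50_000),))
        a = simulate_genome(cfg, seed=1)
        b = simulate_genome(cfg, seed=1)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.probes, b.probes)
        c = simulate_genome(cfg, seed=2)
        assert c.sequences != a.sequences

    def test_probe_gc_matches_sequence(self, small_genome):
        row = small_genome.probes.iloc[37]
        window = small_genome.sequences[row.chrom][row.start : row.end]
        assert row.gc == (window.count("G") + window.count("C")) / len(window)

    def test_all_gc_sequence_gives_probe_gc_one(self):
        g = simulate_genome(
            GenomeConfig(chromosomes=(("chr1", 20_000),), gc_mean=1.0, gc_block_sd=0.0),
            seed=0,
        )
        assert set(g.sequences["chr1"]) <= {"G", "C"}
        assert (g.probes["gc"] == 1.0).all()

    def test_probe_count_bounds_from_spacing(self):
        g = simulate_genome(
            GenomeConfig(chromosomes=(("chr1", 1_000_000),), spacing_range=(1000, 2000)),
            seed=3,
        )
        assert 500 <= len(g.probes) <= 1000

    def test_probes_sorted_and_within_chromosomes(self, small_genome):
        p = small_genome.probes
        lengths = small_genome.chromosome_lengths()
        assert (p["end"] <= p["chrom"].map(lengths)).all()
        for _, grp in p.groupby("chrom"):
            assert grp["start"].is_monotonic_increasing

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GenomeConfig(chromosomes=(("chr1", -5),))
        with pytest.raises(ValueError):
            GenomeConfig(chromosomes=(("chr1", 800),), spacing_range=(1000, 2000))


class TestSimulateHybridization:
    def test_zero_bias_zero_noise_gives_zero_ratios(self, small_genome):
        arr = simulate_hybridization(small_genome, BiasModel(), 0)
        r = np.log2(arr.test / arr.ref)
        assert np.allclose(r, 0.0)

    def test_cnv_segment_closed_form(self, small_genome):
        bias = BiasModel(cnv_segments=[("chr1", 10_000, 60_000, -1.585)])
        arr = simulate_hybridization(small_genome, bias, 0)
        r = np.log2(arr.test / arr.ref)
        mid = (arr.probes["start"] + arr.probes["end"]) / 2
        inside = (arr.probes["chrom"] == "chr1") & (mid >= 10_000) & (mid < 60_000)
        assert np.allclose(r[inside.to_numpy()], -1.585)
        assert np.allclose(2.0 ** r[inside.to_numpy()], 1 / 3, atol=1e-3)
        assert np.allclose(r[~inside.to_numpy()], 0.0)

    def test_bias_linearity_exact_at_zero_noise(self, small_genome):
        bias = BiasModel(
            gc_coefficient=-1.5,
            telomere_depression=1.2,
            telomere_decay=10_000,
            cnv_segments=[("chr2", 50_000, 90_000, 0.7)],
        )
        arr = simulate_hybridization(small_genome, bias, 123)
        r = np.log2(arr.test / arr.ref)
        assert np.allclose(r, expected_log2_ratio(small_genome, bias), atol=1e-9)

    def test_noise_sd_recovered(self):
        g = simulate_genome(
            GenomeConfig(chromosomes=(("chr1", 6_000_000),), spacing_range=(500, 700)),
            seed=2,
        )
        arr = simulate_hybridization(g, BiasModel(noise_sd=0.12), 99)
        r = np.log2(arr.test / arr.ref)
        assert len(r) >= 8000
        assert abs(np.std(r) - 0.12) < 0.005

    def test_dlrs_converges_to_noise_sd(self):
        g = simulate_genome(
            GenomeConfig(chromosomes=(("chr1", 6_000_000),), spacing_range=(500, 700)),
            seed=2,
        )
        arr = simulate_hybridization(g, BiasModel(noise_sd=0.165), 7)
        est = dlrs(compute_log2_ratios(arr, normalize=False))
        assert abs(est - 0.165) / 0.165 < 0.05

    def test_gc_monotonicity(self, small_genome):
        arr = simulate_hybridization(small_genome, BiasModel(gc_coefficient=-2.0), 1)
        r = np.log2(arr.test / arr.ref)
        gc = arr.probes["gc"].to_numpy()
        top, bottom = np.quantile(gc, [0.9, 0.1])
        assert r[gc >= top].mean() < r[gc <= bottom].mean()

    def test_cnv_outside_genome_rejected(self, small_genome):
        bias = BiasModel(cnv_segments=[("chrX", 0, 100, -1.0)])
        with pytest.raises(ValueError):
            simulate_hybridization(small_genome, bias, 0)

    def test_replicate_seed_determinism(self, small_genome):
        a = simulate_hybridization(small_genome, BiasModel(noise_sd=0.2), 5)
        b = simulate_hybridization(small_genome, BiasModel(noise_sd=0.2), 5)
        assert np.array_equal(a.test, b.test) and np.array_equal(a.ref, b.ref)


class TestSimulateCtTable:
    def test_calibrator_copy_number_round_trip(self):
        df = simulate_ct_table({"L1": 2}, noise_sd=0.0, n_replicates=1)
        assert df.loc[0, "ct_target"] == df.loc[0, "ct_reference"]

    def test_doubling_removes_one_cycle(self):
        df = simulate_ct_table({"L2": 2, "L4": 4}, noise_sd=0.0, n_replicates=1)
        ct = df.set_index("locus")["ct_target"]
        assert ct["L2"] - ct["L4"] == pytest.approx(1.0)

    def test_noisy_cn_recovered_near_two(self):
        df = simulate_ct_table({"L": 2}, noise_sd=0.05, n_replicates=4, seed=3)
        dct = df["ct_target"] - df["ct_reference"]
        cn = 2.0 * 2.0 ** (-dct)  # calibrator ddCt = 0 in expectation
        assert 1.9 <= cn.mean() <= 2.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_ct_table({"L": -1})
        with pytest.raises(ValueError):
            simulate_ct_table({"L": 2}, noise_sd=-0.1)


class TestSimulateBidirectionalReads:
    def test_no_injections_matches_reference(self):
        ref = "ACGT" * 50
        fwd, rev = simulate_bidirectional_reads(ref)
        assert fwd == ref and rev == ref

    def test_mutation_concordant_on_both_strands(self):
        ref = "A" * 30
        fwd, rev = simulate_bidirectional_reads(ref, mutation_positions=[10], seed=1)
        assert fwd[10] == rev[10] != "A"
        assert fwd[:10] == ref[:10] and fwd[11:] == ref[11:]

    def test_nocall_and_discordant_structure(self):
        ref = "ACGT" * 500
        fwd, rev = simulate_bidirectional_reads(
            ref, nocall_positions=[5, 100, 900], discordant_positions=[50, 700], seed=2
        )
        for p in (5, 100, 900):
            assert "N" in (fwd[p], rev[p])
        for p in (50, 700):
            assert fwd[p] != rev[p] and "N" not in (fwd[p], rev[p])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            simulate_bidirectional_reads("ACGT" * 10, [3], [3], [])
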
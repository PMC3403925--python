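import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wgaqc.acgh import RatioProfile
from wgaqc.simulate import GenomeConfig, simulate_genome
from wgaqc.workflow import StudyConfig, run_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_profile(values, chrom=None, spacing=1000, smoothed=False):
    """RatioProfile from a plain value vector, with synthetic coordinates."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * n)
    start = np.concatenate(
        [np.arange(np.sum(chrom == c)) * spacing for c in pd.unique(chrom)]
    )
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i}" for i in range(n)],
            "chrom": chrom,
            "start": start,
            "end": start + 60,
        }
    )
    return RatioProfile(probes=probes, log2_ratio=values, smoothed=smoothed)


@pytest.fixture(scope="session")
def small_genome():
    cfg = GenomeConfig(chromosomes=(("chr1", 150_000), ("chr2", 150_000)))
    return simulate_genome(cfg, seed=7)


@pytest.fixture(scope="session")
def small_study_config():
    """Desk-scale study with the default kit presets on a reduced genome."""
    # injected windows hold >= 10 probes at 1-2 kb spacing so per-group
    # detection is in the regime the recovery property is defined on
    return StudyConfig(
        genome=GenomeConfig(chromosomes=(("chr1", 200_000), ("chr2", 200_000))),
        cbs_permutations=120,
        underamp_segments=3,
        underamp_bp=16_000,
    )


@pytest.fixture(scope="session")
def small_study(small_study_config):
    return run_study(small_study_config, seed=11)


@pytest.fixture(scope="session")
def silent_study():
    """Degenerate limit: zero bias, zero noise everywhere."""
    cfg = StudyConfig(
        genome=GenomeConfig(chromosomes=(("chr1", 120_000),)),
        kits={"REPLI-g": dict(noise_sd=0.0), "GenomiPhi": dict(noise_sd=0.0)},
        self_self_noise_sd=0.0,
        underamp_segments=0,
        cbs_permutations=120,
        qpcr_noise_sd=0.0,
        fidelity_exclusion_rate={"REPLI-g": 0.0, "GenomiPhi": 0.0},
    )
    return run_study(cfg, seed=5)
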
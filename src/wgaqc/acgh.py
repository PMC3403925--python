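"""Probe-level aCGH ratio analysis.

Two-channel array CGH measures the abundance of a test DNA sample relative to
a reference sample at each genomic probe.  The per-probe statistic is the
log2 ratio of test over reference intensity; 0 means equal abundance.  This
module covers reading probe tables, dye-bias normalization, direction-agnostic
fold changes, the derivative log ratio spread (DLRS) array-noise estimate,
fold-change threshold tables, and quality-weighted replicate combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbeArray",
    "RatioProfile",
    "ThresholdTable",
    "read_probe_table",
    "write_probe_table",
    "compute_log2_ratios",
    "fold_change",
    "dlrs",
    "threshold_table",
    "combine_replicates",
    "profile_to_bed",
]

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]

#: IQR of a standard normal sample estimates 1.349 sigma; consecutive-probe
#: differences of iid noise have sd sigma*sqrt(2).
_DLRS_SCALE = 1.349 * np.sqrt(2.0)


def _sort_probes(probes: pd.DataFrame, *extras: np.ndarray):
    order = np.lexsort((probes["start"].to_numpy(), probes["chrom"].to_numpy()))
    if np.array_equal(order, np.arange(len(probes))):
        return (probes, *extras)
    probes = probes.iloc[order].reset_index(drop=True)
    return (probes, *(np.asarray(e)[order] for e in extras))


@dataclass
class ProbeArray:
    """One hybridization: probe coordinates plus two-channel intensities.

    ``probes`` holds ``probe_id, chrom, start, end`` (0-based half-open) and
    optionally ``gc``; ``test`` and ``ref`` are positive intensity vectors
    aligned with the probe rows.  ``labels`` carries (sample, kit, replicate,
    comparison) bookkeeping.
    """

    probes: pd.DataFrame
    test: np.ndarray
    ref: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.test = np.asarray(self.test, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        if not (len(self.probes) == len(self.test) == len(self.ref)):
            raise ValueError("probe table and intensity vectors differ in length")
        if np.any(self.test <= 0) or np.any(self.ref <= 0):
            raise ValueError("intensities must be positive")
        self.probes, self.test, self.ref = _sort_probes(self.probes, self.test, self.ref)

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class RatioProfile:
    """Per-probe log2 ratios ordered along the genome.

    ``smoothed`` distinguishes raw per-probe ratios from segment-mean
    (CBS-smoothed) values; several downstream operations require one or the
    other.
    """

    probes: pd.DataFrame
    log2_ratio: np.ndarray
    smoothed: bool = False
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if len(self.probes) != len(self.log2_ratio):
            raise ValueError("probe table and ratio vector differ in length")
        if not np.all(np.isfinite(self.log2_ratio)):
            raise ValueError("log2 ratios must be finite")

    def __len__(self) -> int:
        return len(self.probes)

    def chromosome_slices(self):
        """Yield (chrom, slice) for each chromosome run, in probe order."""
        chrom = self.probes["chrom"].to_numpy()
        if len(chrom) == 0:
            return
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [len(chrom)]])
        for s, e in zip(starts, stops):
            yield chrom[s], slice(s, e)


def same_probe_set(a, b) -> bool:
    """True when two profiles/arrays address the identical probe set."""
    pa, pb = a.probes, b.probes
    if len(pa) != len(pb):
        return False
    return (
        pa["chrom"].to_numpy().tolist() == pb["chrom"].to_numpy().tolist()
        and np.array_equal(pa["start"].to_numpy(), pb["start"].to_numpy())
    )


@dataclass
class ThresholdTable:
    """Percent of probes beyond each fold-change cutoff, averaged over replicates."""

    cutoffs: np.ndarray
    percentages: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.percentages = np.asarray(self.percentages, dtype=float)
        if np.any((self.percentages < 0) | (self.percentages > 100)):
            raise ValueError("percentages must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold_cutoff": self.cutoffs, "percent_probes": self.percentages}
        ).assign(group=self.label)


def read_probe_table(path, sep: str = "\t") -> ProbeArray:
    """Read a TSV probe table into a validated, sorted :class:`ProbeArray`.

    Expected header: ``probe_id chrom start end test_intensity ref_intensity``
    with an optional trailing ``gc`` column.  Rows with non-positive
    intensities are dropped with a warning; unsorted rows are sorted.
    """
    df = pd.read_csv(path, sep=sep)
    required = PROBE_COLUMNS + ["test_intensity", "ref_intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} missing columns: {missing}")
    bad = (df["test_intensity"] <= 0) | (df["ref_intensity"] <= 0)
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} probe rows with non-positive intensity",
            stacklevel=2,
        )
        df = df[~bad].reset_index(drop=True)
    probe_cols = PROBE_COLUMNS + (["gc"] if "gc" in df.columns else [])
    return ProbeArray(
        probes=df[probe_cols].copy(),
        test=df["test_intensity"].to_numpy(float),
        ref=df["ref_intensity"].to_numpy(float),
    )


def write_probe_table(array: ProbeArray, path, sep: str = "\t") -> None:
    df = array.probes.copy()
    df["test_intensity"] = array.test
    df["ref_intensity"] = array.ref
    if "gc" in df.columns:  # keep gc as the trailing column, matching the dialect
        df = df[PROBE_COLUMNS + ["test_intensity", "ref_intensity", "gc"]]
    df.to_csv(path, sep=sep, index=False)


def compute_log2_ratios(array: ProbeArray, normalize: bool = True) -> RatioProfile:
    """log2(test/reference) per probe, optionally median-centered.

    Normalization applies one global multiplicative factor to the test channel
    so the median log2 ratio is 0 — the log-space equivalent of a linear
    dye-bias correction.  It is idempotent.
    """
    r = np.log2(array.test / array.ref)
    if normalize:
        r = r - np.median(r)
    return RatioProfile(
        probes=array.probes, log2_ratio=r, smoothed=False, labels=dict(array.labels)
    )


def fold_change(log2_ratio):
    """Direction-agnostic fold change ``2**|r|`` (scalar or array)."""
    return 2.0 ** np.abs(np.asarray(log2_ratio, dtype=float))


def dlrs(profile: RatioProfile) -> float:
    """Derivative log ratio spread: robust per-probe noise sd of an array.

    Computed as the interquartile range of consecutive-probe log2-ratio
    differences within chromosomes, divided by 1.349*sqrt(2) so that iid
    Gaussian probe noise of sd sigma yields an estimate of sigma.
    """
    if profile.smoothed:
        raise ValueError("DLRS is defined on raw (unsmoothed) profiles")
    if len(profile) < 3:
        raise ValueError("DLRS requires at least 3 probes")
    diffs = [np.diff(profile.log2_ratio[sl]) for _, sl in profile.chromosome_slices()]
    d = np.concatenate([x for x in diffs if x.size] or [np.empty(0)])
    if d.size == 0:
        raise ValueError("no consecutive probe pairs within a chromosome")
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / _DLRS_SCALE)


def threshold_table(
    profiles,
    cutoffs=(1.5, 2.0, 2.5, 3.0, 4.0),
    label: str = "",
    two_sided: bool = True,
) -> ThresholdTable:
    """Percent of probes with fold change beyond each cutoff, replicate-averaged.

    ``two_sided`` counts over- and under-amplification together via
    ``2**|r| > cutoff`` (the default); one-sided counts gains only.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles[1:]:
        if not same_probe_set(profiles[0], p):
            raise ValueError("profiles do not share an identical probe set")
    cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
    pct = np.zeros_like(cutoffs)
    for p in profiles:
        fc = fold_change(p.log2_ratio) if two_sided else 2.0 ** p.log2_ratio
        pct += [100.0 * np.mean(fc > c) for c in cutoffs]
    return ThresholdTable(cutoffs=cutoffs, percentages=pct / len(profiles), label=label)


def combine_replicates(profiles, weights=None) -> RatioProfile:
    """Quality-weighted per-probe mean of replicate profiles.

    Default weights are proportional to 1/DLRS^2 (inverse variance of the
    per-probe noise), normalized to sum 1.  Profiles with DLRS 0 (noiseless)
    fall back to equal weights.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles[1:]:
        if not same_probe_set(profiles[0], p):
            raise ValueError("profiles do not share an identical probe set")
    if weights is None:
        d = np.array([dlrs(p) for p in profiles])
        if np.any(d == 0):
            weights = np.ones(len(profiles))
        else:
            weights = 1.0 / d**2
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    w = weights / total
    stacked = np.vstack([p.log2_ratio for p in profiles])
    labels = dict(profiles[0].labels)
    labels["replicate"] = "combined"
    return RatioProfile(
        probes=profiles[0].probes,
        log2_ratio=w @ stacked,
        smoothed=profiles[0].smoothed,
        labels=labels,
    )


def profile_to_bed(profile: RatioProfile, path) -> None:
    """Export per-probe ratios as BED6 (score = log2 ratio x 1000, integer)."""
    df = pd.DataFrame(
        {
            "chrom": profile.probes["chrom"],
            "start": profile.probes["start"],
            "end": profile.probes["end"],
            "name": profile.probes["probe_id"],
            "score": np.round(profile.log2_ratio * 1000).astype(int),
            "strand": "+",
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)
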
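"""Relative copy number from TaqMan-style qPCR Ct values (comparative Ct).

Each well measures a target locus and a reference assay (e.g. RNase P) in the
same sample.  Delta Ct = Ct_target - Ct_reference removes template-amount
effects; double-differencing against a calibrator sample (the unamplified
DNA, copy number 2) and exponentiating gives the relative copy number

    CN = calibrator_cn * E^-(dCt_sample - dCt_calibrator)

with amplification efficiency E = 2 (perfect doubling) by default.
Replicates are combined at the copy-number scale: mean with min/max bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberResult",
    "delta_ct",
    "copy_number",
    "summarize_cn",
    "analyze_ct_table",
    "read_ct_table",
]


@dataclass
class CopyNumberResult:
    """Replicate summary of calculated copy number at one (sample, locus)."""

    sample: str
    locus: str
    mean_cn: float
    min_cn: float
    max_cn: float
    n: int
    flagged: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one replicate")
        if not self.min_cn <= self.mean_cn <= self.max_cn:
            raise ValueError("min <= mean <= max violated")


def delta_ct(ct_target, ct_reference):
    """Ct_target - Ct_reference (scalar or vectorized)."""
    return np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)


def copy_number(dct_sample, dct_calibrator, calibrator_cn: float = 2.0, efficiency: float = 2.0):
    """Relative copy number ``calibrator_cn * E^-(ddCt)``.

    Strictly decreasing in delta-delta Ct; homogeneous of degree 1 in
    ``calibrator_cn``.
    """
    if calibrator_cn <= 0:
        raise ValueError("calibrator copy number must be positive")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = np.asarray(dct_sample, dtype=float) - np.asarray(dct_calibrator, dtype=float)
    return calibrator_cn * efficiency ** (-ddct)


def summarize_cn(
    replicate_cns,
    sample: str = "",
    locus: str = "",
    calibrator_cn: float = 2.0,
    flag_fold: float = 2.0,
) -> CopyNumberResult:
    """Mean/min/max across replicate copy numbers.

    Flags the locus when any replicate differs from the calibrator by more
    than ``flag_fold`` in either direction (over- or under-amplification).
    """
    cns = np.asarray(list(replicate_cns), dtype=float)
    if cns.size == 0:
        raise ValueError("no replicate measurements")
    fold_vs_cal = 2.0 ** np.abs(np.log2(cns / calibrator_cn))
    return CopyNumberResult(
        sample=sample,
        locus=locus,
        mean_cn=float(cns.mean()),
        min_cn=float(cns.min()),
        max_cn=float(cns.max()),
        n=int(cns.size),
        flagged=bool(np.any(fold_vs_cal > flag_fold)),
    )


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample, locus, replicate, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "locus", "replicate", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def analyze_ct_table(
    ct: pd.DataFrame,
    calibrator_sample: str,
    calibrator_cn: float = 2.0,
    efficiency: float = 2.0,
    flag_fold: float = 2.0,
) -> pd.DataFrame:
    """Full comparative-Ct pipeline over a Ct table.

    The calibrator's per-locus mean delta Ct standardizes every sample;
    replicates are summarized at the copy-number scale.  Returns one row per
    (sample, locus) with mean/min/max CN, replicate count, and the >flag_fold
    deviation flag.
    """
    if calibrator_sample not in set(ct["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    ct = ct.assign(dct=delta_ct(ct["ct_target"], ct["ct_reference"]))
    cal = (
        ct[ct["sample"] == calibrator_sample]
        .groupby("locus")["dct"]
        .mean()
        .rename("dct_cal")
    )
    ct = ct.join(cal, on="locus")
    if ct["dct_cal"].isna().any():
        raise ValueError("calibrator lacks measurements for some loci")
    ct = ct.assign(
        cn=copy_number(ct["dct"], ct["dct_cal"], calibrator_cn, efficiency)
    )
    rows = []
    for (sample, locus), grp in ct.groupby(["sample", "locus"], sort=False):
        res = summarize_cn(
            grp["cn"], sample=sample, locus=locus,
            calibrator_cn=calibrator_cn, flag_fold=flag_fold,
        )
        rows.append(
            (res.sample, res.locus, res.mean_cn, res.min_cn, res.max_cn, res.n, res.flagged)
        )
    return pd.DataFrame(
        rows, columns=["sample", "locus", "mean_cn", "min_cn", "max_cn", "n", "flagged"]
    )
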
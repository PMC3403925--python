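"""Consistency statistics for replicate hybridizations.

Two complementary measures of WGA uniformity:

* the Kolmogorov distance — the supremum absolute difference between the
  empirical distribution functions of two arrays' log2-ratio values (the
  two-sample Kolmogorov-Smirnov statistic, no p-value).  Low values mean the
  ratio *distributions* agree.
* the Phi correlation — Pearson correlation of two binary CNV-location
  vectors via the 2x2 agreement table.  High values mean CNVs sit in the
  *same places*.

A low Kolmogorov distance together with a high Phi correlation indicates
highly uniform, reproducible amplification.  Pairwise matrices collect the
metric over all replicate pairs within a group (6 unique pairs of 4
replicates) or between two groups (full 4x4 grid), and are summarized by
their median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import RatioProfile
from .segmentation import CNVCallVector

__all__ = [
    "PairwiseMatrix",
    "kolmogorov_distance",
    "phi_correlation",
    "pairwise_matrix",
    "matrix_median",
]


def kolmogorov_distance(a, b) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)| over the pooled sample points, in [0, 1].

    ECDFs are right-continuous; evaluating at the pooled sample points attains
    the supremum of the step functions.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def phi_correlation(a, b) -> float:
    """Phi coefficient of two binary vectors from their 2x2 agreement table.

    phi = (n11*n00 - n10*n01) / sqrt((n11+n10)(n01+n00)(n11+n01)(n10+n00)).
    Identical vectors (including all-zero) return 1.0 — two arrays calling no
    CNVs anywhere are in perfect agreement.  Differing vectors with a
    degenerate marginal return 0.0 with a warning.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    if np.array_equal(a, b):
        return 1.0
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        warnings.warn("degenerate marginal in phi correlation; returning 0.0", stacklevel=2)
        return 0.0
    return float((n11 * n00 - n10 * n01) / np.sqrt(denom))


def _metric_values(item):
    if isinstance(item, RatioProfile):
        return item.log2_ratio
    if isinstance(item, CNVCallVector):
        return item.calls
    return np.asarray(item)


_METRICS = {"kolmogorov": kolmogorov_distance, "phi": phi_correlation}


@dataclass
class PairwiseMatrix:
    """Metric values for all pairs of replicates within or between groups."""

    values: pd.DataFrame
    mode: str  # "within" | "between"
    metric: str
    group_a: str = ""
    group_b: str = ""

    def __post_init__(self):
        if self.mode not in ("within", "between"):
            raise ValueError("mode must be 'within' or 'between'")

    def unique_values(self) -> np.ndarray:
        """The 6 unique off-diagonal pairs (within) or all cells (between)."""
        v = self.values.to_numpy(float)
        if self.mode == "within":
            iu = np.triu_indices(v.shape[0], k=1)
            return v[iu]
        return v.ravel()

    def to_tsv(self, path) -> None:
        """Write the grid with its median appended, mirroring the report layout."""
        with open(path, "w") as fh:
            self.values.to_csv(fh, sep="\t")
            fh.write(f"median\t{matrix_median(self):.3f}\n")


def pairwise_matrix(
    group_a,
    group_b=None,
    metric: str = "kolmogorov",
    group_a_label: str = "A",
    group_b_label: str = "B",
) -> PairwiseMatrix:
    """Evaluate a metric over every replicate pair.

    Within-group (``group_b`` omitted): symmetric grid over the replicates of
    one group, diagonal 0 for Kolmogorov and 1 for Phi.  Between-group: the
    full rectangular grid of ordered pairs.
    """
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    a = [_metric_values(x) for x in group_a]
    rows = [f"{group_a_label} rep{i + 1}" for i in range(len(a))]
    if group_b is None:
        if len(a) < 2:
            raise ValueError("within-group matrix needs >= 2 replicates")
        m = np.zeros((len(a), len(a)))
        diag = 1.0 if name == "phi" else 0.0
        np.fill_diagonal(m, diag)
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                m[i, j] = m[j, i] = fn(a[i], a[j])
        df = pd.DataFrame(m, index=rows, columns=rows)
        return PairwiseMatrix(df, "within", name, group_a_label, group_a_label)
    b = [_metric_values(x) for x in group_b]
    if not a or not b:
        raise ValueError("between-group matrix needs >= 1 replicate per group")
    cols = [f"{group_b_label} rep{j + 1}" for j in range(len(b))]
    m = np.array([[fn(ai, bj) for bj in b] for ai in a])
    df = pd.DataFrame(m, index=rows, columns=cols)
    return PairwiseMatrix(df, "between", name, group_a_label, group_b_label)


def matrix_median(matrix) -> float:
    """Median over a matrix's unique pair values.

    Within-group matrices use the 6 unique unordered pairs; between-group
    matrices use all cells.  Even counts take the midpoint of the two central
    order statistics.  Also accepts a plain sequence of values.
    """
    if isinstance(matrix, PairwiseMatrix):
        vals = matrix.unique_values()
    else:
        vals = np.asarray(matrix, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty matrix has no median")
    return float(np.median(vals))
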
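"""Published reference values from the original three-sample WGA evaluation.

The study this package reimplements compared three human DNA samples (Normal,
CF1, CF2) amplified four times each by two MDA kits (REPLI-g, GenomiPhi)
against the unamplified template, plus four self-self hybridizations.  Its
report prints the pairwise Kolmogorov-distance and Phi-correlation matrices,
the sequencing primer panel, and the sequencing exclusion counts.  Those
printed values are inputs: the package's statistics can be re-run on them
(e.g. :func:`wgaqc.uniformity.matrix_median` on a printed grid) to reproduce
the published medians and rates.

Matrix cells are row-major lists; within-group grids store the 6 unique
off-diagonal pair values (lower triangle, row by row), between-group grids
store all 16 ordered cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "AMPLIFIED_VS_UNAMPLIFIED_KS",
    "WITHIN_GROUP_KS",
    "WITHIN_GROUP_KS_PRINTED_MEDIANS",
    "BETWEEN_KIT_KS",
    "WITHIN_GROUP_PHI",
    "BETWEEN_KIT_PHI",
    "CNV_PERCENTAGES",
    "PRIMER_PANEL",
    "QPCR_PANEL",
    "SEQUENCED_BASES_PER_METHOD",
    "EXCLUDED_BASES",
    "SELF_SELF_DLRS",
    "within_matrix",
    "between_matrix",
]

#: Kolmogorov distances, amplified Normal replicates vs the four self-self
#: hybridizations (4x4 ordered grids; published medians 0.407 and 0.368).
AMPLIFIED_VS_UNAMPLIFIED_KS = {
    "REPLI-g": [
        0.398, 0.402, 0.405, 0.402,
        0.409, 0.413, 0.416, 0.413,
        0.385, 0.389, 0.392, 0.388,
        0.415, 0.419, 0.423, 0.420,
    ],
    "GenomiPhi": [
        0.370, 0.354, 0.386, 0.342,
        0.381, 0.366, 0.398, 0.354,
        0.357, 0.340, 0.373, 0.328,
        0.388, 0.373, 0.405, 0.361,
    ],
}

#: Within-group Kolmogorov distances (6 unique pairs per group of 4).
WITHIN_GROUP_KS = {
    ("Normal", "UnAmp"): [0.019, 0.026, 0.044, 0.024, 0.018, 0.049],
    ("Normal", "REPLI-g"): [0.009, 0.011, 0.005, 0.015, 0.020, 0.021],
    ("Normal", "GenomiPhi"): [0.026, 0.020, 0.033, 0.048, 0.023, 0.053],
    ("CF1", "REPLI-g"): [0.108, 0.046, 0.062, 0.065, 0.062, 0.120],
    ("CF1", "GenomiPhi"): [0.050, 0.056, 0.023, 0.042, 0.082, 0.095],
    ("CF2", "REPLI-g"): [0.003, 0.065, 0.066, 0.029, 0.029, 0.088],
    ("CF2", "GenomiPhi"): [0.018, 0.050, 0.036, 0.055, 0.043, 0.009],
}

#: Medians as printed alongside the within-group grids.  The CF1/REPLI-g
#: printed value (0.085) is not the median of its own six printed cells
#: (0.0635) — a typesetting inconsistency in the source report.
WITHIN_GROUP_KS_PRINTED_MEDIANS = {
    ("Normal", "UnAmp"): 0.025,
    ("Normal", "REPLI-g"): 0.013,
    ("Normal", "GenomiPhi"): 0.029,
    ("CF1", "REPLI-g"): 0.085,
    ("CF1", "GenomiPhi"): 0.053,
    ("CF2", "REPLI-g"): 0.047,
    ("CF2", "GenomiPhi"): 0.039,
}

#: Kolmogorov distances between REPLI-g and GenomiPhi replicates per sample
#: (4x4 ordered grids; published medians 0.046, 0.055, 0.046).
BETWEEN_KIT_KS = {
    "Normal": [
        0.031, 0.055, 0.026, 0.078,
        0.038, 0.063, 0.035, 0.085,
        0.041, 0.065, 0.037, 0.088,
        0.032, 0.051, 0.019, 0.072,
    ],
    "CF1": [
        0.095, 0.050, 0.041, 0.131,
        0.017, 0.061, 0.071, 0.025,
        0.050, 0.009, 0.019, 0.085,
        0.079, 0.115, 0.130, 0.037,
    ],
    "CF2": [
        0.082, 0.069, 0.033, 0.027,
        0.083, 0.069, 0.034, 0.028,
        0.021, 0.019, 0.034, 0.039,
        0.106, 0.095, 0.060, 0.052,
    ],
}

#: Within-group Phi correlations of CNV calls after CBS smoothing (6 pairs).
WITHIN_GROUP_PHI = {
    ("Normal", "UnAmp"): [1.000, 1.000, 1.000, 1.000, 1.000, 1.000],
    ("Normal", "REPLI-g"): [0.855, 0.840, 0.843, 0.877, 0.840, 0.809],
    ("Normal", "GenomiPhi"): [0.853, 0.839, 0.796, 0.773, 0.814, 0.707],
    ("CF1", "REPLI-g"): [0.597, 0.764, 0.665, 0.457, 0.625, 0.520],
    ("CF1", "GenomiPhi"): [0.687, 0.679, 0.777, 0.632, 0.656, 0.589],
    ("CF2", "REPLI-g"): [0.824, 0.697, 0.744, 0.796, 0.793, 0.707],
    ("CF2", "GenomiPhi"): [0.865, 0.798, 0.746, 0.762, 0.728, 0.838],
}

#: Phi correlations between kits per sample (4x4 ordered grids; published
#: medians 0.739, 0.789, 0.792).
BETWEEN_KIT_PHI = {
    "Normal": [
        0.746, 0.724, 0.782, 0.725,
        0.729, 0.712, 0.783, 0.706,
        0.688, 0.664, 0.751, 0.653,
        0.814, 0.772, 0.811, 0.763,
    ],
    "CF1": [
        0.736, 0.804, 0.906, 0.681,
        0.842, 0.782, 0.711, 0.807,
        0.828, 0.804, 0.815, 0.738,
        0.733, 0.692, 0.622, 0.796,
    ],
    "CF2": [
        0.762, 0.771, 0.833, 0.835,
        0.776, 0.773, 0.831, 0.818,
        0.789, 0.839, 0.782, 0.795,
        0.736, 0.741, 0.825, 0.828,
    ],
}

#: Published percent of probes beyond each fold cutoff (replicate averages).
CNV_PERCENTAGES = pd.DataFrame(
    [
        ("Normal", "UnAmp/UnAmp", 0.004, 0.000, 0.000, 0.000, 0.000),
        ("Normal", "Amp-R/UnAmp", 2.043, 0.525, 0.194, 0.077, 0.010),
        ("Normal", "Amp-G/UnAmp", 8.139, 1.273, 0.339, 0.109, 0.017),
        ("CF1", "Amp-R/UnAmp", 2.191, 0.478, 0.162, 0.057, 0.010),
        ("CF1", "Amp-G/UnAmp", 3.682, 0.747, 0.230, 0.074, 0.015),
        ("CF2", "Amp-R/UnAmp", 1.913, 0.486, 0.192, 0.075, 0.007),
        ("CF2", "Amp-G/UnAmp", 2.883, 0.605, 0.183, 0.061, 0.015),
    ],
    columns=["sample", "comparison", "pct_1.5", "pct_2.0", "pct_2.5", "pct_3.0", "pct_4.0"],
)

#: Sequencing primer panel: three overlapping amplicons tiling a ~2 kb
#: region; coordinates are 1-based inclusive per the primer-table convention.
PRIMER_PANEL = pd.DataFrame(
    [
        ("Seq1_F", "112776-112797", "GGACATCTCCAAGTTTGCAGAG", 66),
        ("Seq1_R", "113535-113512", "GAAACATTTGACATCAGAGTCAC", 64),
        ("Seq2_F", "113459-113479", "GTCAAGGAGAGAGCTTTGTGG", 64),
        ("Seq2_R", "114187-114165", "TGGACAACACATTACACATTCTG", 64),
        ("Seq3_F", "114050-114071", "GGCTTCTAGACATCCAACATAG", 64),
        ("Seq3_R", "114805-114784", "GATAGCAGTGCTGCCACAACTG", 68),
    ],
    columns=["primer_name", "location", "sequence", "tm"],
)

#: TaqMan copy-number assay panel across the CFTR locus (chromosome 7).
QPCR_PANEL = pd.DataFrame(
    [
        ("I", "Hs05020079_cn", "Intron 1", 117122192),
        ("II", "Hs04952703_cn", "Intron 2", 117145581),
        ("III", "Hs04988506_cn", "Intron 3", 117153814),
        ("IV", "Hs04984230_cn", "Intron 9", 117185643),
        ("V", "Hs04963787_cn", "Intron 11", 117203673),
        ("VI", "Hs05017940_cn", "Intron 12", 117228242),
        ("VII", "Hs05001680_cn", "Intron 15", 117238610),
        ("VIII", "Hs04963453_cn", "Intron 18", 117247359),
        ("IX", "Hs04947556_cn", "Intron 23", 117282984),
        ("X", "Hs00393982_cn", "Intron 27", 117307221),
    ],
    columns=["locus", "assay_id", "cftr_location", "chr7_position"],
)

#: Bases examined per amplification method and bases excluded by the
#: no-call/discordance rules.
SEQUENCED_BASES_PER_METHOD = 23_744
EXCLUDED_BASES = {"GenomiPhi": 53, "REPLI-g": 11}

#: Derivative log ratio spread of the self-self hybridizations.
SELF_SELF_DLRS = 0.165


def within_matrix(pairs, metric: str, label: str = ""):
    """Rebuild a within-group :class:`~wgaqc.uniformity.PairwiseMatrix` from
    its 6 printed unique pair values (lower triangle, row by row)."""
    from .uniformity import PairwiseMatrix

    m = np.full((4, 4), 1.0 if metric == "phi" else 0.0)
    (m[1, 0], m[2, 0], m[2, 1], m[3, 0], m[3, 1], m[3, 2]) = pairs
    m = np.tril(m, -1) + np.tril(m, -1).T + np.diag(np.diag(m))
    rows = [f"{label} rep{i + 1}" for i in range(4)]
    return PairwiseMatrix(pd.DataFrame(m, index=rows, columns=rows), "within", metric, label, label)


def between_matrix(cells, metric: str, label_a: str = "A", label_b: str = "B"):
    """Rebuild a between-group matrix from its 16 printed cells (row-major)."""
    from .uniformity import PairwiseMatrix

    m = np.asarray(cells, dtype=float).reshape(4, 4)
    rows = [f"{label_a} rep{i + 1}" for i in range(4)]
    cols = [f"{label_b} rep{j + 1}" for j in range(4)]
    return PairwiseMatrix(pd.DataFrame(m, index=rows, columns=cols), "between", metric, label_a, label_b)
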
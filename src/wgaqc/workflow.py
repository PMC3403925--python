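"""End-to-end study orchestration.

Runs the full evaluation design — three DNA samples amplified by two MDA kits
with four replicate hybridizations each, plus four self-self hybridizations
of the unamplified Normal sample (28 arrays) — from a single declarative
config, on synthetic data or on user-supplied probe tables entering at any
stage via the CLI subcommands.  Emits fold-change threshold tables, pairwise
Kolmogorov/Phi matrices with medians, the common under-amplified region set
with GC summary, a qPCR copy-number summary, a sequencing-fidelity report,
and a structured run log.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acgh, fidelity, qpcr, regions, segmentation, simulate, uniformity
from .reference import QPCR_PANEL
from .simulate import BiasModel, GenomeConfig, child_seed

__all__ = ["StudyConfig", "StudyError", "run_study", "default_kits"]

SELF_SELF = "UnAmp"


class StudyError(RuntimeError):
    """A study stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def default_kits() -> dict:
    """Per-kit MDA bias presets as parameter sets of one BiasModel.

    GenomiPhi carries more noise and stronger GC/telomere bias than REPLI-g,
    reproducing the published ordering of CNV percentages between the kits;
    the self-self preset is pure noise at the published DLRS (0.165).
    """
    return {
        "REPLI-g": dict(
            noise_sd=0.40, gc_coefficient=-1.2, telomere_depression=1.6,
            telomere_decay=8_000.0,
        ),
        "GenomiPhi": dict(
            noise_sd=0.48, gc_coefficient=-1.8, telomere_depression=2.0,
            telomere_decay=8_000.0,
        ),
    }


@dataclass
class StudyConfig:
    """Declarative description of one study run.

    The defaults mirror the evaluation design at desk scale: a 3 x 400 kb
    genome at 1-2 kb probe spacing, 3 samples x 2 kits x 4 replicates plus 4
    self-self arrays, CBS at alpha 0.01, CNV calls at 2-fold, aberrations at
    3-fold over >= 3 probes.
    """

    samples: tuple = ("Normal", "CF1", "CF2")
    kits: dict = field(default_factory=default_kits)
    replicates: int = 4
    self_self_noise_sd: float = 0.165
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    # Shared consistently-under-amplified loci (GC-richest windows).
    # each shared under-amplified window spans >= 10 probes at 1-2 kb spacing
    underamp_segments: int = 4
    underamp_bp: int = 16_000
    underamp_shift: float = -2.0
    # Analysis parameters.
    normalize: bool = True
    cbs_alpha: float = 0.01
    cbs_permutations: int = 200
    cbs_min_width: int = 2
    cbs_undo_sd: float = 1.0
    cnv_fold_cutoff: float = 2.0
    aberration_fold_cutoff: float = 3.0
    aberration_min_probes: int = 3
    threshold_cutoffs: tuple = (1.5, 2.0, 2.5, 3.0, 4.0)
    # qPCR stage.
    qpcr_noise_sd: float = 0.05
    qpcr_replicates: int = 4
    # Fidelity stage.
    fidelity_region_bp: int = 2000
    fidelity_exclusion_rate: dict = field(
        default_factory=lambda: {"REPLI-g": 11 / 23_744, "GenomiPhi": 53 / 23_744}
    )
    fidelity_mutations: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("within-group matrices need >= 2 replicates")
        if list(self.threshold_cutoffs) != sorted(self.threshold_cutoffs):
            raise ValueError("threshold cutoffs must be sorted ascending")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genome" in raw:
            g = raw["genome"]
            if "chromosomes" in g:
                g["chromosomes"] = tuple((str(n), int(l)) for n, l in g["chromosomes"])
            raw["genome"] = GenomeConfig(**g)
        for key in ("samples", "threshold_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = dataclasses.asdict(self.genome)
        return d


def _kit_bias(cfg: StudyConfig, kit: str, cnv_segments) -> BiasModel:
    params = dict(cfg.kits[kit])
    return BiasModel(kit_label=kit, cnv_segments=cnv_segments, **params)


def _pick_underamp_segments(genome, cfg: StudyConfig):
    """GC-richest non-overlapping windows become shared under-amplified loci."""
    windows = []
    for name, length in genome.chromosomes:
        seq = np.frombuffer(genome.sequences[name].encode(), dtype="S1")
        is_gc = (seq == b"G") | (seq == b"C")
        for start in range(0, length - cfg.underamp_bp + 1, cfg.underamp_bp):
            gc = float(np.mean(is_gc[start : start + cfg.underamp_bp]))
            windows.append((gc, name, start))
    windows.sort(reverse=True)
    chosen = windows[: cfg.underamp_segments]
    return [
        (name, start, start + cfg.underamp_bp, cfg.underamp_shift)
        for _, name, start in sorted(chosen, key=lambda w: (w[1], w[2]))
    ]


def run_study(config: StudyConfig, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full study; returns a result bundle, optionally writing it.

    Every number in the bundle is reproducible from ``config`` and the seed.
    A failure in any stage removes files already written and raises
    :class:`StudyError` labeled with the stage.
    """
    root = config.seed if seed is None else int(seed)
    out = Path(out_dir) if out_dir is not None else None
    written: list[Path] = []
    result: dict = {"seed": root, "warnings": []}

    def emit(name, writer):
        if out is None:
            return
        out.mkdir(parents=True, exist_ok=True)
        path = out / name
        writer(path)
        written.append(path)

    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "simulate"
            genome = simulate.simulate_genome(config.genome, seed=root)
            underamp = _pick_underamp_segments(genome, config)
            result["genome"] = genome
            result["underamp_truth"] = underamp

            profiles: dict = {}
            group_keys = [("Normal", SELF_SELF)] + [
                (s, k) for s in config.samples for k in config.kits
            ]
            for sample, kit in group_keys:
                if kit == SELF_SELF:
                    bias = BiasModel(noise_sd=config.self_self_noise_sd, kit_label=SELF_SELF)
                else:
                    bias = _kit_bias(config, kit, underamp)
                reps = []
                for rep in range(1, config.replicates + 1):
                    arr = simulate.simulate_hybridization(
                        genome, bias, child_seed(root, sample, kit, rep),
                        labels={"sample": sample, "kit": kit, "replicate": rep},
                    )
                    reps.append(acgh.compute_log2_ratios(arr, normalize=config.normalize))
                profiles[(sample, kit)] = reps
            result["profiles"] = profiles
            result["dlrs"] = {
                key: [acgh.dlrs(p) for p in reps] for key, reps in profiles.items()
            }

            stage = "threshold_tables"
            tables = {
                key: acgh.threshold_table(
                    reps, cutoffs=config.threshold_cutoffs, label=f"{key[0]} {key[1]}"
                )
                for key, reps in profiles.items()
            }
            result["threshold_tables"] = tables
            emit(
                "threshold_tables.tsv",
                lambda p: pd.concat([t.to_frame() for t in tables.values()]).to_csv(
                    p, sep="\t", index=False
                ),
            )

            stage = "segmentation"
            smoothed: dict = {}
            calls: dict = {}
            for key, reps in profiles.items():
                sm, cl = [], []
                for i, prof in enumerate(reps):
                    segs = segmentation.cbs_segment(
                        prof,
                        alpha=config.cbs_alpha,
                        n_permutations=config.cbs_permutations,
                        min_width=config.cbs_min_width,
                        undo_sd=config.cbs_undo_sd,
                        seed=child_seed(root, "cbs", *key, i),
                    )
                    s = segmentation.smooth_profile(prof, segs)
                    sm.append(s)
                    cl.append(segmentation.call_cnv(s, config.cnv_fold_cutoff))
                smoothed[key] = sm
                calls[key] = cl
            result["smoothed"] = smoothed
            result["calls"] = calls

            stage = "uniformity"
            matrices: dict = {}
            medians: dict = {}
            # Amplified vs self-self ratio-distribution distances.
            for sample in config.samples:
                for kit in config.kits:
                    m = uniformity.pairwise_matrix(
                        profiles[(sample, kit)],
                        profiles[("Normal", SELF_SELF)],
                        metric="kolmogorov",
                        group_a_label=f"{sample} {kit}",
                        group_b_label="Normal UnAmp",
                    )
                    matrices[("ks_vs_selfself", sample, kit)] = m
            # Within-group distances and call correlations.
            for key in profiles:
                label = f"{key[0]} {key[1]}"
                matrices[("ks_within",) + key] = uniformity.pairwise_matrix(
                    profiles[key], metric="kolmogorov", group_a_label=label
                )
                matrices[("phi_within",) + key] = uniformity.pairwise_matrix(
                    calls[key], metric="phi", group_a_label=label
                )
            # Between-kit comparisons per sample.
            kits = list(config.kits)
            if len(kits) >= 2:
                ka, kb = kits[0], kits[1]
                for sample in config.samples:
                    matrices[("ks_between_kits", sample)] = uniformity.pairwise_matrix(
                        profiles[(sample, ka)], profiles[(sample, kb)],
                        metric="kolmogorov",
                        group_a_label=f"{sample} {ka}", group_b_label=f"{sample} {kb}",
                    )
                    matrices[("phi_between_kits", sample)] = uniformity.pairwise_matrix(
                        calls[(sample, ka)], calls[(sample, kb)],
                        metric="phi",
                        group_a_label=f"{sample} {ka}", group_b_label=f"{sample} {kb}",
                    )
            medians = {k: uniformity.matrix_median(m) for k, m in matrices.items()}
            result["matrices"] = matrices
            result["medians"] = medians
            for k, m in matrices.items():
                emit("matrix_" + "_".join(str(x) for x in k) + ".tsv", m.to_tsv)
            emit(
                "medians.tsv",
                lambda p: pd.DataFrame(
                    [(" ".join(str(x) for x in k), v) for k, v in medians.items()],
                    columns=["comparison", "median"],
                ).to_csv(p, sep="\t", index=False),
            )

            stage = "regions"
            group_regions = {}
            for sample in config.samples:
                for kit in config.kits:
                    combined = acgh.combine_replicates(profiles[(sample, kit)])
                    segs = segmentation.cbs_segment(
                        combined,
                        alpha=config.cbs_alpha,
                        n_permutations=config.cbs_permutations,
                        min_width=config.cbs_min_width,
                        undo_sd=config.cbs_undo_sd,
                        seed=child_seed(root, "cbs-combined", sample, kit),
                    )
                    sm = segmentation.smooth_profile(combined, segs)
                    group_regions[(sample, kit)] = regions.aberration_report(
                        sm,
                        fold_cutoff=config.aberration_fold_cutoff,
                        min_probes=config.aberration_min_probes,
                        group=f"{sample} {kit}",
                    )
            common = regions.common_regions(
                list(group_regions.values()), direction="loss"
            )
            lengths = genome.chromosome_lengths()
            frac = regions.genome_fraction(common, lengths) if common else 0.0
            if common:
                _, region_mean_gc = regions.region_gc(common, genome)
            else:
                region_mean_gc = float("nan")
            result["group_regions"] = group_regions
            result["common_regions"] = common
            result["region_summary"] = {
                "n_regions": len(common),
                "genome_fraction_pct": frac,
                "region_mean_gc": region_mean_gc,
                "genome_mean_gc": genome.mean_gc,
            }
            emit("common_regions.bed", lambda p: regions.regions_to_bed(common, p))
            emit(
                "region_summary.tsv",
                lambda p: pd.DataFrame([result["region_summary"]]).to_csv(
                    p, sep="\t", index=False
                ),
            )

            stage = "qpcr"
            loci = {str(l): 2 for l in QPCR_PANEL["locus"]}
            ct_frames = [
                simulate.simulate_ct_table(
                    loci, noise_sd=config.qpcr_noise_sd,
                    n_replicates=config.qpcr_replicates,
                    seed=root, sample=SELF_SELF,
                )
            ]
            for sample in config.samples:
                for kit in config.kits:
                    ct_frames.append(
                        simulate.simulate_ct_table(
                            loci, noise_sd=config.qpcr_noise_sd,
                            n_replicates=config.qpcr_replicates,
                            seed=root, sample=f"{sample} {kit}",
                        )
                    )
            ct = pd.concat(ct_frames, ignore_index=True)
            cn = qpcr.analyze_ct_table(ct, calibrator_sample=SELF_SELF)
            result["qpcr"] = cn
            emit("qpcr_summary.tsv", lambda p: cn.to_csv(p, sep="\t", index=False))

            stage = "fidelity"
            chrom0 = genome.chromosomes[0][0]
            ref2kb = genome.sequences[chrom0][: config.fidelity_region_bp]
            comparisons = []
            for sample in config.samples:
                for kit in config.kits:
                    agg = dict(aligned=0, examined=0, nocall=0, discordant=0, mutations=[])
                    for rep in range(1, config.replicates + 1):
                        rng = np.random.default_rng(
                            child_seed(root, "fid", sample, kit, rep)
                        )
                        n_excl = rng.binomial(
                            len(ref2kb), config.fidelity_exclusion_rate[kit]
                        )
                        pos = rng.choice(len(ref2kb), size=n_excl, replace=False)
                        # Roughly half no-calls, half strand-discordant calls.
                        half = n_excl // 2
                        fwd, rev = simulate.simulate_bidirectional_reads(
                            ref2kb,
                            mutation_positions=(),
                            nocall_positions=pos[:half],
                            discordant_positions=pos[half:],
                            seed=int(rng.integers(2**31)),
                        )
                        c = fidelity.compare_bidirectional(
                            fwd, rev, ref2kb, labels={"sample": sample, "kit": kit}
                        )
                        agg["aligned"] += c.aligned
                        agg["examined"] += c.examined
                        agg["nocall"] += c.excluded_nocall
                        agg["discordant"] += c.excluded_discordant
                        agg["mutations"].extend(c.mutations)
                    comparisons.append(
                        fidelity.SequenceComparison(
                            aligned=agg["aligned"],
                            examined=agg["examined"],
                            excluded_nocall=agg["nocall"],
                            excluded_discordant=agg["discordant"],
                            mutations=agg["mutations"],
                            labels={"sample": sample, "kit": kit},
                        )
                    )
            report = fidelity.comparison_report(comparisons)
            result["fidelity_comparisons"] = comparisons
            result["fidelity_report"] = report
            emit("fidelity_report.tsv", lambda p: report.to_csv(p, sep="\t", index=False))

            stage = "log"
            result["warnings"] = [str(w.message) for w in caught]
            log = {
                "config": config.to_dict(),
                "seed": root,
                "stages": [
                    "simulate", "threshold_tables", "segmentation", "uniformity",
                    "regions", "qpcr", "fidelity",
                ],
                "warnings": result["warnings"],
                "medians": {" ".join(str(x) for x in k): v for k, v in medians.items()},
                "region_summary": result["region_summary"],
            }
            emit(
                "run_log.json",
                lambda p: p.write_text(json.dumps(log, indent=2, sort_keys=True, default=str)),
            )
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StudyError(stage, exc) from exc
    return result
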
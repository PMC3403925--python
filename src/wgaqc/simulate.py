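"""Synthetic genomes, aCGH hybridizations, qPCR Ct tables, and Sanger reads.

Multiple displacement amplification (MDA) with phi29 polymerase amplifies
nanogram DNA to microgram scale but introduces position-dependent bias:
GC-rich regions and chromosome ends tend to be under-amplified, and per-probe
log2 ratios against the unamplified template carry extra noise.  The
generators here emit data with that statistical structure so every analysis
stage of the package can be exercised end to end without real arrays.  All
outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import ProbeArray

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "BiasModel",
    "child_seed",
    "simulate_genome",
    "simulate_hybridization",
    "simulate_ct_table",
    "simulate_bidirectional_reads",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Ct reported for an undetectable (copy number 0) target.
MAX_CT = 40.0


def child_seed(root_seed: int, *labels) -> np.random.SeedSequence:
    """Derive a per-stream seed from a root seed and text labels.

    Uses CRC32 of the joined labels so streams are stable across runs and
    platforms (hash() is salted per process and unusable here).
    """
    tag = zlib.crc32("/".join(str(x) for x in labels).encode())
    return np.random.SeedSequence([int(root_seed), tag])


@dataclass
class GenomeConfig:
    """Layout of the synthetic genome and its probe set.

    Probes are tiled at 1-2 kb spacing by default, emulating a ~1 M-feature
    human CGH array at desk scale.  GC composition follows a two-state
    (strong/weak) Markov chain whose target GC varies by block so that
    GC-rich blocks exist for the bias model to act on.
    """

    chromosomes: tuple = (("chr1", 400_000), ("chr2", 400_000), ("chr3", 400_000))
    spacing_range: tuple = (1000, 2000)
    probe_length: int = 60
    gc_mean: float = 0.41  # human genome-wide GC
    gc_block_sd: float = 0.09
    gc_block_bp: int = 10_000
    gc_run_length: float = 20.0

    def __post_init__(self):
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        lo, hi = self.spacing_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid spacing range")
        if any(lo >= length for _, length in self.chromosomes):
            raise ValueError("probe spacing must be smaller than every chromosome")


@dataclass
class GenomeModel:
    """Synthetic genome: sequences plus an ordered probe layout with GC."""

    chromosomes: list  # [(name, length), ...]
    sequences: dict  # name -> A/C/G/T string
    probes: pd.DataFrame  # probe_id, chrom, start, end, gc (0-based half-open)

    @property
    def mean_gc(self) -> float:
        """Genome-wide GC fraction of the emitted sequence."""
        gc = total = 0
        for seq in self.sequences.values():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            gc += int(np.sum((arr == b"G") | (arr == b"C")))
            total += len(arr)
        return gc / total

    def chromosome_lengths(self) -> dict:
        return dict(self.chromosomes)


@dataclass
class BiasModel:
    """Linear model of MDA amplification bias on the log2-ratio scale.

    Expected log2 ratio at a probe = CNV shift + gc_coefficient * (probe GC -
    genome mean GC) - telomere_depression * exp(-d / telomere_decay), where d
    is the distance to the nearest chromosome end.  A zero model is a
    self-self hybridization.
    """

    gc_coefficient: float = 0.0
    telomere_depression: float = 0.0  # max depression at the very end, log2 units
    telomere_decay: float = 50_000.0  # bp
    cnv_segments: list = field(default_factory=list)  # (chrom, start, end, shift)
    noise_sd: float = 0.0
    kit_label: str = ""

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.telomere_decay <= 0:
            raise ValueError("telomere decay length must be positive")


def _markov_gc_states(n: int, gc_target: float, run_length: float, rng) -> np.ndarray:
    """Boolean strong(G/C) states from a 2-state Markov chain, via run lengths.

    Leave probabilities (1-g)/L from strong and g/L from weak give stationary
    P(strong) = g and GC-clustered runs of mean length ~L/(1-g) and ~L/g.
    """
    g = float(np.clip(gc_target, 0.0, 1.0))
    if g >= 1.0:
        return np.ones(n, dtype=bool)
    if g <= 0.0:
        return np.zeros(n, dtype=bool)
    leave_s = (1.0 - g) / run_length
    leave_w = g / run_length
    # Enough alternating runs to cover n with margin.
    n_runs = max(8, int(2.5 * n * (leave_s + leave_w) / 2) + 8)
    runs_s = rng.geometric(leave_s, size=n_runs)
    runs_w = rng.geometric(leave_w, size=n_runs)
    first_strong = rng.random() < g
    lengths = np.empty(2 * n_runs, dtype=np.int64)
    lengths[0::2] = runs_s if first_strong else runs_w
    lengths[1::2] = runs_w if first_strong else runs_s
    states = np.zeros(2 * n_runs, dtype=bool)
    states[0::2] = first_strong
    states[1::2] = not first_strong
    out = np.repeat(states, lengths)
    while out.size < n:  # pathological short draw; extend
        out = np.concatenate([out, np.repeat(states, lengths)])
    return out[:n]


def _simulate_sequence(length: int, cfg: GenomeConfig, rng) -> np.ndarray:
    """One chromosome as an S1 byte array with block-varying GC."""
    parts = []
    pos = 0
    while pos < length:
        block = min(cfg.gc_block_bp, length - pos)
        target = rng.normal(cfg.gc_mean, cfg.gc_block_sd)
        strong = _markov_gc_states(block, target, cfg.gc_run_length, rng)
        picks = rng.integers(0, 2, size=block)
        codes = np.where(strong, 1 + picks, 3 * picks)  # C/G vs A/T
        parts.append(_BASES[codes])
        pos += block
    return np.concatenate(parts)


def simulate_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Generate sequences and a probe layout; deterministic for a fixed seed.

    Probe GC is computed from the emitted sequence, so it is exact by
    construction.  The first probe of each chromosome starts at position 0 and
    successive starts are spaced uniformly within ``spacing_range``.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(child_seed(seed, "genome"))
    sequences = {}
    rows = []
    for name, length in cfg.chromosomes:
        seq = _simulate_sequence(length, cfg, rng)
        sequences[name] = seq.tobytes().decode()
        is_gc = np.concatenate([[0], np.cumsum((seq == b"G") | (seq == b"C"))])
        lo, hi = cfg.spacing_range
        start = 0
        while start + cfg.probe_length <= length:
            end = start + cfg.probe_length
            gc = (is_gc[end] - is_gc[start]) / cfg.probe_length
            rows.append((name, start, end, gc))
            start += int(rng.integers(lo, hi + 1))
    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])
    probes.insert(0, "probe_id", [f"P{i:06d}" for i in range(len(probes))])
    return GenomeModel(chromosomes=list(cfg.chromosomes), sequences=sequences, probes=probes)


def expected_log2_ratio(genome: GenomeModel, bias: BiasModel) -> np.ndarray:
    """Closed-form noiseless log2 ratio at every probe under a bias model."""
    probes = genome.probes
    mu = bias.gc_coefficient * (probes["gc"].to_numpy() - genome.mean_gc)
    if bias.telomere_depression:
        lengths = genome.chromosome_lengths()
        mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
        chrom_len = probes["chrom"].map(lengths).to_numpy(float)
        d = np.minimum(mid, chrom_len - mid)
        mu = mu - bias.telomere_depression * np.exp(-d / bias.telomere_decay)
    lengths = genome.chromosome_lengths()
    for chrom, start, end, shift in bias.cnv_segments:
        if chrom not in lengths or start < 0 or end > lengths[chrom] or start >= end:
            raise ValueError(f"CNV segment {(chrom, start, end)} outside the genome")
        mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
        mask = (probes["chrom"] == chrom).to_numpy() & (mid >= start) & (mid < end)
        mu = np.where(mask, mu + shift, mu)
    return mu


def simulate_hybridization(
    genome: GenomeModel,
    bias: BiasModel,
    replicate_seed,
    base_intensity: float = 1000.0,
    intensity_log2_sd: float = 0.3,
    labels: dict | None = None,
) -> ProbeArray:
    """One two-channel hybridization under an MDA bias model.

    The reference channel is unbiased (lognormal around ``base_intensity``);
    the test channel multiplies it by ``2**(mu + noise)`` with mu the
    closed-form bias and iid Gaussian log2 noise of sd ``noise_sd``.
    """
    rng = np.random.default_rng(replicate_seed)
    mu = expected_log2_ratio(genome, bias)
    n = len(genome.probes)
    ref = base_intensity * 2.0 ** rng.normal(0.0, intensity_log2_sd, size=n)
    noise = rng.normal(0.0, bias.noise_sd, size=n) if bias.noise_sd > 0 else 0.0
    test = ref * 2.0 ** (mu + noise)
    lab = dict(labels or {})
    lab.setdefault("kit", bias.kit_label)
    return ProbeArray(probes=genome.probes.copy(), test=test, ref=ref, labels=lab)


def simulate_ct_table(
    true_copy_numbers: dict,
    reference_ct_level: float = 27.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    sample: str = "sample",
) -> pd.DataFrame:
    """qPCR cycle-threshold table for loci of known copy number.

    Noiseless Ct_target = reference level - log_E(CN/2); each extra copy
    doubling removes one cycle at efficiency 2.  Copy number 0 reports the
    instrument ceiling ``MAX_CT``.  Columns: sample, locus, replicate,
    ct_target, ct_reference.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if any(cn < 0 for cn in true_copy_numbers.values()):
        raise ValueError("copy numbers must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "qpcr", sample))
    rows = []
    for locus, cn in true_copy_numbers.items():
        for rep in range(1, n_replicates + 1):
            if cn == 0:
                ct_t = MAX_CT
            else:
                ct_t = reference_ct_level - np.log2(cn / 2.0) / np.log2(efficiency)
            ct_r = reference_ct_level
            if noise_sd > 0:
                ct_t += rng.normal(0.0, noise_sd)
                ct_r += rng.normal(0.0, noise_sd)
            rows.append((sample, locus, rep, ct_t, ct_r))
    return pd.DataFrame(
        rows, columns=["sample", "locus", "replicate", "ct_target", "ct_reference"]
    )


def simulate_bidirectional_reads(
    reference: str,
    mutation_positions=(),
    nocall_positions=(),
    discordant_positions=(),
    seed: int = 0,
):
    """Forward/reverse base-call strings (same orientation, pre-aligned).

    Injected mutations are concordant on both strands and differ from the
    reference; no-calls appear as 'N' on one randomly chosen strand;
    discordant positions carry different called bases on the two strands.
    The three position sets must be disjoint and within the reference.
    """
    ref = reference.upper()
    n = len(ref)
    sets = [set(mutation_positions), set(nocall_positions), set(discordant_positions)]
    if sum(len(s) for s in sets) != len(set().union(*sets)):
        raise ValueError("mutation/no-call/discordant position sets must be disjoint")
    for s in sets:
        if any(p < 0 or p >= n for p in s):
            raise ValueError("position outside the reference")
    rng = np.random.default_rng(child_seed(seed, "reads"))
    fwd = list(ref)
    rev = list(ref)
    bases = "ACGT"
    for p in sorted(sets[0]):
        alt = rng.choice([b for b in bases if b != ref[p]])
        fwd[p] = rev[p] = alt
    for p in sorted(sets[1]):
        (fwd if rng.random() < 0.5 else rev)[p] = "N"
    for p in sorted(sets[2]):
        a, b = rng.choice(list(bases), size=2, replace=False)
        fwd[p], rev[p] = a, b
    return "".join(fwd), "".join(rev)


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    """Write name -> sequence mappings as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
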
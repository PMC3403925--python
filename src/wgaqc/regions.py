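"""Aberration regions and consistently under-amplified loci.

An aberration is a run of at least ``min_probes`` consecutive probes whose
segment-smoothed fold change exceeds a cutoff (default 3-fold) in a
consistent direction.  Regions found independently in every sample/kit group
are intersected at base-pair resolution into "consistently under-amplified"
loci, summarized as a genome fraction and by their GC content (MDA bias is
GC-linked: such regions are typically GC-richer than the genome average).

Coordinates are 0-based half-open throughout (BED-native).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import RatioProfile, fold_change

__all__ = [
    "Region",
    "aberration_report",
    "common_regions",
    "genome_fraction",
    "region_gc",
    "merge_intervals",
    "regions_to_bed",
    "read_bed",
    "cytoband_rollup",
]


@dataclass
class Region:
    """A contiguous aberrant interval with its supporting evidence."""

    chrom: str
    start: int
    end: int
    n_probes: int | None = None
    direction: str = ""  # "gain" | "loss"
    mean_fold: float | None = None
    groups: list = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


def aberration_report(
    smoothed: RatioProfile,
    fold_cutoff: float = 3.0,
    min_probes: int = 3,
    group: str = "",
) -> list:
    """Maximal runs of >= ``min_probes`` consecutive probes beyond the cutoff.

    Runs require a consistent direction (all gains or all losses); each run
    becomes one :class:`Region` spanning the first probe's start to the last
    probe's end, with the run's direction-agnostic mean fold.
    """
    if not smoothed.smoothed:
        raise ValueError("aberration reporting expects a segment-smoothed profile")
    if fold_cutoff <= 1:
        raise ValueError("fold cutoff must exceed 1")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    r = smoothed.log2_ratio
    beyond = fold_change(r) > fold_cutoff
    sign = np.sign(r)
    starts = smoothed.probes["start"].to_numpy()
    ends = smoothed.probes["end"].to_numpy()
    regions = []
    for chrom, sl in smoothed.chromosome_slices():
        i = sl.start
        while i < sl.stop:
            if beyond[i]:
                j = i
                while (
                    j + 1 < sl.stop and beyond[j + 1] and sign[j + 1] == sign[i]
                ):
                    j += 1
                n = j - i + 1
                if n >= min_probes:
                    regions.append(
                        Region(
                            chrom=str(chrom),
                            start=int(starts[i]),
                            end=int(ends[j]),
                            n_probes=n,
                            direction="loss" if sign[i] < 0 else "gain",
                            mean_fold=float(2.0 ** np.abs(np.mean(r[i : j + 1]))),
                            groups=[group] if group else [],
                        )
                    )
                i = j + 1
            else:
                i += 1
    return regions


def merge_intervals(intervals, gap_tolerance: int = 0):
    """Merge sorted-or-not (start, end) pairs, joining gaps <= gap_tolerance."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged = []
    for s, e in ivs:
        if merged and s - merged[-1][1] <= gap_tolerance:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect(a, b):
    """Intersection of two merged, sorted interval lists (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _by_chrom(regions):
    d = {}
    for r in regions:
        d.setdefault(r.chrom, []).append((r.start, r.end))
    return {c: merge_intervals(v) for c, v in d.items()}


def common_regions(per_group_regions, gap_tolerance: int = 0, direction: str | None = None):
    """Base-pair intersection of region sets across every group.

    ``direction`` optionally filters each group's regions (e.g. ``"loss"`` for
    under-amplification) before intersecting.  Fragments separated by at most
    ``gap_tolerance`` bp are merged afterwards.  The result is associative and
    order-independent across groups.
    """
    if len(per_group_regions) < 2:
        raise ValueError("need at least two groups to intersect")
    group_labels = []
    chrom_sets = []
    for regs in per_group_regions:
        if direction is not None:
            regs = [r for r in regs if r.direction == direction]
        labels = sorted({g for r in regs for g in r.groups})
        group_labels.append(labels)
        chrom_sets.append(_by_chrom(regs))
    chroms = set(chrom_sets[0])
    for cs in chrom_sets[1:]:
        chroms &= set(cs)
    support = sorted({g for labels in group_labels for g in labels})
    out = []
    for chrom in sorted(chroms):
        ivs = chrom_sets[0][chrom]
        for cs in chrom_sets[1:]:
            ivs = _intersect(ivs, cs[chrom])
            if not ivs:
                break
        for s, e in merge_intervals(ivs, gap_tolerance):
            out.append(
                Region(chrom=chrom, start=s, end=e, direction=direction or "", groups=support)
            )
    return out


def genome_fraction(regions, chromosome_lengths: dict) -> float:
    """Percent of the genome covered by the (merged) regions."""
    total = sum(chromosome_lengths.values())
    if total <= 0:
        raise ValueError("genome length must be positive")
    covered = 0
    for chrom, ivs in _by_chrom(regions).items():
        if chrom not in chromosome_lengths:
            raise ValueError(f"region on unknown chromosome {chrom}")
        if any(e > chromosome_lengths[chrom] or s < 0 for s, e in ivs):
            raise ValueError(f"region outside chromosome {chrom}")
        covered += sum(e - s for s, e in ivs)
    return 100.0 * covered / total


def _sequences_of(genome):
    if hasattr(genome, "sequences"):
        return genome.sequences
    if isinstance(genome, dict):
        return genome
    # Path to a FASTA file.
    from pyfaidx import Fasta

    fa = Fasta(str(genome))
    return {name: str(fa[name][:]) for name in fa.keys()}


def region_gc(regions, genome):
    """GC fraction per region plus the pooled (length-weighted) mean.

    GC = (#G + #C) / (#A + #C + #G + #T); ambiguity codes are excluded from
    both numerator and denominator.  ``genome`` may be a GenomeModel, a
    name -> sequence dict, or a FASTA path.  Returns ``(per_region, mean)``
    where the mean weights each region by its counted bases.
    """
    seqs = _sequences_of(genome)
    per_region = []
    gc_total = acgt_total = 0
    for r in regions:
        if r.chrom not in seqs:
            raise ValueError(f"no sequence for chromosome {r.chrom}")
        seq = seqs[r.chrom]
        if r.end > len(seq):
            raise ValueError(f"region extends beyond chromosome {r.chrom}")
        window = np.frombuffer(seq[r.start : r.end].upper().encode(), dtype="S1")
        gc = int(np.sum((window == b"G") | (window == b"C")))
        at = int(np.sum((window == b"A") | (window == b"T")))
        denom = gc + at
        per_region.append(gc / denom if denom else float("nan"))
        gc_total += gc
        acgt_total += denom
    mean = gc_total / acgt_total if acgt_total else float("nan")
    return per_region, mean


def regions_to_bed(regions, path) -> None:
    rows = [
        (
            r.chrom,
            r.start,
            r.end,
            r.direction or "region",
            f"{r.mean_fold:.3f}" if r.mean_fold is not None else ".",
        )
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path):
    """Read BED (>= 3 columns) into Region objects; column 4 becomes direction."""
    df = pd.read_csv(path, sep="\t", header=None)
    regions = []
    for row in df.itertuples(index=False):
        direction = str(row[3]) if len(row) > 3 and row[3] in ("gain", "loss") else ""
        regions.append(
            Region(chrom=str(row[0]), start=int(row[1]), end=int(row[2]), direction=direction)
        )
    return regions


def cytoband_rollup(regions, cytobands: pd.DataFrame):
    """Report the cytoband range covering each region (presentation parity).

    ``cytobands`` is BED4-style: chrom, start, end, name.  Returns a DataFrame
    with each region's covering band(s) as ``first_band - last_band``.
    """
    rows = []
    for r in regions:
        bands = cytobands[
            (cytobands["chrom"] == r.chrom)
            & (cytobands["end"] > r.start)
            & (cytobands["start"] < r.end)
        ]["name"].tolist()
        if not bands:
            label = "."
        elif bands[0] == bands[-1]:
            label = bands[0]
        else:
            label = f"{bands[0]} - {bands[-1]}"
        rows.append((r.chrom, r.start, r.end, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cytoband"])
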
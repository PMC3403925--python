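"""Replication fidelity from bidirectional Sanger sequencing.

Amplified DNA is sequenced on both strands and compared position-by-position
with the unamplified reference.  Positions where either strand made no base
call ('N') or where the two strands disagree are excluded; a mutation is a
position where both strands concordantly call a base different from the
reference.  With zero mutations in N examined bases, the induced mutation
rate is bounded as "fewer than 1 per N" (with the one-sided 95% rule-of-three
bound 3/N also available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Amplicon",
    "SequenceComparison",
    "amplicon_length",
    "read_primer_table",
    "compare_bidirectional",
    "exclusion_rate",
    "mutation_rate_bound",
    "global_align",
    "strip_gap_columns",
    "comparison_report",
]

_ALPHABET = set("ACGTN")


@dataclass
class Amplicon:
    """A sequenced PCR product defined by its primer pair.

    Primer coordinates follow the primer-table convention: 1-based, inclusive
    on both ends (everything else in this package is 0-based half-open).
    """

    name: str
    fwd_name: str
    fwd_start: int
    fwd_end: int
    fwd_seq: str
    rev_name: str
    rev_start: int
    rev_end: int
    rev_seq: str

    @property
    def expected_length(self) -> int:
        return amplicon_length(self.fwd_start, self.rev_end)


@dataclass
class SequenceComparison:
    """Per-position concordance bookkeeping for one read pair vs reference."""

    aligned: int
    examined: int
    excluded_nocall: int
    excluded_discordant: int
    mutations: list = field(default_factory=list)  # (position, ref base, called base)
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.examined + self.excluded_nocall + self.excluded_discordant != self.aligned:
            raise ValueError("examined + excluded counts must sum to aligned length")

    @property
    def excluded(self) -> int:
        return self.excluded_nocall + self.excluded_discordant


def amplicon_length(fwd_start: int, rev_end: int) -> int:
    """Amplicon size in bp from 1-based inclusive primer coordinates."""
    if rev_end < fwd_start:
        raise ValueError("reverse-primer end precedes forward-primer start")
    return rev_end - fwd_start + 1


def read_primer_table(path) -> list:
    """Primer-panel TSV -> amplicons.

    Columns: ``primer_name location sequence tm`` with paired ``<name>_F`` /
    ``<name>_R`` rows and ``location`` as ``start-end`` (1-based inclusive).
    """
    df = pd.read_csv(path, sep="\t")
    halves = {}
    for row in df.itertuples(index=False):
        name, strand = str(row.primer_name).rsplit("_", 1)
        start, end = (int(x) for x in str(row.location).split("-"))
        halves.setdefault(name, {})[strand.upper()] = (row.primer_name, start, end, row.sequence)
    amplicons = []
    for name, pair in halves.items():
        if "F" not in pair or "R" not in pair:
            raise ValueError(f"amplicon {name} lacks a primer pair")
        f, r = pair["F"], pair["R"]
        amplicons.append(
            Amplicon(
                name=name,
                fwd_name=f[0], fwd_start=f[1], fwd_end=f[2], fwd_seq=str(f[3]),
                rev_name=r[0], rev_start=min(r[1], r[2]), rev_end=max(r[1], r[2]),
                rev_seq=str(r[3]),
            )
        )
    return amplicons


def compare_bidirectional(fwd: str, rev: str, reference: str, labels: dict | None = None) -> SequenceComparison:
    """Classify every position of a pre-aligned read pair against the reference.

    Precedence: no-call (either strand 'N') before discordance (fwd != rev,
    both called) before mutation (fwd == rev != reference).  The classes are
    exhaustive and mutually exclusive, so counts sum to the aligned length.
    """
    fwd, rev, reference = fwd.upper(), rev.upper(), reference.upper()
    if not (len(fwd) == len(rev) == len(reference)):
        raise ValueError("forward, reverse and reference lengths differ")
    bad = (set(fwd) | set(rev) | set(reference)) - _ALPHABET
    if bad:
        raise ValueError(f"unexpected characters in base calls: {sorted(bad)}")
    nocall = discordant = 0
    mutations = []
    for i, (f, r, ref) in enumerate(zip(fwd, rev, reference)):
        if f == "N" or r == "N":
            nocall += 1
        elif f != r:
            discordant += 1
        elif f != ref:
            mutations.append((i, ref, f))
    n = len(reference)
    return SequenceComparison(
        aligned=n,
        examined=n - nocall - discordant,
        excluded_nocall=nocall,
        excluded_discordant=discordant,
        mutations=mutations,
        labels=dict(labels or {}),
    )


def exclusion_rate(excluded: int, aligned: int, decimals: int | None = None) -> float:
    """Percent of aligned positions excluded, optionally at report precision."""
    if aligned <= 0:
        raise ValueError("aligned base count must be positive")
    pct = 100.0 * excluded / aligned
    return round(pct, decimals) if decimals is not None else pct


def mutation_rate_bound(mutations: int, examined: int):
    """(point rate, upper bound, rule-of-three bound) per examined base.

    With zero mutations the upper bound follows the "fewer than 1 per N"
    convention (1/examined); the rule-of-three bound 3/examined is the exact
    one-sided 95% binomial bound for zero events.  With mutations observed,
    the point rate stands and the convention bounds are None.
    """
    if examined <= 0:
        raise ValueError("examined base count must be positive")
    point = mutations / examined
    if mutations == 0:
        return point, 1.0 / examined, 3.0 / examined
    return point, None, None


def global_align(a: str, b: str):
    """Convenience global aligner (match 1 / mismatch -1 / gap -2).

    Co-registers two reads that differ by offsets before per-position
    comparison; returns the two gapped strings.  Indel columns should be
    removed with :func:`strip_gap_columns` before applying the per-position
    rules, which are defined on substitution columns only.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def strip_gap_columns(*gapped: str):
    """Drop columns where any sequence has a gap; returns ungapped strings."""
    keep = [i for i in range(len(gapped[0])) if all(s[i] != "-" for s in gapped)]
    return tuple("".join(s[i] for i in keep) for s in gapped)


def comparison_report(comparisons) -> pd.DataFrame:
    """Tabulate comparisons: sample, method, bases examined, mutations, bound.

    The percentage column prints the explicit upper bound for zero mutations
    rather than an opaque "<x" cutoff.
    """
    rows = []
    for c in comparisons:
        point, upper, _ = mutation_rate_bound(len(c.mutations), c.examined)
        pct = 100.0 * (upper if upper is not None else point)
        rows.append(
            (
                c.labels.get("sample", ""),
                c.labels.get("kit", ""),
                c.examined,
                len(c.mutations),
                f"<{pct:.3f}" if not c.mutations else f"{pct:.3f}",
            )
        )
    return pd.DataFrame(
        rows, columns=["sample", "method", "nucleotides_examined", "mutations", "percentage"]
    )
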
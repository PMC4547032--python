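"""Uncorrected p-distances and per-group-pair summaries.

The p-distance between two aligned sequences is the proportion of differing
sites among the jointly resolved ones: columns where either sequence carries
a gap or an IUPAC ambiguity code are excluded pairwise.  Group summaries
average over all cross-group *specimen* pairs (alleles expanded to their
carriers), report the minimum over the same pairs, and attach a standard
error by two routes — the analytic SE of the pair mean and a seeded
site-bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .seqmodel import UNAMBIGUOUS_BASES, LocusAlignment

__all__ = [
    "DistanceMatrix",
    "PairSummary",
    "GroupDistanceSummary",
    "p_distance",
    "pairwise_distances",
    "group_distance_summary",
]


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance with pairwise deletion.

    Returns ``(proportion_of_differences, n_compared_sites)``.  Raises if the
    sequences differ in length or share no jointly resolved position.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    compared = 0
    diffs = 0
    for a, b in zip(seq_a, seq_b):
        if a in UNAMBIGUOUS_BASES and b in UNAMBIGUOUS_BASES:
            compared += 1
            if a != b:
                diffs += 1
    if compared == 0:
        raise ValueError("no jointly resolved positions")
    return diffs / compared, compared


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances with per-pair site counts."""

    ids: list[str]
    values: np.ndarray
    compared_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        self.compared_sites = np.asarray(self.compared_sites, dtype=int)
        if self.values.shape != (n, n) or self.compared_sites.shape != (n, n):
            raise ValueError("matrix shape disagrees with id list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("p-distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            rows.append(
                {
                    "id_a": self.ids[i],
                    "id_b": self.ids[j],
                    "p_distance": self.values[i, j],
                    "compared_sites": self.compared_sites[i, j],
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pairwise_distances(aln: LocusAlignment) -> DistanceMatrix:
    """All pairwise p-distances within an alignment."""
    ids = aln.ids
    n = len(ids)
    values = np.zeros((n, n))
    compared = np.full((n, n), aln.length, dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d, c = p_distance(aln.sequences[ids[i]], aln.sequences[ids[j]])
        values[i, j] = values[j, i] = d
        compared[i, j] = compared[j, i] = c
    return DistanceMatrix(ids, values, compared)


@dataclass(frozen=True)
class PairSummary:
    """Distance summary for one unordered group pair."""

    group_a: str
    group_b: str
    mean: float
    se: float
    minimum: float
    n_pairs: int
    se_bootstrap: float | None = None


@dataclass
class GroupDistanceSummary:
    """Per-group-pair means/minima, mirrorable as a two-triangle table
    (means below the diagonal, minima above)."""

    groups: list[str]
    pairs: dict[tuple[str, str], PairSummary]

    def get(self, a: str, b: str) -> PairSummary:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.pairs[key]

    def to_frame(self) -> pd.DataFrame:
        """Square table: means below the main diagonal, minima above."""
        g = self.groups
        df = pd.DataFrame("", index=g, columns=g, dtype=object)
        for (a, b), s in self.pairs.items():
            ia, ib = g.index(a), g.index(b)
            lo, hi = min(ia, ib), max(ia, ib)
            df.iloc[hi, lo] = f"{s.mean:.3f}±{s.se:.3f}"
            df.iloc[lo, hi] = f"{s.minimum:.3f}"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _cross_pairs(ids_a, ids_b, same_group):
    if same_group:
        return list(itertools.combinations(ids_a, 2))
    return list(itertools.product(ids_a, ids_b))


def group_distance_summary(
    matrix: DistanceMatrix,
    grouping: Mapping[str, str],
    alignment: LocusAlignment | None = None,
    include_within: bool = False,
    n_bootstrap: int = 500,
    seed: int | None = None,
) -> GroupDistanceSummary:
    """Summarise a distance matrix over group pairs.

    Every id in the matrix must be grouped.  For each unordered pair of
    distinct groups the mean and minimum over all cross-group specimen pairs
    are computed, with the analytic SE of the pair mean.  When ``alignment``
    is supplied (sequences keyed by the same specimen ids), a site-bootstrap
    SE (``n_bootstrap`` replicates, seeded) is attached as well.
    ``include_within`` adds within-group summaries over distinct pairs.
    """
    ungrouped = [i for i in matrix.ids if i not in grouping]
    if ungrouped:
        raise ValueError(f"ungrouped ids: {ungrouped}")
    groups: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in matrix.ids:
        g = grouping[sid]
        if g not in members:
            members[g] = []
            groups.append(g)
        members[g].append(sid)
    for g, ids in members.items():
        if not ids:
            raise ValueError(f"group {g!r} has no specimens")

    rng = np.random.default_rng(seed)
    pairs: dict[tuple[str, str], PairSummary] = {}
    group_pairs = list(itertools.combinations(groups, 2))
    if include_within:
        group_pairs += [(g, g) for g in groups]
    for ga, gb in group_pairs:
        id_pairs = _cross_pairs(members[ga], members[gb], ga == gb)
        if not id_pairs:
            continue
        dists = np.array([matrix.get(a, b) for a, b in id_pairs])
        se = float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else 0.0
        se_boot = None
        if alignment is not None:
            se_boot = _site_bootstrap_se(alignment, id_pairs, n_bootstrap, rng)
        pairs[(ga, gb)] = PairSummary(
            group_a=ga,
            group_b=gb,
            mean=float(dists.mean()),
            se=se,
            minimum=float(dists.min()),
            n_pairs=len(dists),
            se_bootstrap=se_boot,
        )
    return GroupDistanceSummary(groups=groups, pairs=pairs)


def _site_bootstrap_se(
    aln: LocusAlignment,
    id_pairs: list[tuple[str, str]],
    n_bootstrap: int,
    rng: np.random.Generator,
) -> float:
    """SE of the mean cross-pair p-distance under resampling of alignment
    columns with replacement."""
    length = aln.length
    # Encode mismatch indicators per pair per site (NaN where unresolved).
    indicators = np.empty((len(id_pairs), length))
    for k, (a, b) in enumerate(id_pairs):
        sa, sb = aln.sequences[a], aln.sequences[b]
        for col in range(length):
            ca, cb = sa[col], sb[col]
            if ca in UNAMBIGUOUS_BASES and cb in UNAMBIGUOUS_BASES:
                indicators[k, col] = 1.0 if ca != cb else 0.0
            else:
                indicators[k, col] = np.nan
    means = np.empty(n_bootstrap)
    for r in range(n_bootstrap):
        cols = rng.integers(0, length, size=length)
        sample = indicators[:, cols]
        per_pair = np.nanmean(sample, axis=1)
        means[r] = per_pair.mean()
    return float(means.std(ddof=1))
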
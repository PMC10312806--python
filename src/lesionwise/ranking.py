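"""Rank-then-aggregate challenge ranking with permutation significance.

Each team is ranked against its competitors independently for every
(subject, region, metric) slot — Dice descending (higher is better), HD95
ascending — with midranks for ties. Averaging a team's six slot ranks
within a subject gives its cumulative rank for that subject; averaging
cumulative ranks over subjects gives the final ranking score (FRS, lower
is better). A challenge with 59 subjects, 3 regions and 2 metrics thus
produces 59 x 3 x 2 = 354 individual rank slots per team.

Significance of the FRS gap between two teams is assessed with a paired
permutation (sign-flip) test on the per-subject cumulative ranks: each
permutation independently swaps the two teams' cumulative ranks within
each subject, and the p-value is the proportion of permutations whose FRS
difference is at least as extreme as the observed one. Exhaustive
enumeration of all 2^n swap patterns replaces Monte Carlo for small
cohorts; Monte Carlo p-values use add-one smoothing so they are never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import IncompleteGridError, ValidationError

#: metric -> True when larger values are better (descending rank order)
METRIC_ORIENTATION = {"lesionwise_dice": True, "lesionwise_hd95": False}

EXACT_ENUMERATION_MAX_SUBJECTS = 20


@dataclass(frozen=True)
class RankingParams:
    """Settings for the permutation test on FRS differences."""

    n_permutations: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


@dataclass
class RankingTable:
    """Ranks, cumulative ranks, final ranking scores, and significance."""

    teams: list[str]
    subjects: list[str]
    regions: list[str]
    metrics: list[str]
    #: long-format frame (team, subject, region, metric, score, rank)
    individual_ranks: pd.DataFrame
    #: (team x subject) frame of cumulative ranks
    cumulative_rank: pd.DataFrame
    #: final ranking score per team, ascending (lower is better)
    frs: pd.Series
    #: upper-triangular p-value frame in FRS order (filled by significance)
    pvalue_matrix: pd.DataFrame | None = None

    @property
    def slots_per_team(self) -> int:
        return len(self.subjects) * len(self.regions) * len(self.metrics)


def rank_teams(scores: pd.DataFrame) -> RankingTable:
    """Build the ranking table from a long-format score frame.

    Parameters
    ----------
    scores
        Long-format frame with columns ``team, subject, region, metric,
        value``. Every (team, subject, region, metric) cell must be
        present exactly once; higher Dice ranks better, lower HD95 ranks
        better, ties receive midranks.
    """
    required = {"team", "subject", "region", "metric", "value"}
    missing_cols = required - set(scores.columns)
    if missing_cols:
        raise ValidationError(f"score frame missing columns: {sorted(missing_cols)}")
    unknown = set(scores["metric"].unique()) - set(METRIC_ORIENTATION)
    if unknown:
        raise ValidationError(
            f"unknown metrics {sorted(unknown)}; expected {sorted(METRIC_ORIENTATION)}"
        )

    teams = sorted(scores["team"].unique())
    subjects = sorted(scores["subject"].unique())
    regions = sorted(scores["region"].unique())
    metrics = sorted(scores["metric"].unique())

    grid = scores.set_index(["team", "subject", "region", "metric"])["value"]
    if grid.index.has_duplicates:
        dups = grid.index[grid.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate score cells: {dups[:10]}")
    expected = pd.MultiIndex.from_product(
        [teams, subjects, regions, metrics],
        names=["team", "subject", "region", "metric"],
    )
    missing = expected.difference(grid.index)
    if len(missing):
        raise IncompleteGridError(missing.tolist())

    slot_index = pd.MultiIndex.from_product(
        [subjects, regions, metrics], names=["subject", "region", "metric"]
    )
    wide = grid.unstack("team").reindex(index=slot_index, columns=teams)
    rank_arr = np.empty(wide.shape, float)
    for metric in metrics:
        rows = wide.index.get_level_values("metric") == metric
        vals = wide.to_numpy()[rows]
        if METRIC_ORIENTATION[metric]:
            vals = -vals  # descending: higher score -> rank 1
        rank_arr[rows] = rankdata(vals, axis=1, method="average")
    ranks = pd.DataFrame(rank_arr, index=slot_index, columns=wide.columns)

    long_ranks = ranks.stack().rename("rank").reset_index()
    long_ranks = long_ranks.rename(columns={long_ranks.columns[3]: "team"})
    long_ranks = long_ranks.merge(
        grid.rename("value").reset_index(), on=["team", "subject", "region", "metric"]
    )

    cum = ranks.groupby(level="subject").mean().T  # team x subject
    cum = cum.loc[teams, subjects]
    frs = cum.mean(axis=1).sort_values(kind="stable")
    return RankingTable(
        teams=teams,
        subjects=subjects,
        regions=regions,
        metrics=metrics,
        individual_ranks=long_ranks,
        cumulative_rank=cum,
        frs=frs,
    )


def permutation_test(
    cumranks_a: np.ndarray,
    cumranks_b: np.ndarray,
    params: RankingParams | None = None,
) -> float:
    """Paired sign-flip test on the FRS difference between two teams.

    The observed statistic is ``mean(a) - mean(b)``. Each permutation
    independently swaps the two teams' cumulative ranks within each
    subject, which flips the sign of the per-subject difference. With at
    most ``EXACT_ENUMERATION_MAX_SUBJECTS`` subjects all 2^n patterns are
    enumerated exactly; otherwise ``n_permutations`` Monte Carlo draws are
    used with add-one smoothing, seeded for reproducibility.
    """
    params = params or RankingParams()
    a = np.asarray(cumranks_a, float)
    b = np.asarray(cumranks_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"paired cumulative-rank lists must have equal length, got {a.shape} and {b.shape}"
        )
    n = a.size
    if n == 0:
        raise ValidationError("empty cumulative-rank lists")
    d = a - b
    observed = d.mean()

    def exceeds(stat: np.ndarray) -> np.ndarray:
        if params.two_sided:
            return np.abs(stat) >= abs(observed) - 1e-12
        return stat >= observed - 1e-12

    if n <= EXACT_ENUMERATION_MAX_SUBJECTS:
        # exhaustive: all 2^n sign patterns
        signs = np.array([1.0, -1.0])
        stats = np.zeros(1)
        for di in d:  # iterative outer sum keeps memory at 2^n floats
            stats = (stats[:, None] + signs[None, :] * di / n).ravel()
        return float(np.mean(exceeds(stats)))

    rng = np.random.default_rng(params.seed)
    count = 0
    chunk = 20_000
    remaining = params.n_permutations
    while remaining > 0:
        m = min(chunk, remaining)
        flips = rng.integers(0, 2, size=(m, n)).astype(float) * 2 - 1
        stats = flips @ d / n
        count += int(np.sum(exceeds(stats)))
        remaining -= m
    return (count + 1) / (params.n_permutations + 1)


def pairwise_significance(
    table: RankingTable, params: RankingParams | None = None
) -> pd.DataFrame:
    """Permutation p-values for every team pair, upper-triangular in FRS order."""
    params = params or RankingParams()
    order = list(table.frs.index)
    mat = pd.DataFrame(np.nan, index=order, columns=order)
    for i, j in combinations(range(len(order)), 2):
        ta, tb = order[i], order[j]
        p = permutation_test(
            table.cumulative_rank.loc[ta].to_numpy(),
            table.cumulative_rank.loc[tb].to_numpy(),
            params,
        )
        mat.loc[ta, tb] = p
    table.pvalue_matrix = mat
    return mat
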
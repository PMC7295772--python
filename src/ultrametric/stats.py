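"""Nonparametric group comparisons across spawning-stage categories.

Metrics compared across oocyte ratio categories are skewed and the groups
small, so a Kruskal-Wallis omnibus test is followed by pairwise Wilcoxon
rank-sum tests with Benjamini-Hochberg adjustment, summarised as compact
significance letters (groups sharing a letter are not significantly
different at the chosen alpha).  Paired before/after designs (e.g. repeated
measurements of the same sample) use the Wilcoxon signed-rank test, exact
for small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError


@dataclass
class GroupComparison:
    metric: str
    kw_statistic: float
    kw_p: float
    pairwise_adjusted: pd.DataFrame  # symmetric matrix of BH-adjusted p-values
    pairwise_raw: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    try:
        stat, p = sps.kruskal(*arrays)
    except ValueError as exc:  # all values identical
        if "identical" in str(exc):
            return 0.0, 1.0
        raise
    return float(stat), float(p)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    # two-sided Wilcoxon rank-sum (Mann-Whitney), mid-ranks for ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def significance_letters(
    adjusted: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from a symmetric adjusted p-value matrix.

    Two groups share a letter iff their adjusted p-value is >= alpha (or
    undefined).  Letters are the maximal cliques of the
    not-significantly-different graph, ordered by their first group.
    """
    names = list(adjusted.index)
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        p = adjusted.loc[a, b]
        if not np.isfinite(p) or p >= alpha:
            g.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=names.index) for c in nx.find_cliques(g)),
        key=lambda c: (names.index(c[0]), names.index(c[-1])),
    )
    letters: dict[str, list[str]] = {n: [] for n in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for n in clique:
            letters[n].append(letter)
    return {n: "".join(v) for n, v in letters.items()}


def pairwise_wilcoxon_bh(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str = "",
) -> GroupComparison:
    """All-pairs rank-sum tests with Benjamini-Hochberg step-up adjustment.

    Pairs involving a group of fewer than 2 observations are reported as NaN
    and excluded from the adjustment family.  The adjusted matrix is
    symmetric with NaN on the diagonal; significance letters are computed at
    ``alpha`` from the adjusted matrix.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups.keys())
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        if arrays[a].size < 2 or arrays[b].size < 2:
            raw.append(np.nan)
        else:
            raw.append(_rank_sum_p(arrays[a], arrays[b]))
    raw_arr = np.array(raw)
    adj_arr = np.full_like(raw_arr, np.nan)
    defined = np.isfinite(raw_arr)
    if defined.any():
        adj_arr[defined] = multipletests(raw_arr[defined], method="fdr_bh")[1]

    def _matrix(vals: np.ndarray) -> pd.DataFrame:
        m = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        for (a, b), v in zip(pairs, vals):
            m.loc[a, b] = m.loc[b, a] = v
        return m

    adj = _matrix(adj_arr)
    kw_stat, kw_p = kruskal_wallis(groups)
    return GroupComparison(
        metric=metric,
        kw_statistic=kw_stat,
        kw_p=kw_p,
        pairwise_adjusted=adj,
        pairwise_raw=_matrix(raw_arr),
        letters=significance_letters(adj, alpha),
        alpha=alpha,
    )


def wilcoxon_paired(
    before: Sequence[float],
    after: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired measurements.

    Zero differences are discarded; the null distribution is exact for up to
    25 remaining untied differences and a normal approximation otherwise.
    Raises :class:`DegenerateDataError` when every pair is tied.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size or b.size == 0:
        raise ValueError("before/after must be equal-length non-empty vectors")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    untied = np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if (nonzero.size <= 25 and untied) else "approx"
    res = sps.wilcoxon(
        b, a, alternative=alternative, method=method, zero_method="wilcox"
    )
    return float(res.statistic), float(res.pvalue)
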
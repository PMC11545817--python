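"""Univariate screening of isotope markers across origins and harvest years.

For each marker the route is gated on per-group Shapiro–Wilk normality: when
every group passes at the chosen alpha, a one-way ANOVA with Scheffé's post
hoc test is used; otherwise Kruskal–Wallis with pairwise Mann–Whitney U
(Bonferroni-corrected) takes over.  Pairwise outcomes are condensed into a
compact letter display ordered by descending group mean (``a`` = highest),
the convention used in food-chemistry summary tables.

The gate is applied per group rather than to pooled residuals: a single
non-normal group is enough to route a marker down the nonparametric path.
No multiple-testing correction is applied across markers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import IsotopeDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GroupTestResult:
    """Outcome of one marker's across-group comparison."""

    marker: str
    test_used: str  # "anova" | "kruskal_wallis" | "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    letters: dict[str, str]  # group -> letter string
    pairwise_significant: dict[frozenset, bool]
    group_means: dict[str, float]


def _as_groups(values_by_group: dict) -> dict[str, np.ndarray]:
    return {str(g): np.asarray(v, dtype=float) for g, v in values_by_group.items()}


def normality_gate(values_by_group: dict, alpha: float = DEFAULT_ALPHA) -> str:
    """Choose "anova" or "kruskal_wallis" from per-group Shapiro–Wilk tests.

    Returns "anova" iff every group's Shapiro–Wilk p-value is >= *alpha*.
    Groups need n >= 3 (the test is undefined below that).  A zero-variance
    group cannot be tested for normality and routes to "kruskal_wallis" (the
    documented degenerate rule).
    """
    groups = _as_groups(values_by_group)
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r}: Shapiro–Wilk needs n >= 3")
    for name, vals in groups.items():
        if np.ptp(vals) == 0:
            logger.warning("group %r constant; routing to kruskal_wallis", name)
            return "kruskal_wallis"
        if stats.shapiro(vals).pvalue < alpha:
            return "kruskal_wallis"
    return "anova"


def assign_letters(
    group_means: dict[str, float], significant: dict[frozenset, bool]
) -> dict[str, str]:
    """Compact letter display from a pairwise significance matrix.

    Letters label the maximal cliques of the "not significantly different"
    graph, ordered by the highest group mean inside each clique, so ``a``
    always marks the top group.  Two groups share a letter iff they are not
    significantly different; groups sharing no letter differ significantly.
    """
    names = sorted(group_means, key=lambda g: -group_means[g])
    k = len(names)

    def compatible(i: int, j: int) -> bool:
        return not significant.get(frozenset((names[i], names[j])), False)

    # maximal cliques by brute force (k is small: origins or years)
    cliques: list[frozenset] = []
    for r in range(k, 0, -1):
        for combo in itertools.combinations(range(k), r):
            if any(set(combo) <= c for c in cliques):
                continue
            if all(compatible(i, j) for i, j in itertools.combinations(combo, 2)):
                cliques.append(frozenset(combo))
    # order cliques by their best (highest-mean) member; names sorted desc
    cliques.sort(key=lambda c: tuple(sorted(c)))
    letters = {name: "" for name in names}
    for rank, clique in enumerate(cliques):
        letter = chr(ord("a") + rank)
        for i in sorted(clique):
            letters[names[i]] += letter
    return letters


def _pairwise_dict(pairs: dict) -> dict[frozenset, bool]:
    return {frozenset(p): bool(s) for p, s in pairs.items()}


def anova_scheffe(
    values_by_group: dict, alpha: float = DEFAULT_ALPHA, marker: str = ""
) -> GroupTestResult:
    """One-way ANOVA with Scheffé's post hoc test and a letter display.

    The Scheffé criterion declares the contrast between groups i and j
    significant iff

        (mean_i - mean_j)^2 > (k-1) * F_crit(alpha; k-1, N-k) * MSE * (1/n_i + 1/n_j)

    Zero within-group variance is handled without division: equal means give
    F = 0, p = 1; unequal means give p = 0 and every unequal pair significant.
    """
    groups = _as_groups(values_by_group)
    names = list(groups)
    if len(names) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(names)
    ns = {g: len(v) for g, v in groups.items()}
    N = sum(ns.values())
    means = {g: float(v.mean()) for g, v in groups.items()}
    grand = sum(v.sum() for v in groups.values()) / N
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ssw = sum(float(((v - means[g]) ** 2).sum()) for g, v in groups.items())
    df_b, df_w = k - 1, N - k

    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
            sig = {frozenset((a, b)): False for a, b in itertools.combinations(names, 2)}
        else:
            f_stat, p = np.inf, 0.0
            sig = {
                frozenset((a, b)): means[a] != means[b]
                for a, b in itertools.combinations(names, 2)
            }
    else:
        mse = ssw / df_w
        f_stat = (ssb / df_b) / mse
        p = float(stats.f.sf(f_stat, df_b, df_w))
        f_crit = stats.f.ppf(1 - alpha, df_b, df_w)
        sig = {}
        for a, b in itertools.combinations(names, 2):
            crit = (k - 1) * f_crit * mse * (1 / ns[a] + 1 / ns[b])
            sig[frozenset((a, b))] = (means[a] - means[b]) ** 2 > crit
    return GroupTestResult(
        marker=marker,
        test_used="anova",
        statistic=float(f_stat),
        p_value=p,
        letters=assign_letters(means, sig),
        pairwise_significant=sig,
        group_means=means,
    )


def kruskal_letters(
    values_by_group: dict, alpha: float = DEFAULT_ALPHA, marker: str = ""
) -> GroupTestResult:
    """Kruskal–Wallis global test with Bonferroni-corrected pairwise
    Mann–Whitney U for the letter display.

    The global H statistic uses the standard tie correction.  When all
    values across all groups are tied, H is undefined: p = 1 and a single
    shared letter are returned.
    """
    groups = _as_groups(values_by_group)
    names = list(groups)
    if len(names) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    means = {g: float(v.mean()) for g, v in groups.items()}
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        sig = {frozenset(p): False for p in itertools.combinations(names, 2)}
        return GroupTestResult(
            marker, "kruskal_wallis", 0.0, 1.0, assign_letters(means, sig), sig, means
        )
    h_stat, p = stats.kruskal(*groups.values())
    n_pairs = len(names) * (len(names) - 1) // 2
    sig = {}
    for a, b in itertools.combinations(names, 2):
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            sig[frozenset((a, b))] = False
            continue
        p_pair = stats.mannwhitneyu(
            groups[a], groups[b], alternative="two-sided"
        ).pvalue
        sig[frozenset((a, b))] = min(1.0, p_pair * n_pairs) < alpha
    return GroupTestResult(
        marker, "kruskal_wallis", float(h_stat), float(p),
        assign_letters(means, sig), sig, means,
    )


def year_effect_test(
    values_by_year: dict, alpha: float = DEFAULT_ALPHA, marker: str = ""
) -> GroupTestResult:
    """Interannual comparison of one marker within one origin.

    Two years: Student's t-test when both years pass Shapiro–Wilk, else
    Mann–Whitney U.  More than two years: routed through
    :func:`normality_gate` to ANOVA/Scheffé or Kruskal–Wallis.
    """
    groups = _as_groups(values_by_year)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 harvest years")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("each year needs n >= 3")
    if len(names) > 2:
        route = normality_gate(groups, alpha)
        fn = anova_scheffe if route == "anova" else kruskal_letters
        return fn(groups, alpha, marker=marker)
    a, b = names
    means = {g: float(v.mean()) for g, v in groups.items()}
    va, vb = groups[a], groups[b]
    degenerate = np.ptp(va) == 0 or np.ptp(vb) == 0
    normal = (
        not degenerate
        and stats.shapiro(va).pvalue >= alpha
        and stats.shapiro(vb).pvalue >= alpha
    )
    if normal:
        stat, p = stats.ttest_ind(va, vb, equal_var=True)
        test = "t_test"
    elif np.ptp(np.concatenate([va, vb])) == 0:
        stat, p, test = 0.0, 1.0, "mann_whitney"
    else:
        stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        test = "mann_whitney"
    sig = {frozenset((a, b)): float(p) < alpha}
    return GroupTestResult(
        marker, test, float(stat), float(p), assign_letters(means, sig), sig, means
    )


def screen_dataset(
    dataset: IsotopeDataset, alpha: float = DEFAULT_ALPHA
) -> list[GroupTestResult]:
    """Across-origin test for every marker, route chosen per marker."""
    results = []
    for j, marker in enumerate(dataset.marker_names):
        groups = {
            origin: dataset.X[dataset.origins == origin, j]
            for origin in dataset.class_labels
        }
        route = normality_gate(groups, alpha)
        logger.info("marker %s routed to %s", marker, route)
        fn = anova_scheffe if route == "anova" else kruskal_letters
        results.append(fn(groups, alpha, marker=marker))
    return results


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Summary-table layout: one row per marker, letters per group."""
    groups = sorted({g for r in results for g in r.letters})
    rows = []
    for r in results:
        row = {"marker": r.marker, "test": r.test_used, "p_value": r.p_value}
        for g in groups:
            row[f"letters_{g}"] = r.letters.get(g, "")
            row[f"mean_{g}"] = r.group_means.get(g, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
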
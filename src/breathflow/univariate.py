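"""Univariate follow-up statistics: normality screening, omnibus
group/timepoint tests, post hoc comparisons, and summary matrices.

The decision rule mirrors common practice for skewed concentration data:
a Lilliefors test (Kolmogorov-Smirnov against a normal with estimated
moments, Monte-Carlo null) decides per variable between the parametric
branch (one-way ANOVA + Tukey HSD) and the non-parametric branch
(tie-corrected Kruskal-Wallis + Tukey-Kramer on group mean ranks).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GROUPS, SCFA_IONS, TIMEPOINTS

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# Lilliefors


def _ks_normal_statistic(x: np.ndarray) -> float:
    """KS distance of studentized data to the standard normal CDF."""
    n = x.shape[-1]
    z = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, ddof=1,
                                                     keepdims=True)
    z = np.sort(z, axis=-1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_draws: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, n)))
    draws = rng.standard_normal((n_draws, n))
    return np.sort(_ks_normal_statistic(draws))


def lilliefors(x, variable: str = "", alpha: float = 0.05,
               n_draws: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The statistic is the KS distance between the empirical CDF of the
    studentized sample and the standard normal; its null distribution
    (normal data, estimated mean and sd) is simulated once per sample
    size and cached.  A constant sample is degenerate and reported
    non-normal with a note.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if np.ptp(x) == 0:
        return TestResult(variable, "lilliefors", np.inf, 0.0, alpha=alpha,
                          note="constant sample; degenerate, non-normal")
    d = float(_ks_normal_statistic(x[None, :])[0])
    null = _lilliefors_null(len(x), n_draws, seed)
    p = float((np.sum(null >= d) + 1) / (len(null) + 1))
    return TestResult(variable, "lilliefors", d, p, alpha=alpha)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    all_values = np.concatenate(groups)
    n = len(all_values)
    ranks = stats.rankdata(all_values)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_values, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(groups: dict[str, np.ndarray] | list,
                   variable: str = "", alpha: float = 0.05,
                   method: str = "auto") -> TestResult:
    """Kruskal-Wallis omnibus test over two or more groups.

    ``method``: ``"chi2"`` uses the chi-square approximation with
    df = g - 1; ``"exact"`` enumerates all assignments of the pooled
    values to the group sizes (total n <= 10); ``"auto"`` picks exact for
    small samples.  All-identical values give H = 0, p = 1.
    """
    if isinstance(groups, dict):
        names = tuple(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = tuple(f"g{i+1}" for i in range(len(groups)))
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2 or any(len(g) < 1 for g in data):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(len(g) for g in data)
    if n < 3:
        raise ValueError("need >= 3 observations in total")
    if np.ptp(np.concatenate(data)) == 0:
        return TestResult(variable, "kruskal-wallis", 0.0, 1.0, names,
                          alpha, note="all values identical")
    h = _h_statistic(data)
    if method == "auto":
        method = "exact" if n <= 10 else "chi2"
    if method == "exact":
        p = _exact_kw_p(data, h)
    else:
        p = float(stats.chi2.sf(h, df=len(data) - 1))
    return TestResult(variable, "kruskal-wallis", h, p, names, alpha)


def _exact_kw_p(data: list[np.ndarray], h_obs: float) -> float:
    """Permutation p-value by full enumeration of group assignments."""
    pooled = np.concatenate(data)
    n = len(pooled)
    if n > 10:
        raise ValueError("exact enumeration limited to total n <= 10")
    sizes = [len(g) for g in data]
    indices = list(range(n))
    count = total = 0

    def recurse(remaining: list[int], k: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if k == len(sizes) - 1:
            groups = chosen + [pooled[remaining]]
            total += 1
            if _h_statistic(groups) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = [i for i in remaining if i not in set(combo)]
            recurse(rest, k + 1, chosen + [pooled[list(combo)]])

    recurse(indices, 0, [])
    return count / total


# ---------------------------------------------------------------------------
# Post hoc


def posthoc_mean_ranks(groups: dict[str, np.ndarray], variable: str = "",
                       alpha: float = 0.05,
                       method: str = "tukey") -> list[TestResult]:
    """Pairwise comparisons of group mean ranks after Kruskal-Wallis.

    ``method="tukey"`` (default) is the Tukey-Kramer procedure on mean
    ranks against the studentized-range distribution — the standard post
    hoc companion to a Kruskal-Wallis fit in common statistical software.
    ``method="dunn"`` gives Dunn's z tests with Holm adjustment instead.
    Empty groups are skipped.
    """
    names = [k for k in groups if len(groups[k])]
    data = [np.asarray(groups[k], dtype=float) for k in names]
    sizes = np.array([len(g) for g in data])
    n = sizes.sum()
    ranks = stats.rankdata(np.concatenate(data))
    mean_ranks, start = [], 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, counts = np.unique(np.concatenate(data), return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    var_rank = n * (n + 1) / 12.0 * tie
    k = len(names)
    results = []
    raw = []
    for (i, j) in itertools.combinations(range(k), 2):
        diff = abs(mean_ranks[i] - mean_ranks[j])
        se2 = var_rank * (1.0 / sizes[i] + 1.0 / sizes[j])
        if method == "tukey":
            q = diff / np.sqrt(se2 / 2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            results.append(TestResult(variable, "posthoc", q, min(p, 1.0),
                                      (names[i], names[j]), alpha))
        elif method == "dunn":
            z = diff / np.sqrt(se2)
            raw.append((z, 2 * float(stats.norm.sf(z)), (names[i], names[j])))
        else:
            raise ValueError(f"unknown post hoc method {method!r}")
    if method == "dunn":
        order = np.argsort([-z for z, _, _ in raw])
        m = len(raw)
        adj, running = [None] * m, 0.0
        for rank_i, idx in enumerate(order):
            z, p, pair = raw[idx]
            running = max(running, min(1.0, (m - rank_i) * p))
            adj[idx] = (z, running, pair)
        results = [TestResult(variable, "posthoc", z, p_adj, pair, alpha)
                   for z, p_adj, pair in adj]
    return results


def anova_with_tukey(groups: dict[str, np.ndarray], variable: str = "",
                     alpha: float = 0.05
                     ) -> tuple[TestResult, list[TestResult]]:
    """Parametric branch: one-way ANOVA followed by Tukey HSD."""
    names = [k for k in groups if len(groups[k])]
    data = [np.asarray(groups[k], dtype=float) for k in names]
    f, p = stats.f_oneway(*data)
    omnibus = TestResult(variable, "anova", float(f), float(p),
                         tuple(names), alpha)
    hsd = stats.tukey_hsd(*data)
    posthoc = [
        TestResult(variable, "posthoc", float(hsd.statistic[i, j]),
                   float(hsd.pvalue[i, j]), (names[i], names[j]), alpha)
        for i, j in itertools.combinations(range(len(names)), 2)]
    return omnibus, posthoc


def analyze_variable(groups: dict[str, np.ndarray], variable: str = "",
                  alpha: float = 0.05, seed: int = 0
                  ) -> tuple[TestResult, TestResult, list[TestResult]]:
    """Full decision rule for one variable.

    Lilliefors on the pooled values decides the branch: normal data go to
    ANOVA + Tukey HSD, non-normal to Kruskal-Wallis + Tukey-Kramer on
    mean ranks.  Returns (normality, omnibus, posthoc results).
    """
    pooled = np.concatenate([np.asarray(v, float) for v in groups.values()])
    norm = lilliefors(pooled, variable=variable, alpha=alpha, seed=seed)
    if norm.significant:  # non-normal
        omnibus = kruskal_wallis(groups, variable=variable, alpha=alpha,
                                 method="chi2")
        posthoc = posthoc_mean_ranks(groups, variable=variable, alpha=alpha)
    else:
        omnibus, posthoc = anova_with_tukey(groups, variable=variable,
                                            alpha=alpha)
    return norm, omnibus, posthoc


# ---------------------------------------------------------------------------
# SCFA cluster and summary matrices


def replicate_means(values: pd.DataFrame) -> pd.DataFrame:
    """Average duplicates: one row per participant-timepoint.

    Expects a (participant, timepoint, replicate) row index; using the
    replicate mean as the analysis unit avoids pseudo-replication.
    """
    return values.groupby(level=["participant_id", "timepoint"],
                          sort=False).mean()


def scfa_cluster_series(values: pd.DataFrame, design: pd.DataFrame,
                        ions: tuple[str, ...] = SCFA_IONS
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Total SCFA concentration per sample and its group x timepoint summary.

    Returns (per participant-timepoint totals, summary frame with mean,
    standard error and n per group x timepoint cell).  The total is the
    sum of the three parent acid ions; fragments are excluded to avoid
    double counting.
    """
    missing = [i for i in ions if i not in values.columns]
    if missing:
        raise ValueError(f"SCFA ions missing from the matrix: {missing}")
    per_sample = replicate_means(values[list(ions)]).sum(axis=1)
    per_sample.name = "scfa_ppbv"
    frame = per_sample.reset_index()
    group_of = design.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    frame["group"] = frame["participant_id"].map(group_of)
    summary = (frame.groupby(["group", "timepoint"])["scfa_ppbv"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n="count")
               .reset_index())
    return per_sample, summary


@dataclass
class RelativeChangeMatrix:
    """Row-scaled median concentrations relative to a reference cell."""

    values: pd.DataFrame        # compounds x (group, timepoint) cells
    reference: tuple[str, str]
    flat_rows: list[str] = field(default_factory=list)


def relative_change_matrix(values: pd.DataFrame, design: pd.DataFrame,
                           reference: tuple[str, str] = ("St0", "Day0")
                           ) -> RelativeChangeMatrix:
    """Median concentration per group x timepoint, centred and range scaled.

    Per compound: the cell medians are centred on the reference cell
    (baseline of non-statin users by default) and divided by the range
    (max - min) of the centred medians, so each row spans an interval of
    length 1 starting at 0 for the row minimum.  Zero-range rows are
    reported all-zero and flagged.
    """
    per_sample = replicate_means(values)
    frame = per_sample.reset_index()
    group_of = design.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    frame["group"] = frame["participant_id"].map(group_of)
    medians = frame.drop(columns="participant_id").groupby(
        ["group", "timepoint"]).median()
    if reference not in medians.index:
        raise ValueError(f"reference cell {reference} is empty")
    cols = [tp for tp in TIMEPOINTS if tp in set(frame["timepoint"])] or \
        sorted(set(frame["timepoint"]))
    grps = [g for g in GROUPS if g in set(frame["group"])] or \
        sorted(set(frame["group"]))
    cells = [(g, tp) for g in grps for tp in cols]
    centred = medians.loc[cells].T.sub(medians.loc[reference], axis=0)
    span = centred.max(axis=1) - centred.min(axis=1)
    flat = list(span[span == 0].index)
    for name in flat:
        logger.info("compound %s is constant across cells; zero row", name)
    span = span.replace(0.0, 1.0)
    scaled = centred.div(span, axis=0)
    scaled.loc[flat] = 0.0
    return RelativeChangeMatrix(values=scaled, reference=reference,
                                flat_rows=flat)
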
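"""Planned nonparametric test battery for the extreme-group comparisons.

Normality is screened with Shapiro–Wilk; differences between the five
discrete-emotion groups use the Kruskal–Wallis rank-sum test with
Tukey-HSD pairwise follow-up at familywise α = 0.05 (a rank-based Dunn
follow-up is available behind a flag); high/low dimensional contrasts
and the gender comparison use the two-sample Wilcoxon rank-sum
(Mann–Whitney U) test with continuity correction, exact when the sample
product is small and there are no ties.  Effect sizes are Cohen's d;
group medians get percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "normality_screen", "kruskal_wallis", "tukey_hsd",
           "dunn_posthoc", "wilcoxon_rank_sum", "cohens_d",
           "bootstrap_median_ci", "significance_stars"]

EXACT_LIMIT = 400  # use exact Mann-Whitney enumeration when n*m <= this


def significance_stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    effect_size_d: float | None = None
    groups: list = field(default_factory=list)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def normality_screen(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one sample (3 ≤ n ≤ 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample; normality undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups, labels=None) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with χ² p on k−1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values tied; H undefined")
    h, p = stats.kruskal(*groups)
    return TestResult("kruskal-wallis", float(h), float(p),
                      groups=list(labels) if labels is not None else [])


def tukey_hsd(groups, labels=None, alpha_fw: float = 0.05) -> pd.DataFrame:
    """Studentised-range pairwise comparisons, familywise-adjusted p.

    Returns one row per pair with the mean difference, adjusted p,
    significance stars, and a flag at ``alpha_fw``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_tot = sum(len(g) for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        raise ValueError("zero within-group variance; HSD undefined")
    labels = list(labels) if labels is not None else list(range(len(groups)))
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group_1": labels[i], "group_2": labels[j],
            "diff": float(groups[i].mean() - groups[j].mean()),
            "p_adj": p, "stars": significance_stars(p),
            "significant": p < alpha_fw,
        })
    return pd.DataFrame(rows)


def dunn_posthoc(groups, labels=None, alpha_fw: float = 0.05) -> pd.DataFrame:
    """Rank-based Dunn pairwise z tests with Šidák familywise adjustment.

    Non-default alternative to :func:`tukey_hsd` for users preferring a
    follow-up on the same ranks as the omnibus test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else list(range(len(groups)))
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    m = len(list(combinations(range(len(groups)), 2)))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        num = rank_groups[i].mean() - rank_groups[j].mean()
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = num / se
        p = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        rows.append({"group_1": labels[i], "group_2": labels[j], "z": float(z),
                     "p_adj": float(p_adj), "stars": significance_stars(p_adj),
                     "significant": p_adj < alpha_fw})
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> TestResult:
    """Two-sided Mann–Whitney U (Wilcoxon rank-sum); unequal lengths allowed.

    Exact enumeration when n·m ≤ 400 and the data carry no ties; tied
    data at very small n (≤ 12 total) get a full tie-aware permutation
    enumeration (scipy's closed-form exact null does not correct for
    ties); otherwise the tie-corrected normal approximation with
    optional continuity correction.  The reported statistic is U for
    ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) * len(y) <= EXACT_LIMIT and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=continuity)
        u, p = float(res.statistic), float(res.pvalue)
    elif has_ties and len(x) + len(y) <= 12:
        method = "enumeration"
        u, p = _exact_tied_mw(x, y)
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=continuity)
        u, p = float(res.statistic), float(res.pvalue)
    d = cohens_d(x, y) if len(x) >= 2 and len(y) >= 2 and _pooled_sd(x, y) > 0 else None
    return TestResult(f"wilcoxon-rank-sum ({method})", u, min(p, 1.0),
                      effect_size_d=d)


def _exact_tied_mw(x, y) -> tuple[float, float]:
    """Full tie-aware enumeration of the two-sided Mann-Whitney null.

    Counts assignments at least as far from the null mean nm/2 as the
    observed U (the permutation distribution of U is symmetric, so this
    equals the summed symmetric tails).
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    mu = len(x) * len(y) / 2.0
    offset = n * (n + 1) / 2.0
    u_obs = ranks[:n].sum() - offset
    extreme = total = 0
    for c in combinations(range(len(pooled)), n):
        u = ranks[list(c)].sum() - offset
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def _pooled_sd(x, y) -> float:
    nx, ny = len(x), len(y)
    return float(np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                         / (nx + ny - 2)))


def cohens_d(x, y) -> float:
    """(mean x − mean y) / pooled sd, with (n−1) pooling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    sd = _pooled_sd(x, y)
    if sd == 0:
        raise ValueError("zero pooled sd; d undefined")
    return float((x.mean() - y.mean()) / sd)


def bootstrap_median_ci(values, n_boot: int = 5000, level: float = 0.95,
                        seed=None, rng: np.random.Generator | None = None
                        ) -> tuple[float, float, float]:
    """Percentile bootstrap CI around the sample median.

    Returns (median, lo, hi); deterministic for a fixed seed/rng.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    meds = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(np.median(x)), float(lo), float(hi)
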
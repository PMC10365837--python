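"""The study's statistical decision workflow.

Per dataset: (1) remove outliers per group with the ROUT procedure at
Q = 1% (robust regression — here a robust constant-location fit — followed
by an FDR-controlled test on the scaled residuals); (2) gate on a
Shapiro-Wilk normality test at α = 0.05 in every group; (3) run the test
the design calls for — two groups: t-test or Mann-Whitney; more than two:
one-way ANOVA + Tukey or Kruskal-Wallis + Dunn; two-factor designs:
two-way ANOVA with Tukey (more than two groups) or Sidak (two groups) post
hocs. All tests are two-sided; significance stars follow the *p<0.05,
**p<0.01, ***p<0.001, ****p<0.0001 convention.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTable",
    "StatsReport",
    "rout_outliers",
    "normality_gate",
    "select_and_run",
    "run_workflow",
    "significance_stars",
]


@dataclass
class GroupTable:
    """Tidy observations: value, group label, optional second factor.

    ``design`` is one of ``two_groups``, ``multi_group``, ``two_factor``;
    when omitted it is inferred from the labels.
    """

    data: pd.DataFrame  # columns: value, group[, factor2]
    design: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if "value" not in df or "group" not in df:
            raise ValueError("table needs 'value' and 'group' columns")
        if (df.groupby("group").size() < 2).any():
            raise ValueError("every group needs >= 2 observations")
        n_groups = df["group"].nunique()
        if not self.design:
            if "factor2" in df and df["factor2"].nunique() > 1:
                self.design = "two_factor"
            else:
                self.design = "two_groups" if n_groups == 2 else "multi_group"
        if self.design in ("two_groups",) and n_groups != 2:
            raise ValueError("two_groups design needs exactly 2 groups")
        if self.design == "two_factor" and "factor2" not in df:
            raise ValueError("two_factor design needs a 'factor2' column")

    def groups(self) -> dict[str, np.ndarray]:
        return {g: grp["value"].to_numpy(float) for g, grp in self.data.groupby("group")}


@dataclass
class StatsReport:
    design: str
    branch: str  # parametric | nonparametric
    test_name: str
    statistic: float
    pvalue: float
    stars: str = field(init=False)
    posthoc: pd.DataFrame | None = None
    outliers_removed: dict | None = None
    normality_pvalues: dict | None = None

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.pvalue)


def significance_stars(p: float) -> str:
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# ROUT outlier removal (robust location fit + FDR step-up on residuals)


def _robust_location(values: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """IRLS constant-location fit with Lorentzian weights.

    Weights are ``1 / (1 + (r / RSDR)^2)`` where RSDR is the robust residual
    scale: the 68.27th percentile of |residuals| with the small-sample
    correction n/(n - K), K = 1 parameter.
    """
    n = len(values)
    loc = float(np.median(values))
    scale = _rsdr(values - loc, n)
    if scale == 0:
        return loc, 0.0
    for _ in range(max_iter):
        r = values - loc
        w = 1.0 / (1.0 + (r / scale) ** 2)
        new = float(np.sum(w * values) / np.sum(w))
        scale_new = _rsdr(values - new, n)
        if abs(new - loc) < tol * max(1.0, abs(loc)) and abs(scale_new - scale) < tol * scale:
            loc, scale = new, scale_new
            break
        loc, scale = new, scale_new
        if scale == 0:
            break
    return loc, scale


def _rsdr(residuals: np.ndarray, n: int, k_params: int = 1) -> float:
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / max(n - k_params, 1)


def rout_outliers(values, q_percent: float = 1.0):
    """Flag outliers with the ROUT construction at FDR Q (percent).

    The location is fit robustly (Lorentzian IRLS), residuals are scaled by
    the RSDR into t-like scores with n − 1 degrees of freedom, and flags are
    assigned by a Benjamini-Hochberg step-up at rate Q on the two-sided tail
    probabilities, so at most a fraction ~Q of clean points is removed in
    expectation. Returns ``(clean_values, outlier_values, is_outlier_mask)``.

    With fewer than 3 points nothing is removed (warning).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        warnings.warn("ROUT needs n >= 3; no outliers removed", stacklevel=2)
        return values, values[:0], np.zeros(n, dtype=bool)
    q = q_percent / 100.0
    loc, scale = _robust_location(values)
    if scale == 0:  # constant (or near-constant) data: nothing to flag
        return values, values[:0], np.zeros(n, dtype=bool)
    t_scores = (values - loc) / scale
    pvals = 2.0 * stats.t.sf(np.abs(t_scores), df=n - 1)
    order = np.argsort(pvals)
    flagged = np.zeros(n, dtype=bool)
    thresh = q * (np.arange(1, n + 1)) / n
    below = pvals[order] <= thresh
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flagged[order[: k + 1]] = True
    return values[~flagged], values[flagged], flagged


# ---------------------------------------------------------------------------
# Normality gate and test selection


def normality_gate(groups: dict[str, np.ndarray], alpha: float = 0.05) -> tuple[str, dict]:
    """Shapiro-Wilk gate: parametric iff every group passes at ``alpha``.

    Returns ``(branch, per-group p-values)``. Degenerate groups (constant
    values, or n outside [3, 5000]) raise ``ValueError``.
    """
    pvalues = {}
    for g, v in groups.items():
        if not 3 <= len(v) <= 5000:
            raise ValueError(f"group {g!r}: Shapiro-Wilk supports 3 <= n <= 5000")
        if np.ptp(v) == 0:
            raise ValueError(f"group {g!r}: constant values, normality undefined")
        pvalues[g] = float(stats.shapiro(v).pvalue)
    branch = "parametric" if all(p > alpha for p in pvalues.values()) else "nonparametric"
    return branch, pvalues


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple comparison test after Kruskal-Wallis.

    Pairwise z statistics on pooled mean ranks with tie-corrected standard
    errors; p-values are Bonferroni-multiplied by the number of comparisons
    (the convention of "Dunn's multiple comparison test" in figure-legend
    usage).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i : i + k].mean()
        sizes[g] = k
        i += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        rows.append((a, b, z, p, significance_stars(p)))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p_adj", "stars"])


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    df = df.rename(columns={"p-adj": "p_adj"})
    df["stars"] = [significance_stars(float(p)) for p in df["p_adj"]]
    return df


def _two_factor(table: GroupTable, branch: str) -> StatsReport:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if branch == "nonparametric":
        logger.warning(
            "two-factor design has no nonparametric branch in the workflow; "
            "running two-way ANOVA on ranks"
        )
    df = table.data.copy()
    if branch == "nonparametric":
        df["value"] = stats.rankdata(df["value"])
    model = ols("value ~ C(group) * C(factor2)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f = float(anova.loc["C(group)", "F"])
    p = float(anova.loc["C(group)", "PR(>F)"])
    n_groups = df["group"].nunique()
    rows = []
    levels2 = sorted(df["factor2"].unique())
    if n_groups == 2:  # Sidak-adjusted pairwise comparisons within each level
        g1, g2 = sorted(df["group"].unique())
        m = len(levels2)
        for lvl in levels2:
            a = df.query("group == @g1 and factor2 == @lvl")["value"]
            b = df.query("group == @g2 and factor2 == @lvl")["value"]
            t, praw = stats.ttest_ind(a, b)
            padj = 1.0 - (1.0 - praw) ** m
            rows.append((f"{g1} vs {g2}", lvl, float(t), float(padj), significance_stars(padj)))
        posthoc = pd.DataFrame(rows, columns=["comparison", "factor2", "t", "p_adj", "stars"])
        name = "two-way ANOVA + Sidak"
    else:
        sub = {g: grp["value"].to_numpy(float) for g, grp in df.groupby("group")}
        posthoc = _tukey_posthoc(sub)
        name = "two-way ANOVA + Tukey"
    return StatsReport(table.design, branch, name, f, p, posthoc=posthoc)


def select_and_run(table: GroupTable, branch: str) -> StatsReport:
    """Run the test the design/branch pair dictates, with post hocs.

    The decision table: two_groups → Student t-test | Mann-Whitney;
    multi_group → one-way ANOVA + Tukey | Kruskal-Wallis + Dunn;
    two_factor → two-way ANOVA + Tukey (>2 groups) or Sidak (2 groups).
    """
    if branch not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown branch {branch!r}")
    groups = table.groups()
    if table.design == "two_groups":
        a, b = groups.values()
        if branch == "parametric":
            res = stats.ttest_ind(a, b)
            return StatsReport(table.design, branch, "t-test", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return StatsReport(table.design, branch, "Mann-Whitney", float(res.statistic), float(res.pvalue))
    if table.design == "multi_group":
        if len(groups) < 3:
            raise ValueError("multi_group design needs > 2 groups")
        if branch == "parametric":
            res = stats.f_oneway(*groups.values())
            return StatsReport(
                table.design, branch, "one-way ANOVA + Tukey",
                float(res.statistic), float(res.pvalue), posthoc=_tukey_posthoc(groups),
            )
        res = stats.kruskal(*groups.values())
        return StatsReport(
            table.design, branch, "Kruskal-Wallis + Dunn",
            float(res.statistic), float(res.pvalue), posthoc=_dunn_posthoc(groups),
        )
    if table.design == "two_factor":
        return _two_factor(table, branch)
    raise ValueError(f"unknown design {table.design!r}")


def run_workflow(
    table: GroupTable,
    alpha: float = 0.05,
    rout_q_percent: float = 1.0,
    remove_outliers: bool = True,
) -> StatsReport:
    """Full decision workflow: ROUT per group → normality gate → test."""
    df = table.data
    removed: dict[str, np.ndarray] = {}
    if remove_outliers:
        kept = []
        for g, grp in df.groupby("group", sort=False):
            clean, out, mask = rout_outliers(grp["value"].to_numpy(float), rout_q_percent)
            removed[g] = out
            kept.append(grp.loc[~mask])
        df = pd.concat(kept, ignore_index=True)
    clean_table = GroupTable(df, design=table.design)
    branch, pvals = normality_gate(clean_table.groups(), alpha)
    report = select_and_run(clean_table, branch)
    report.outliers_removed = removed
    report.normality_pvalues = pvals
    return report
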
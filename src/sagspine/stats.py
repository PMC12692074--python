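"""Group-comparison statistics for sagittal alignment variables.

Implements the statistical battery applied to the two cohorts:
per-group descriptives with independent two-sided t-tests, normality
flags, Spearman rank correlations, empirical ROC curves with
Youden-index / Kolmogorov-Smirnov cutoff selection, Cohen's d effect
sizes, and post hoc sample-size requirements from noncentral-t power.

ROC orientation is fixed: a value at or above the cutoff predicts
membership of the positive (patient) group.  The orientation is never
auto-flipped, so an anti-discriminating variable is reported with
AUC < 0.5 rather than silently inverted.

The user-facing entry point is :class:`CohortComparison`, a
statsmodels-style model object over a wide measurement table whose
``fit()`` returns a :class:`CohortComparisonResults` with a ``summary()``
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "EffectSize",
    "ROCResult",
    "describe",
    "spearman_matrix",
    "cohens_d",
    "cohens_d_from_samples",
    "two_sample_power",
    "required_sample_size",
    "roc_analysis",
    "normality_flags",
    "CohortComparison",
    "CohortComparisonResults",
]

#: Variables analyzed by default, in reporting order.
DEFAULT_VARIABLES = (
    "ARA_L1L5", "ARA_T12S1", "Cobb_T12S1", "SBA", "PT_S1", "API", "PTPIA",
    "ba_ratio", "API_minus_ARA_T12S1", "API_minus_ARA_L1L5",
    "API_minus_Cobb_T12S1",
)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptives of one variable."""

    variable: str
    group: str
    n: int
    mean: float
    sd: float
    max: float
    min: float


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference (pooled-SD Cohen's d)."""

    d: float
    pooled_sd: float


@dataclass(frozen=True)
class ROCResult:
    """Empirical two-sample ROC curve and optimal-cutoff summary.

    ``thresholds`` are the distinct observed values in ascending order;
    ``sensitivity[i]`` / ``specificity[i]`` are the operating
    characteristics of the rule "value >= thresholds[i] predicts the
    positive (patient) group".  The optimal cutoff maximizes the Youden
    index J = sensitivity + specificity - 1; among ties the largest
    cutoff is reported.  ``ks_metric`` is the oriented Kolmogorov-
    Smirnov separation max(F_negative - F_positive), which equals the
    maximal J on every input and coincides with the classical two-sample
    K-S statistic whenever the positive group is stochastically larger.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    youden_j: float
    ks_metric: float
    n_negative: int
    n_positive: int
    orientation: str = "higher-predicts-positive"

    def to_dict(self, include_curve: bool = False) -> dict:
        out = {
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sens_at_cutoff,
            "specificity": self.spec_at_cutoff,
            "youden_j": self.youden_j,
            "ks_metric": self.ks_metric,
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
            "orientation": self.orientation,
        }
        if include_curve:
            out["thresholds"] = self.thresholds.tolist()
            out["sens_curve"] = self.sensitivity.tolist()
            out["spec_curve"] = self.specificity.tolist()
        return out


def describe(df: pd.DataFrame, group_col: str = "group",
             variables: tuple[str, ...] | None = None,
             equal_var: bool = True) -> pd.DataFrame:
    """Per-group descriptives plus a two-sided independent t-test per variable.

    Returns a tidy frame with one row per variable: mean/sd/max/min/n for
    each of the two groups and the t-test p-value (Student pooled-variance
    by default; ``equal_var=False`` for Welch).  Zero variance in both
    groups leaves the t-test undefined (p = NaN) and sets a flag.
    """
    groups = list(pd.unique(df[group_col]))
    if len(groups) != 2:
        raise ValueError(f"describe requires exactly 2 groups, got {groups}")
    variables = variables or tuple(v for v in DEFAULT_VARIABLES if v in df.columns)
    rows = []
    for v in variables:
        row: dict[str, object] = {"variable": v}
        samples = []
        for g in groups:
            x = df.loc[df[group_col] == g, v].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 observations for {v!r}")
            samples.append(x)
            row[f"mean_{g}"] = x.mean()
            row[f"sd_{g}"] = x.std(ddof=1)
            row[f"max_{g}"] = x.max()
            row[f"min_{g}"] = x.min()
            row[f"n_{g}"] = len(x)
        x0, x1 = samples
        if x0.std(ddof=1) == 0 and x1.std(ddof=1) == 0:
            row["t"], row["p"], row["undefined_t"] = math.nan, math.nan, True
            if np.isclose(x0.mean(), x1.mean()):
                row["p"] = 1.0  # identical degenerate groups: no evidence
        else:
            t, p = sps.ttest_ind(x1, x0, equal_var=equal_var)
            row["t"], row["p"], row["undefined_t"] = float(t), float(p), False
        rows.append(row)
    return pd.DataFrame(rows)


def group_summaries(df: pd.DataFrame, group_col: str = "group",
                    variables: tuple[str, ...] | None = None
                    ) -> list[GroupSummary]:
    """:class:`GroupSummary` objects for every (variable, group) pair."""
    variables = variables or tuple(v for v in DEFAULT_VARIABLES if v in df.columns)
    out = []
    for v in variables:
        for g, sub in df.groupby(group_col, sort=False):
            x = sub[v].dropna().to_numpy(dtype=float)
            out.append(GroupSummary(variable=v, group=str(g), n=len(x),
                                    mean=float(x.mean()),
                                    sd=float(x.std(ddof=1)) if len(x) > 1 else math.nan,
                                    max=float(x.max()), min=float(x.min())))
    return out


def spearman_matrix(df: pd.DataFrame, variables: tuple[str, ...]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Spearman rho and p-value matrices over ``variables``.

    Ranks are tie-corrected (average ranks); p-values use the
    t-approximation.  A constant column has undefined correlation (NaN,
    flagged by the NaN itself).  Requires >= 3 paired observations.
    """
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            pair = df[[variables[i], variables[j]]].dropna().to_numpy(dtype=float)
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 paired observations for "
                    f"({variables[i]}, {variables[j]})")
            x, y = pair[:, 0], pair[:, 1]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined: leave NaN
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            r = np.corrcoef(rx, ry)[0, 1]
            n = len(x)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * sps.t.sf(abs(t), n - 2)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = list(variables)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(pval, index=idx, columns=idx))


def cohens_d(m0: float, s0: float, n0: int, m1: float, s1: float, n1: int
             ) -> EffectSize:
    """Cohen's d from group summaries, with the pooled SD.

    d = (m1 - m0) / s_pooled,
    s_pooled = sqrt(((n0-1) s0^2 + (n1-1) s1^2) / (n0 + n1 - 2)).
    """
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs n >= 2")
    sp = math.sqrt(((n0 - 1) * s0 ** 2 + (n1 - 1) * s1 ** 2) / (n0 + n1 - 2))
    if sp <= 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return EffectSize(d=(m1 - m0) / sp, pooled_sd=sp)


def cohens_d_from_samples(x0, x1) -> EffectSize:
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    return cohens_d(x0.mean(), x0.std(ddof=1), len(x0),
                    x1.mean(), x1.std(ddof=1), len(x1))


def two_sample_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size ``d`` with
    ``n_per_group`` per arm, from the noncentral t distribution
    (df = 2n - 2, noncentrality d * sqrt(n / 2))."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                         n_max: int = 10_000_000) -> int:
    """Smallest n per group giving two-sample noncentral-t power >= target.

    Monotone nonincreasing in |d|.  Raises for d = 0 or when the
    required n would exceed ``n_max`` (overflow guard for negligible
    effects).
    """
    if d == 0 or not math.isfinite(d):
        raise ValueError("effect size must be nonzero and finite")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    d = abs(d)
    # bracket by doubling, then bisect on the monotone power curve
    lo, hi = 2, 2
    while two_sample_power(d, hi, alpha) < power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(
                f"required n per group exceeds {n_max}; effect size {d:g} "
                "is below the feasibility threshold")
    while lo < hi:
        mid = (lo + hi) // 2
        if two_sample_power(d, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def roc_analysis(scores_negative, scores_positive) -> ROCResult:
    """Empirical ROC of a score separating two samples.

    ``scores_negative`` are the reference (control) group,
    ``scores_positive`` the patient group; the classification rule is
    "value >= cutoff predicts positive" and is never flipped.  The AUC
    is the trapezoidal area, identical to Mann-Whitney U / (n0*n1) with
    half-credit for ties.  The optimal cutoff maximizes Youden's J; the
    largest cutoff is reported when several attain the maximum.
    """
    x0 = np.sort(np.asarray(scores_negative, dtype=float))
    x1 = np.sort(np.asarray(scores_positive, dtype=float))
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x0).any() or np.isnan(x1).any():
        raise ValueError("scores must not contain NaN")
    n0, n1 = len(x0), len(x1)
    thr = np.unique(np.concatenate([x0, x1]))
    # value >= c predicts positive
    sens = 1.0 - np.searchsorted(x1, thr, side="left") / n1   # P(x1 >= c)
    fpr = 1.0 - np.searchsorted(x0, thr, side="left") / n0    # P(x0 >= c)
    spec = 1.0 - fpr
    # ROC polyline from (0,0) (cutoff above max) to (1,1) (cutoff below min)
    fpr_curve = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr_curve = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    j = sens + spec - 1.0
    jmax = j.max()
    best = np.flatnonzero(j >= jmax - 1e-12)
    i = int(best[-1])  # largest cutoff among ties
    # oriented K-S separation of the ECDFs (independent computation):
    # max(F_neg - F_pos), the two-sample K-S statistic whenever the
    # positive group is stochastically the larger one.  Under the fixed
    # ROC orientation this equals max Youden J on every input (for an
    # anti-discriminating score both are 0, not |F0 - F1|).
    f0 = np.searchsorted(x0, thr, side="right") / n0
    f1 = np.searchsorted(x1, thr, side="right") / n1
    ks = float((f0 - f1).max())
    return ROCResult(thresholds=thr, sensitivity=sens, specificity=spec,
                     auc=auc, optimal_cutoff=float(thr[i]),
                     sens_at_cutoff=float(sens[i]), spec_at_cutoff=float(spec[i]),
                     youden_j=float(jmax), ks_metric=ks,
                     n_negative=n0, n_positive=n1)


def normality_flags(df: pd.DataFrame, group_col: str = "group",
                    variables: tuple[str, ...] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk and Lilliefors (Kolmogorov-Smirnov) normality flags.

    Contract-level calls to the standard implementations; results are
    report flags only and never trigger an automatic method switch.
    """
    from statsmodels.stats.diagnostic import lilliefors

    variables = variables or tuple(v for v in DEFAULT_VARIABLES if v in df.columns)
    rows = []
    for v in variables:
        for g, sub in df.groupby(group_col, sort=False):
            x = sub[v].dropna().to_numpy(dtype=float)
            if len(x) < 4 or np.ptp(x) == 0:
                continue
            sw_p = float(sps.shapiro(x).pvalue)
            ks_p = float(lilliefors(x, dist="norm")[1])
            rows.append({"variable": v, "group": str(g),
                         "shapiro_p": sw_p, "ks_p": ks_p,
                         "nonnormal": bool(sw_p < alpha or ks_p < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects

class CohortComparison:
    """Two-group comparison of sagittal alignment variables.

    Parameters
    ----------
    data : DataFrame
        Wide measurement table, one row per subject, with a group column.
    group_col : str
        Column holding the group labels (exactly two distinct values).
    positive_group : str
        The patient group; ROC orientation is "higher value predicts
        this group" and effect sizes are positive-group minus reference.
    variables : tuple of str, optional
        Variables to analyze (default: the standard measurement set
        intersected with the available columns).
    """

    def __init__(self, data: pd.DataFrame, group_col: str = "group",
                 positive_group: str = "albp",
                 variables: tuple[str, ...] | None = None) -> None:
        groups = list(pd.unique(data[group_col]))
        if len(groups) != 2:
            raise ValueError(
                f"exactly two groups required, found {groups}; "
                "single-group input cannot be compared")
        if positive_group not in groups:
            raise ValueError(f"positive_group {positive_group!r} not in {groups}")
        self.data = data
        self.group_col = group_col
        self.positive_group = positive_group
        self.reference_group = next(g for g in groups if g != positive_group)
        self.variables = tuple(
            variables or (v for v in DEFAULT_VARIABLES if v in data.columns))
        if not self.variables:
            raise ValueError("no analyzable variables found")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "CohortComparison":
        return cls(data, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "CohortComparison":
        from .landmarks import read_measurements

        return cls(read_measurements(path), **kw)

    def fit(self, alpha: float = 0.05, power: float = 0.80,
            equal_var: bool = True) -> "CohortComparisonResults":
        """Run the full battery and return the results object."""
        df = self.data
        desc = describe(df, self.group_col, self.variables, equal_var=equal_var)
        spearman = {}
        for g, sub in df.groupby(self.group_col, sort=False):
            usable = tuple(v for v in self.variables
                           if sub[v].notna().sum() >= 3 and np.ptp(
                               sub[v].dropna().to_numpy()) > 0)
            if len(usable) >= 2:
                spearman[str(g)] = spearman_matrix(sub, usable)
        roc = {}
        effects = {}
        sample_sizes = {}
        neg = df[df[self.group_col] == self.reference_group]
        pos = df[df[self.group_col] == self.positive_group]
        for v in self.variables:
            x0 = neg[v].dropna().to_numpy(dtype=float)
            x1 = pos[v].dropna().to_numpy(dtype=float)
            roc[v] = roc_analysis(x0, x1)
            try:
                es = cohens_d_from_samples(x0, x1)
            except ValueError:
                es = EffectSize(d=math.nan, pooled_sd=0.0)
            effects[v] = es
            if es.d and math.isfinite(es.d):
                try:
                    sample_sizes[v] = required_sample_size(es.d, alpha, power)
                except ValueError:
                    sample_sizes[v] = None
            else:
                sample_sizes[v] = None
        norm = normality_flags(df, self.group_col, self.variables, alpha)
        return CohortComparisonResults(
            model=self, table1=desc, spearman=spearman, roc=roc,
            effect_sizes=effects, sample_sizes=sample_sizes,
            normality=norm, alpha=alpha, power=power, equal_var=equal_var)


@dataclass
class CohortComparisonResults:
    """Fitted results of a :class:`CohortComparison`.

    ``table1``: per-variable group descriptives + t-test p.
    ``spearman``: per-group (rho, p) matrix pair.
    ``roc``: per-variable :class:`ROCResult`.
    ``effect_sizes`` / ``sample_sizes``: per-variable Cohen's d and the
    post hoc required n per group at the configured alpha and power.
    """

    model: CohortComparison
    table1: pd.DataFrame
    spearman: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    roc: dict[str, ROCResult]
    effect_sizes: dict[str, EffectSize]
    sample_sizes: dict[str, int | None]
    normality: pd.DataFrame
    alpha: float = 0.05
    power: float = 0.80
    equal_var: bool = True

    def roc_table(self) -> pd.DataFrame:
        """ROC summary, one row per variable (AUC, cutoff, sens, spec)."""
        rows = []
        for v, r in self.roc.items():
            rows.append({"variable": v, "auc": r.auc,
                         "cutoff": round(r.optimal_cutoff, 1),
                         "sensitivity": r.sens_at_cutoff,
                         "specificity": r.spec_at_cutoff,
                         "youden_j": r.youden_j, "ks_metric": r.ks_metric})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        ref, pos = self.model.reference_group, self.model.positive_group
        return {
            "reference_group": ref,
            "positive_group": pos,
            "alpha": self.alpha,
            "power": self.power,
            "equal_var": self.equal_var,
            "descriptives": self.table1.to_dict(orient="records"),
            "spearman": {
                g: {"rho": r.round(6).to_dict(), "p": p.round(6).to_dict()}
                for g, (r, p) in self.spearman.items()},
            "roc": {v: r.to_dict() for v, r in self.roc.items()},
            "effect_sizes": {v: {"d": e.d, "pooled_sd": e.pooled_sd}
                             for v, e in self.effect_sizes.items()},
            "required_n_per_group": self.sample_sizes,
            "normality": self.normality.to_dict(orient="records"),
        }

    def summary(self) -> str:
        ref, pos = self.model.reference_group, self.model.positive_group
        lines = [
            "Cohort comparison summary",
            "=========================",
            f"reference group: {ref}    positive group: {pos}",
            f"t-test: {'Student (pooled)' if self.equal_var else 'Welch'}, "
            f"two-sided; alpha={self.alpha}, target power={self.power}",
            "",
            f"{'variable':<22}{'mean ' + ref:>14}{'mean ' + pos:>14}"
            f"{'p':>9}{'d':>8}{'AUC':>7}{'cutoff':>9}{'sens':>6}{'spec':>6}"
            f"{'n req':>7}",
        ]
        for _, row in self.table1.iterrows():
            v = row["variable"]
            r = self.roc[v]
            d = self.effect_sizes[v].d
            nreq = self.sample_sizes[v]
            lines.append(
                f"{v:<22}{row[f'mean_{ref}']:>14.2f}{row[f'mean_{pos}']:>14.2f}"
                f"{row['p']:>9.3f}{d:>8.3f}{r.auc:>7.3f}"
                f"{r.optimal_cutoff:>9.1f}{r.sens_at_cutoff:>6.2f}"
                f"{r.spec_at_cutoff:>6.2f}"
                f"{nreq if nreq is not None else '-':>7}")
        lines.append("")
        lines.append("ROC orientation: value >= cutoff predicts the positive "
                     "group (never flipped).")
        return "\n".join(lines)
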
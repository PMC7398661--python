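"""Cohort-level inference: repeated-measures ANOVA, Holm-Sidak, t-tests, OLS.

The one-way repeated-measures ANOVA and the two-way mixed design (one
between-subject group factor, one within-subject timepoint factor) are
computed from first-principles sums of squares on the complete-case pivot
table. Missing cells are rejected loudly (no imputation). For unequal group
sizes the within-factor and interaction effects use observed-margin
(group-size-weighted) means, which keeps the SS partition exactly additive;
with balanced groups this reduces to the classical textbook partition.

Sphericity is not corrected by default; a Greenhouse-Geisser option is
available for the within-subject effects. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "ComparisonSet",
    "RegressionResult",
    "TTestResult",
    "rm_anova_one_way",
    "rm_anova_two_way",
    "holm_sidak",
    "unpaired_t",
    "paired_t",
    "linregress",
    "pairwise_contrasts",
]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: float
    ms: float
    F: float | None = None
    p: float | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.name,
            "ss": self.ss,
            "df": self.df,
            "ms": self.ms,
            "F": self.F,
            "p": self.p,
        }


@dataclass
class AnovaResult:
    design: str
    effects: list[AnovaEffect]
    ss_total: float
    sphericity_epsilon: float | None = None

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.effects])

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "ss_total": self.ss_total,
            "sphericity_epsilon": self.sphericity_epsilon,
            "effects": [e.to_dict() for e in self.effects],
        }


def _f_p(ss_num, df_num, ss_den, df_den):
    """F and p with a guarded zero-variance path (0/0 -> F=0, p=1)."""
    ms_num = ss_num / df_num if df_num > 0 else 0.0
    ms_den = ss_den / df_den if df_den > 0 else 0.0
    if ms_den <= 0:
        if ms_num <= 0:
            return 0.0, 0.0, 0.0, 1.0
        return ms_num, ms_den, np.inf, 0.0
    F = ms_num / ms_den
    p = float(sps.f.sf(F, df_num, df_den))
    return ms_num, ms_den, float(F), p


def _pivot(df, dv, within, subject):
    for col in (dv, within, subject):
        if col not in df.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    counts = df.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        bad = counts.stack(future_stack=True)
        bad = bad[(bad != 1) | bad.isna()]
        cell = bad.index[0]
        raise ValueError(
            f"incomplete or duplicated cell: subject {cell[0]!r} at level "
            f"{cell[1]!r} (complete balanced within-subject data required)"
        )
    return df.pivot(index=subject, columns=within, values=dv).sort_index()


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance matrix."""
    t = Y.shape[1]
    if t < 3:
        return 1.0
    S = np.cov(Y, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / t
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (t * (mean_diag - grand)) ** 2
    den = (t - 1) * (
        (S**2).sum() - 2 * t * (row_means**2).sum() + t**2 * grand**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (t - 1))))


def rm_anova_one_way(
    cohort: pd.DataFrame,
    dv: str = "value",
    within: str = "timepoint",
    subject: str = "mouse_id",
    correction: bool = False,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a long-format table.

    Requires every subject measured once at every within-subject level, at
    least 2 subjects and 2 levels. ``correction=True`` applies the
    Greenhouse-Geisser adjustment to the within-effect p-value.
    """
    pivot = _pivot(cohort, dv, within, subject)
    Y = pivot.to_numpy(dtype=float)
    n, t = Y.shape
    if n < 2 or t < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 levels; got {n} x {t}")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subject = float(t * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_within = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_within
    df_w, df_e, df_s = t - 1, (n - 1) * (t - 1), n - 1
    ms_w, ms_e, F, p = _f_p(ss_within, df_w, ss_error, df_e)
    eps = None
    if correction:
        eps = _gg_epsilon(Y)
        if np.isfinite(F) and F > 0:
            p = float(sps.f.sf(F, eps * df_w, eps * df_e))
    effects = [
        AnovaEffect(within, ss_within, df_w, ms_w, F, p),
        AnovaEffect("subject", ss_subject, df_s, ss_subject / df_s),
        AnovaEffect("error", max(ss_error, 0.0), df_e, ms_e),
    ]
    return AnovaResult(
        design=f"one-way RM ({t} levels x {n} subjects)",
        effects=effects,
        ss_total=ss_total,
        sphericity_epsilon=eps,
    )


def rm_anova_two_way(
    cohort: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "timepoint",
    subject: str = "mouse_id",
    correction: bool = False,
) -> AnovaResult:
    """Mixed-design ANOVA: between-subject group, within-subject timepoint.

    The between-group effect is tested against subjects-within-groups; the
    within and interaction effects against the subject-by-timepoint
    residual. SS components sum exactly to the total SS.
    """
    if between not in cohort.columns:
        raise ValueError(f"cohort table missing column {between!r}")
    gmap = cohort.groupby(subject, observed=True)[between].nunique()
    if (gmap > 1).any():
        bad = gmap[gmap > 1].index[0]
        raise ValueError(f"subject {bad!r} appears in more than one group")
    subj_group = cohort.groupby(subject, observed=True)[between].first().sort_index()
    groups = sorted(subj_group.unique())
    if len(groups) < 2:
        raise ValueError(
            "only one group present; use rm_anova_one_way for a pure "
            "within-subject design"
        )
    pivot = _pivot(cohort, dv, within, subject)
    Y = pivot.to_numpy(dtype=float)
    n_total, t = Y.shape
    glabels = subj_group.loc[pivot.index].to_numpy()
    n_g = {g: int((glabels == g).sum()) for g in groups}
    if min(n_g.values()) < 2:
        raise ValueError("need >= 2 subjects per group")

    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    subj_means = Y.mean(axis=1)

    # between-subjects partition
    ss_group = 0.0
    ss_subj_within = 0.0
    group_means = {}
    for g in groups:
        sel = glabels == g
        gm = Y[sel].mean()
        group_means[g] = gm
        ss_group += t * n_g[g] * (gm - grand) ** 2
        ss_subj_within += t * ((subj_means[sel] - gm) ** 2).sum()

    # within-subjects partition: d_gt = cell mean - group mean; time effect
    # is the group-size-weighted mean of d_gt (exactly orthogonal partition)
    d = np.empty((len(groups), t))
    for i, g in enumerate(groups):
        sel = glabels == g
        d[i] = Y[sel].mean(axis=0) - group_means[g]
    w = np.array([n_g[g] for g in groups], dtype=float)
    tau = (w[:, None] * d).sum(axis=0) / n_total
    ss_within_factor = float(n_total * (tau**2).sum())
    ss_inter = float((w[:, None] * (d - tau[None, :]) ** 2).sum())
    ss_error = ss_total - ss_group - ss_subj_within - ss_within_factor - ss_inter

    df_g, df_sw = len(groups) - 1, n_total - len(groups)
    df_w, df_i = t - 1, (len(groups) - 1) * (t - 1)
    df_e = (n_total - len(groups)) * (t - 1)

    ms_g, ms_sw, F_g, p_g = _f_p(ss_group, df_g, ss_subj_within, df_sw)
    ms_w, ms_e, F_w, p_w = _f_p(ss_within_factor, df_w, ss_error, df_e)
    ms_i, _, F_i, p_i = _f_p(ss_inter, df_i, ss_error, df_e)
    eps = None
    if correction:
        # pooled within-group covariance for the GG estimate
        resid = np.vstack([Y[glabels == g] - Y[glabels == g].mean(axis=0)
                           for g in groups])
        eps = _gg_epsilon(resid)
        if np.isfinite(F_w) and F_w > 0:
            p_w = float(sps.f.sf(F_w, eps * df_w, eps * df_e))
        if np.isfinite(F_i) and F_i > 0:
            p_i = float(sps.f.sf(F_i, eps * df_i, eps * df_e))

    effects = [
        AnovaEffect(between, ss_group, df_g, ms_g, F_g, p_g),
        AnovaEffect("subject_within_group", ss_subj_within, df_sw, ms_sw),
        AnovaEffect(within, ss_within_factor, df_w, ms_w, F_w, p_w),
        AnovaEffect(f"{between}:{within}", ss_inter, df_i, ms_i, F_i, p_i),
        AnovaEffect("error", max(ss_error, 0.0), df_e, ms_e),
    ]
    return AnovaResult(
        design=(
            f"mixed ANOVA ({len(groups)} groups x {t} levels, "
            f"n={sorted(n_g.values())})"
        ),
        effects=effects,
        ss_total=ss_total,
        sphericity_epsilon=eps,
    )


# ---------------------------------------------------------------------------
# multiple comparisons


@dataclass
class ComparisonSet:
    """Pairwise contrasts with Holm-Sidak step-down adjusted p-values."""

    labels: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float = 0.05
    reject: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.p_raw = np.asarray(self.p_raw, dtype=float)
        self.p_adjusted = np.asarray(self.p_adjusted, dtype=float)
        self.reject = self.p_adjusted <= self.alpha

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast": self.labels,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "reject": self.reject,
            }
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "contrasts": self.table().to_dict(orient="records"),
        }


def holm_sidak(
    pvals, alpha: float = 0.05, labels: list[str] | None = None
) -> ComparisonSet:
    """Holm-Sidak step-down adjustment.

    With raw p-values sorted ascending, rank i (1-based) is adjusted to
    ``1 - (1 - p_(i))^(m - i + 1)``, then a running maximum enforces
    monotonicity before mapping back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(adj_sorted)
    adj[order] = np.minimum(adj_sorted, 1.0)
    if labels is None:
        labels = [f"contrast_{i}" for i in range(m)]
    return ComparisonSet(labels=list(labels), p_raw=p, p_adjusted=adj, alpha=alpha)


# ---------------------------------------------------------------------------
# t-tests and regression


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p}


def unpaired_t(x, y) -> TTestResult:
    """Two-sided pooled-variance t-test for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf * np.sign(x.mean() - y.mean()), df, 0.0)
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test (within-subject contrast)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    df = x.size - 1
    if np.var(d, ddof=1) == 0:
        if d.mean() == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf * np.sign(d.mean()), df, 0.0)
    res = sps.ttest_rel(x, y)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p": self.p,
            "n": self.n,
        }


def linregress(x, y) -> RegressionResult:
    """Ordinary least squares with a t-test on the slope (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    # a constant y gives slope 0, r = nan in scipy; define r2 = 0, p = 1
    if np.var(y, ddof=1) == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, 1.0, x.size)
    return RegressionResult(
        float(res.slope), float(res.intercept), r2, float(res.pvalue), x.size
    )


# ---------------------------------------------------------------------------
# contrast families


def pairwise_contrasts(
    cohort: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "timepoint",
    subject: str = "mouse_id",
    family: str = "all",
    alpha: float = 0.05,
) -> ComparisonSet:
    """Figure-style pairwise contrasts with one Holm-Sidak family.

    ``family='within'``: paired t-tests across timepoints inside each group;
    ``family='between'``: unpaired t-tests between groups at each timepoint;
    ``family='all'``: both, adjusted together.
    """
    if family not in ("within", "between", "all"):
        raise ValueError("family must be 'within', 'between' or 'all'")
    labels: list[str] = []
    pvals: list[float] = []
    timepoints = [t for t in cohort[within].drop_duplicates()]
    groups = sorted(cohort[between].drop_duplicates())
    if family in ("within", "all"):
        for g in groups:
            sub = cohort[cohort[between] == g].pivot(
                index=subject, columns=within, values=dv
            )
            for i, t1 in enumerate(timepoints):
                for t2 in timepoints[i + 1 :]:
                    res = paired_t(sub[t1].to_numpy(), sub[t2].to_numpy())
                    labels.append(f"{g}: {t1} vs {t2}")
                    pvals.append(res.p)
    if family in ("between", "all"):
        for t1 in timepoints:
            sub = cohort[cohort[within] == t1]
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1 :]:
                    res = unpaired_t(
                        sub.loc[sub[between] == g1, dv].to_numpy(),
                        sub.loc[sub[between] == g2, dv].to_numpy(),
                    )
                    labels.append(f"{t1}: {g1} vs {g2}")
                    pvals.append(res.p)
    return holm_sidak(pvals, alpha=alpha, labels=labels)
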
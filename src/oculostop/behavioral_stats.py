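"""Group-level statistics: pooled two-sample t-tests (computable straight
from printed summary tables), a two-factor mixed ANOVA with generalized
eta squared and Greenhouse-Geisser correction, and backward-elimination
OLS regression.

The mixed ANOVA covers the standard design of these tasks: one
between-subjects factor (diagnostic group) crossed with one
within-subjects factor (trial type), balanced over conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import InvalidInputError


@dataclass(frozen=True)
class GroupSummaryStats:
    """Two-group summary statistics as printed in a Mean (s.d.) table."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 < 0 or self.sd2 < 0:
            raise InvalidInputError("standard deviations must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidInputError("each group needs n >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float  # signed, positive when group2 > group1
    df: int
    p: float

    @property
    def magnitude(self) -> float:
        return abs(self.t)


def pooled_t(stats: GroupSummaryStats) -> TTestResult:
    """Independent two-tailed t-test with pooled variance, df = n1+n2-2.

    Computable directly from printed group means/SDs/sizes, which is how
    the worked-example tables are re-checked.
    """
    if stats.n1 + stats.n2 < 3:
        raise InvalidInputError("need n1 + n2 >= 3")
    t, p = sps.ttest_ind_from_stats(
        stats.mean2, stats.sd2, stats.n2,
        stats.mean1, stats.sd1, stats.n1,
        equal_var=True,
    )
    return TTestResult(t=float(t), df=stats.n1 + stats.n2 - 2, p=float(p))


def gg_epsilon(condition_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a k x k condition covariance matrix.

    Computed from the eigenvalues of the double-centered covariance,
    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2), clamped to
    [1/(k-1), 1].  Equals 1 exactly under sphericity (and always for
    k = 2, where sphericity is vacuous).
    """
    s = np.asarray(condition_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise InvalidInputError("covariance must be square with k >= 2")
    if not np.allclose(s, s.T, atol=1e-10):
        raise InvalidInputError("covariance must be symmetric")
    k = s.shape[0]
    center = np.eye(k) - np.ones((k, k)) / k
    sc = center @ s @ center
    lam = np.linalg.eigvalsh(sc)
    lam = np.clip(lam, 0, None)
    denom = (k - 1) * np.sum(lam**2)
    if denom <= 0:
        return 1.0
    eps = np.sum(lam) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    """Two-factor mixed ANOVA (between group x within condition).

    Requires a complete balanced within-subject design: every subject
    contributes exactly one value per condition.  Returns one row per
    effect (group, condition, interaction) with F, (Greenhouse-Geisser
    corrected) degrees of freedom, p, generalized eta squared and epsilon.

    Generalized eta squared follows the Olejnik-Algina partition with the
    group factor treated as *observed* (measured, not manipulated): the
    denominator of every effect adds the sums of squares of all sources
    involving the observed factor plus both error strata, i.e.
    ges(effect) = SS_effect / (SS_effect + SS_other_observed +
    SS_subjects_within_group + SS_within_error).  GG correction is applied
    to within-subject effects only when k > 2 and epsilon < 1.
    """
    d = data[[subject, between, within, dv]].copy()
    conds = sorted(d[within].unique())
    k = len(conds)
    # balance check, naming offenders
    counts = d.groupby([subject, within], observed=True).size()
    for subj in d[subject].unique():
        for c in conds:
            n = counts.get((subj, c), 0)
            if n != 1:
                raise InvalidInputError(
                    f"subject {subj!r} has {n} values for condition {c!r}; need exactly 1"
                )
    groups = sorted(d[between].unique())
    g_sizes = d.groupby(between, observed=True)[subject].nunique()
    if len(groups) < 2 or (g_sizes < 2).any():
        raise InvalidInputError("need >= 2 subjects in each of >= 2 groups")

    y = d[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_subj = d[subject].nunique()
    n_grp = len(groups)

    subj_mean = d.groupby(subject, observed=True)[dv].mean()
    grp_of_subj = d.groupby(subject, observed=True)[between].first()
    grp_mean = d.groupby(between, observed=True)[dv].mean()
    cond_mean = d.groupby(within, observed=True)[dv].mean()
    cell_mean = d.groupby([between, within], observed=True)[dv].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = float(k * (g_sizes * (grp_mean - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = float(n_subj * ((cond_mean - grand) ** 2).sum())
    ss_cell = float(
        sum(
            g_sizes[g] * (cell_mean[(g, c)] - grand) ** 2
            for g in groups
            for c in conds
        )
    )
    ss_inter = ss_cell - ss_group - ss_cond
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter

    df_group, df_subj = n_grp - 1, n_subj - n_grp
    df_cond, df_inter = k - 1, (n_grp - 1) * (k - 1)
    df_err = df_subj * df_cond

    def _f(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err
        return (ss_eff / df_eff) / ms_err if ms_err > 0 else 0.0

    f_group = _f(ss_group, df_group, ss_subj_within, df_subj)
    f_cond = _f(ss_cond, df_cond, ss_err_within, df_err)
    f_inter = _f(ss_inter, df_inter, ss_err_within, df_err)

    # pooled within-group covariance of subject condition vectors
    wide = d.pivot_table(index=subject, columns=within, values=dv, observed=True).loc[:, conds]
    cov = np.zeros((k, k))
    for g in groups:
        members = grp_of_subj[grp_of_subj == g].index
        block = wide.loc[members].to_numpy()
        cov += (block - block.mean(axis=0)).T @ (block - block.mean(axis=0))
    cov /= (n_subj - n_grp)
    eps = gg_epsilon(cov)
    apply_gg = k > 2 and eps < 1.0

    def _row(effect, f, df1, df2, ss_eff, ss_others, within_effect):
        e = eps if (within_effect and apply_gg) else 1.0
        d1, d2 = df1 * e, df2 * e
        p = float(sps.f.sf(f, d1, d2))
        denom = ss_eff + ss_others + ss_subj_within + ss_err_within
        return {
            "effect": effect, "F": f, "df_num": d1, "df_den": d2, "p": p,
            "ges": ss_eff / denom if denom > 0 else 0.0,
            "epsilon": eps if within_effect else np.nan,
        }

    table = pd.DataFrame([
        _row("group", f_group, df_group, df_subj, ss_group, ss_inter, False),
        _row("condition", f_cond, df_cond, df_err, ss_cond, ss_group + ss_inter, True),
        _row("interaction", f_inter, df_inter, df_err, ss_inter, ss_group, True),
    ])
    return table


@dataclass
class RegressionModel:
    """Final model of a backward-elimination OLS fit."""

    coefficients: pd.DataFrame  # index term; columns coef, se, t, p
    retained: list[str]
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int

    @property
    def intercept(self) -> float:
        return float(self.coefficients.loc["const", "coef"])


def backward_eliminate(
    predictors: pd.DataFrame, response: pd.Series | np.ndarray, p_out: float = 0.10
) -> RegressionModel:
    """Backward-elimination OLS: fit all predictors, repeatedly drop the
    one with the largest p-value >= ``p_out`` and refit, until every
    retained predictor is below the threshold (the intercept is never
    removed).  Ties are broken by dropping the later column, making the
    procedure deterministic."""
    x = predictors.copy()
    y = np.asarray(response, dtype=float)
    if x.shape[1] < 1:
        raise InvalidInputError("need at least one predictor")
    if len(y) <= x.shape[1] + 1:
        raise InvalidInputError("need n > number of predictors + 1")
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        collinear = sorted(set(corr.columns[(corr > 0.9999).any()]))
        raise InvalidInputError(f"rank-deficient design; collinear columns: {collinear}")

    kept = list(x.columns)
    while True:
        fit = sm.OLS(y, sm.add_constant(x[kept], has_constant="add")).fit()
        pvals = fit.pvalues.drop("const")
        if kept and len(pvals) > 0:
            worst_p = pvals.max()
            if worst_p >= p_out:
                # later column wins ties
                worst = [c for c in kept if pvals[c] == worst_p][-1]
                kept.remove(worst)
                if kept:
                    continue
                fit = sm.OLS(y, np.ones((len(y), 1))).fit()
                coef = pd.DataFrame(
                    {"coef": [fit.params[0]], "se": [fit.bse[0]],
                     "t": [fit.tvalues[0]], "p": [fit.pvalues[0]]},
                    index=["const"],
                )
                return RegressionModel(coef, [], 0.0, float("nan"), 0, len(y) - 1)
        break

    coef = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return RegressionModel(
        coefficients=coef,
        retained=kept,
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )
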
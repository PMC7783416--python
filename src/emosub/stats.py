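"""Dimensional group comparison and logistic discrimination.

``rm_anova`` fits the 3 (domain, within) x 2 (group, between) mixed-design
analysis of variance on the factor scores, with partial eta squared effect
sizes, noncentral-F 95% confidence intervals, Greenhouse-Geisser epsilon,
and Bonferroni-corrected per-domain group contrasts.  Sums of squares are
computed by model comparison with sum-to-zero coding (Type III), so the
unbalanced two-group design is handled exactly.

``logistic_discrimination`` predicts group membership from the three
domain scores: likelihood-ratio model test, per-predictor Wald tests and
odds ratios, the Hosmer-Lemeshow calibration test, and sensitivity/
specificity at a configurable probability cutoff with Wilson score CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


class AnovaInputError(ValueError):
    """Missing cells / incomplete within-subject data."""


# ---------------------------------------------------------------------------
# Effect-size confidence intervals
# ---------------------------------------------------------------------------


def _ncf_lambda(target: float, f: float, df1: float, df2: float) -> float:
    """Noncentrality at which P(F' <= f) equals ``target`` (0 if impossible)."""
    if sps.ncf.cdf(f, df1, df2, 0.0) < target:
        return 0.0
    hi = 10.0
    while sps.ncf.cdf(f, df1, df2, hi) > target:
        hi *= 2
        if hi > 1e7:  # pragma: no cover - pathological
            return hi
    return brentq(lambda lam: sps.ncf.cdf(f, df1, df2, lam) - target, 0.0, hi)


def partial_eta_sq_ci(
    f: float, df1: float, df2: float, level: float = 0.95
) -> tuple[float, float]:
    """CI for partial eta squared by inverting the noncentral F distribution."""
    alpha = 1.0 - level
    lam_lo = _ncf_lambda(1 - alpha / 2, f, df1, df2)
    lam_hi = _ncf_lambda(alpha / 2, f, df1, df2)
    conv = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (conv(lam_lo), conv(lam_hi))


def eta_sq_label(value: float) -> str:
    """Qualitative benchmark: 0.01 / 0.06 / 0.14 = small / medium / large."""
    if value >= 0.14:
        return "large"
    if value >= 0.06:
        return "medium"
    if value >= 0.01:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # group / domain / group x domain rows
    posthoc: pd.DataFrame  # per-domain group contrasts
    gg_epsilon: float
    ss_total: float
    ss_components: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.to_dict(orient="index"),
            "posthoc": self.posthoc.to_dict(orient="index"),
            "gg_epsilon": self.gg_epsilon,
        }


def _gg_epsilon(wide: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = wide.shape[1]
    pooled = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        sub = wide[groups == g]
        pooled += (len(sub) - 1) * np.cov(sub, rowvar=False)
        dof += len(sub) - 1
    s = pooled / dof
    # double-centered covariance
    row = s.mean(axis=0, keepdims=True)
    dc = s - row - row.T + s.mean()
    eig = np.linalg.eigvalsh(dc)
    eig = eig[eig > 1e-12]
    return float(eig.sum() ** 2 / ((k - 1) * (eig**2).sum()))


def rm_anova(scores: pd.DataFrame, groups: pd.Series) -> AnovaResult:
    """Mixed ANOVA of the domain scores with one two-level between factor.

    ``scores`` is wide (one column per domain); ``groups`` aligns by row.
    Partial eta squared = SS_effect / (SS_effect + SS_error) with 95% CIs
    by noncentral-F inversion; per-domain post-hoc contrasts are pooled-
    variance two-sample t tests, Bonferroni-adjusted.  Uncorrected df are
    reported alongside the Greenhouse-Geisser epsilon.
    """
    y = scores.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise AnovaInputError("missing within-subject cells: complete cases only")
    groups = np.asarray(groups).astype(str)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise AnovaInputError("exactly two between-subject groups required")
    n, k = y.shape
    if n < 3 or k < 2:
        raise AnovaInputError("need >= 3 subjects and >= 2 within-subject levels")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    g_eff = np.where(groups == levels[0], 1.0, -1.0)

    # --- between-subject stratum (on subject means, scaled by k)
    xb = np.column_stack([np.ones(n), g_eff])
    beta_b, *_ = np.linalg.lstsq(xb, subj_means, rcond=None)
    resid_b = subj_means - xb @ beta_b
    ss_group = k * float(((xb @ beta_b - grand) ** 2).sum())
    ss_error_between = k * float((resid_b**2).sum())
    df_group, df_eb = 1, n - 2

    # --- within-subject stratum (subject-centered data, Type III)
    w = (y - subj_means[:, None]).ravel()
    dom = np.tile(np.arange(k), n)
    # sum-to-zero domain dummies
    d_cols = [np.where(dom == j, 1.0, 0.0) - np.where(dom == k - 1, 1.0, 0.0)
              for j in range(k - 1)]
    d_mat = np.column_stack(d_cols)
    g_long = np.repeat(g_eff, k)
    i_mat = d_mat * g_long[:, None]

    def rss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, w, rcond=None)
        r = w - x @ beta
        return float((r**2).sum())

    full = np.column_stack([d_mat, i_mat])
    rss_full = rss(full)
    rss_empty = float((w**2).sum())
    # sequential (domain before interaction): additive decomposition that
    # coincides with Type III in the balanced case
    ss_domain = rss_empty - rss(d_mat)
    ss_inter = rss(d_mat) - rss_full
    ss_error_within = rss_full
    df_domain = k - 1
    df_inter = k - 1
    df_ew = (n - 2) * (k - 1)

    rows = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("group", ss_group, df_group, ss_error_between, df_eb),
        ("domain", ss_domain, df_domain, ss_error_within, df_ew),
        ("group_x_domain", ss_inter, df_inter, ss_error_within, df_ew),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err))
        np2 = ss_eff / (ss_eff + ss_err)
        ci = partial_eta_sq_ci(f, df_eff, df_err)
        rows[name] = {
            "SS": ss_eff,
            "df1": df_eff,
            "df2": df_err,
            "F": f,
            "p": p,
            "partial_eta_sq": np2,
            "eta_ci_lo": ci[0],
            "eta_ci_hi": ci[1],
            "magnitude": eta_sq_label(np2),
        }
    effects = pd.DataFrame(rows).T

    posthoc_rows = {}
    m = k  # number of comparisons for Bonferroni
    for j, domain in enumerate(scores.columns):
        a = y[groups == levels[0], j]
        b = y[groups == levels[1], j]
        t, p = sps.ttest_ind(a, b, equal_var=True)
        dfc = len(a) + len(b) - 2
        np2 = t**2 / (t**2 + dfc)
        ci = partial_eta_sq_ci(t**2, 1, dfc)
        posthoc_rows[domain] = {
            "mean_diff": float(a.mean() - b.mean()),
            "t": float(t),
            "df": dfc,
            "p_bonferroni": float(min(1.0, p * m)),
            "partial_eta_sq": float(np2),
            "eta_ci_lo": ci[0],
            "eta_ci_hi": ci[1],
        }
    posthoc = pd.DataFrame(posthoc_rows).T

    ss_total = float(((y - grand) ** 2).sum())
    components = {
        "group": ss_group,
        "error_between": ss_error_between,
        "domain": ss_domain,
        "group_x_domain": ss_inter,
        "error_within": ss_error_within,
    }
    return AnovaResult(
        effects=effects,
        posthoc=posthoc,
        gg_epsilon=_gg_epsilon(y, groups),
        ss_total=ss_total,
        ss_components=components,
    )


# ---------------------------------------------------------------------------
# Logistic discrimination
# ---------------------------------------------------------------------------


def _check_separation(x: np.ndarray, y: np.ndarray, names) -> None:
    for j, name in enumerate(names):
        lo1, hi1 = x[y == 1, j].min(), x[y == 1, j].max()
        lo0, hi0 = x[y == 0, j].min(), x[y == 0, j].max()
        if lo1 > hi0 or lo0 > hi1:
            raise SeparationError(
                f"complete separation on predictor {name!r}: logistic MLE "
                "does not exist"
            )


def fit_logit(x: np.ndarray, y: np.ndarray, names=None):
    """Maximum-likelihood logistic fit (Newton IRLS, tol 1e-10).

    Raises :class:`SeparationError` on complete separation.  Returns the
    fitted statsmodels results object.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(x.shape[1])]
    _check_separation(x, y, names)
    design = sm.add_constant(x, has_constant="add")
    try:
        res = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        # Newton can fail the step-size criterion with the gradient already
        # at numerical zero (flat likelihood, e.g. rare outcomes); accept a
        # stationary point, otherwise report the trace
        score = np.asarray(res.mle_retvals.get("score", np.inf))
        if not np.all(np.abs(score) < 1e-6):
            raise RuntimeError(
                f"logistic fit did not converge: {res.mle_retvals}"
            )
    if np.max(np.abs(res.params)) > 1e3:
        raise SeparationError(
            "quasi-separation: diverging coefficients "
            f"{dict(zip(['const'] + names, res.params))}"
        )
    return res


def hosmer_lemeshow(
    y: np.ndarray, p: np.ndarray, n_groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over risk deciles: chi2, df, p."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    deciles = pd.qcut(p, n_groups, labels=False, duplicates="drop")
    g = int(deciles.max()) + 1
    chi2 = 0.0
    for i in range(g):
        mask = deciles == i
        o1 = y[mask].sum()
        e1 = p[mask].sum()
        n_i = mask.sum()
        chi2 += (o1 - e1) ** 2 / e1 + ((n_i - o1) - (n_i - e1)) ** 2 / (n_i - e1)
    df = g - 2
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


@dataclass
class LogisticResult:
    model_chi2: float
    model_df: int
    model_p: float
    coefficients: pd.DataFrame  # term, estimate, wald_chi2, p, odds_ratio
    hl_chi2: float
    hl_df: int
    hl_p: float
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "model_chi2": self.model_chi2,
            "model_df": self.model_df,
            "model_p": self.model_p,
            "coefficients": self.coefficients.to_dict(orient="index"),
            "hosmer_lemeshow": {"chi2": self.hl_chi2, "df": self.hl_df,
                                "p": self.hl_p},
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
        }


def logistic_discrimination(
    scores: pd.DataFrame,
    groups: pd.Series,
    cutoff: float = 0.5,
    positive: str = "CD",
) -> LogisticResult:
    """Predict group membership from the domain scores.

    Sensitivity = proportion of cases (``positive`` group) classified
    correctly at the probability cutoff; specificity the same for the
    other group; both carry Wilson score 95% CIs.
    """
    y = (np.asarray(groups).astype(str) == positive).astype(float)
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    x = scores.to_numpy(dtype=float)
    res = fit_logit(x, y, names=list(scores.columns))

    lr = 2.0 * (res.llf - res.llnull)
    df = x.shape[1]
    model_p = float(sps.chi2.sf(lr, df))

    terms = ["intercept"] + list(scores.columns)
    wald = (res.params / res.bse) ** 2
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "wald_chi2": wald,
            "p": sps.chi2.sf(wald, 1),
            "odds_ratio": np.exp(res.params),
        },
    )
    coef.index = terms

    p_hat = res.predict()
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(y, p_hat)

    pred = (p_hat >= cutoff).astype(float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    sens_ci = proportion_confint(tp, n_pos, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, n_neg, alpha=0.05, method="wilson")
    return LogisticResult(
        model_chi2=float(lr),
        model_df=df,
        model_p=model_p,
        coefficients=coef,
        hl_chi2=hl_chi2,
        hl_df=hl_df,
        hl_p=hl_p,
        cutoff=cutoff,
        sensitivity=float(sens),
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=float(spec),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )
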
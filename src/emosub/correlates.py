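"""Clinical scale scoring and deficit-correlate association models.

Scoring: the LPE (Limited Prosocial Emotions) proxy from the YPI CU-trait
subscales (a trait is endorsed when any of its items is answered "applies
very well"; LPE requires two or more endorsed traits), CU total scores,
and the RPQ reactive/proactive aggression sums.

Associations, within the CD group: one linear (continuous outcome) or
logistic (binary outcome) model per clinical variable with the three
deficit flags as predictors; two-group deficient-vs-intact contrasts
(chi-square for proportions, Welch t for means); and one logistic model
per domain flag on the risk-factor battery.  P-values are uncorrected, as
is conventional for these exploratory correlate analyses; a
Benjamini-Hochberg option exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import statsmodels.api as sm

from . import scales
from .config import DOMAINS
from .deficits import FLAG_COLUMNS
from .stats import SeparationError, fit_logit


class ItemValidationError(ValueError):
    """A questionnaire response is outside its admissible range."""


# ---------------------------------------------------------------------------
# Scale scoring
# ---------------------------------------------------------------------------


@dataclass
class LPEResult:
    trait_endorsed: dict[str, bool]
    n_traits: int
    lpe: bool
    cu_total: int


def _validate_items(values: np.ndarray, lo: int, hi: int, what: str) -> None:
    bad = (values < lo) | (values > hi) | (values != np.floor(values))
    if bad.any():
        idx = int(np.argwhere(bad)[0][-1]) + 1
        raise ItemValidationError(
            f"{what} item {idx} out of range [{lo}, {hi}]: {values[..., idx - 1]!r}"
        )


def score_lpe(ypi_items) -> LPEResult:
    """Score the 50 YPI items into CU-trait endorsements and the LPE proxy.

    Missing items are not allowed (no prorating); responses must be
    integers in 1-4.
    """
    items = np.asarray(ypi_items, dtype=float)
    if items.shape != (scales.N_YPI_ITEMS,):
        raise ItemValidationError(
            f"expected {scales.N_YPI_ITEMS} YPI responses, got {items.shape}"
        )
    if np.isnan(items).any():
        raise ItemValidationError("missing YPI responses are not allowed")
    _validate_items(items, *scales.YPI_RESPONSE_RANGE, what="YPI")
    endorsed = {}
    cu_total = 0
    for trait, idx in scales.CU_SUBSCALES.items():
        sub = items[np.asarray(idx) - 1]
        endorsed[trait] = bool((sub == scales.YPI_ENDORSE_VALUE).any())
        cu_total += int(sub.sum())
    n_traits = sum(endorsed.values())
    return LPEResult(
        trait_endorsed=endorsed,
        n_traits=n_traits,
        lpe=n_traits >= scales.LPE_MIN_TRAITS,
        cu_total=cu_total,
    )


def score_rpq(rpq_items) -> tuple[int, int]:
    """Reactive and proactive aggression sums from the 23 RPQ items (0-2)."""
    items = np.asarray(rpq_items, dtype=float)
    if items.shape != (scales.N_RPQ_ITEMS,):
        raise ItemValidationError(
            f"expected {scales.N_RPQ_ITEMS} RPQ responses, got {items.shape}"
        )
    _validate_items(items, *scales.RPQ_RESPONSE_RANGE, what="RPQ")
    reactive = int(items[np.asarray(scales.RPQ_REACTIVE) - 1].sum())
    proactive = int(items[np.asarray(scales.RPQ_PROACTIVE) - 1].sum())
    return reactive, proactive


def score_clinical_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Scored scales for a whole cohort's clinical item table.

    Vectorized application of the same rules as :func:`score_lpe` and
    :func:`score_rpq` (the per-participant functions are the definitional
    reference).
    """
    ypi_cols = [f"ypi_{j:02d}" for j in range(1, scales.N_YPI_ITEMS + 1)]
    rpq_cols = [f"rpq_{j:02d}" for j in range(1, scales.N_RPQ_ITEMS + 1)]
    ypi = clinical[ypi_cols].to_numpy(dtype=float)
    rpq = clinical[rpq_cols].to_numpy(dtype=float)
    if np.isnan(ypi).any():
        raise ItemValidationError("missing YPI responses are not allowed")
    _validate_items(ypi, *scales.YPI_RESPONSE_RANGE, what="YPI")
    _validate_items(rpq, *scales.RPQ_RESPONSE_RANGE, what="RPQ")
    n_traits = np.zeros(len(clinical), dtype=int)
    cu_total = np.zeros(len(clinical), dtype=int)
    for idx in scales.CU_SUBSCALES.values():
        sub = ypi[:, np.asarray(idx) - 1]
        n_traits += (sub == scales.YPI_ENDORSE_VALUE).any(axis=1)
        cu_total += sub.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "id": clinical["id"].to_numpy(),
            "lpe": n_traits >= scales.LPE_MIN_TRAITS,
            "n_cu_traits": n_traits,
            "cu_total": cu_total,
            "rpq_reactive": rpq[:, np.asarray(scales.RPQ_REACTIVE) - 1]
            .sum(axis=1)
            .astype(int),
            "rpq_proactive": rpq[:, np.asarray(scales.RPQ_PROACTIVE) - 1]
            .sum(axis=1)
            .astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Association models
# ---------------------------------------------------------------------------

RISK_PREDICTORS = (
    "sex_male",
    "iq",
    "maternal_smoking",
    "ses",
    "parental_delinquency",
    "ceca_total",
    "saha_deviant_peers",
)


@dataclass
class AssociationResult:
    models: pd.DataFrame  # tidy: outcome, model, predictor, estimate, stat, p
    contrasts: pd.DataFrame  # deficient-vs-intact two-group tests
    skipped: tuple[str, ...] = ()

    def to_csv_frames(self) -> dict[str, pd.DataFrame]:
        return {"models": self.models, "contrasts": self.contrasts}


def _tidy_linear(outcome: str, x: pd.DataFrame, y: np.ndarray) -> list[dict]:
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, design).fit()
    rows = []
    for j, name in enumerate(["intercept"] + list(x.columns)):
        rows.append(
            {
                "outcome": outcome,
                "model": "linear",
                "predictor": name,
                "estimate": res.params[j],
                "statistic": res.tvalues[j],
                "p": res.pvalues[j],
            }
        )
    return rows


def _tidy_logistic(outcome: str, x: pd.DataFrame, y: np.ndarray) -> list[dict]:
    res = fit_logit(x.to_numpy(dtype=float), y, names=list(x.columns))
    wald = (res.params / res.bse) ** 2
    rows = []
    for j, name in enumerate(["intercept"] + list(x.columns)):
        rows.append(
            {
                "outcome": outcome,
                "model": "logistic",
                "predictor": name,
                "estimate": np.exp(res.params[j]),  # odds ratio
                "statistic": wald[j],
                "p": sps.chi2.sf(wald[j], 1),
            }
        )
    return rows


def deficit_associations(
    flags: pd.DataFrame,
    clinical: pd.DataFrame,
    continuous_outcomes=("cd_symptom_count", "cu_total", "rpq_reactive",
                         "rpq_proactive"),
    binary_outcomes=("lpe", "dx_adhd", "dx_odd", "dx_mdd", "dx_gad", "dx_ptsd",
                     "dx_sud"),
    group: str = "CD",
    fdr: bool = False,
) -> AssociationResult:
    """Associations between the three deficit flags and clinical variables.

    One model per outcome with the three flags as simultaneous predictors
    (linear for continuous, logistic for binary outcomes), within the CD
    subset, plus deficient-vs-intact two-group contrasts per flag
    (chi-square for binary outcomes, Welch t for continuous).
    """
    merged = flags.merge(clinical, on="id", how="inner")
    sub = merged[merged["group"] == group]
    if sub.empty:
        raise ValueError(f"no participants in group {group!r}")
    x = sub[list(FLAG_COLUMNS)].astype(float)
    skipped = []
    rows: list[dict] = []
    if x.nunique().le(1).all():
        import warnings

        warnings.warn("all deficit flags constant: association models skipped",
                      stacklevel=2)
        skipped.extend(list(continuous_outcomes) + list(binary_outcomes))
        return AssociationResult(
            models=pd.DataFrame(
                columns=["outcome", "model", "predictor", "estimate",
                         "statistic", "p"]
            ),
            contrasts=pd.DataFrame(
                columns=["flag", "outcome", "kind", "deficient", "intact",
                         "statistic", "p"]
            ),
            skipped=tuple(skipped),
        )
    for outcome in continuous_outcomes:
        y = sub[outcome].to_numpy(dtype=float)
        if np.var(y) == 0:
            skipped.append(outcome)
            continue
        rows.extend(_tidy_linear(outcome, x, y))
    for outcome in binary_outcomes:
        y = sub[outcome].to_numpy(dtype=float)
        if y.min() == y.max():
            skipped.append(outcome)
            continue
        try:
            rows.extend(_tidy_logistic(outcome, x, y))
        except (SeparationError, np.linalg.LinAlgError, RuntimeError):
            skipped.append(outcome)
    models = pd.DataFrame(rows)
    if fdr and not models.empty:
        models["p_fdr"] = multipletests(models["p"], method="fdr_bh")[1]

    contrast_rows = []
    for flag_col, domain in zip(FLAG_COLUMNS, DOMAINS):
        flag = sub[flag_col].astype(bool)
        if flag.nunique() < 2:
            continue
        for outcome in binary_outcomes:
            y = sub[outcome].astype(bool)
            table = pd.crosstab(flag, y)
            if table.shape != (2, 2):
                continue
            chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(),
                                                 correction=False)
            contrast_rows.append(
                {
                    "flag": domain,
                    "outcome": outcome,
                    "kind": "chi2",
                    "deficient": float(y[flag].mean()),
                    "intact": float(y[~flag].mean()),
                    "statistic": float(chi2),
                    "p": float(p),
                }
            )
        for outcome in continuous_outcomes:
            y = sub[outcome].astype(float)
            t, p = sps.ttest_ind(y[flag], y[~flag], equal_var=False)
            contrast_rows.append(
                {
                    "flag": domain,
                    "outcome": outcome,
                    "kind": "welch_t",
                    "deficient": float(y[flag].mean()),
                    "intact": float(y[~flag].mean()),
                    "statistic": float(t),
                    "p": float(p),
                }
            )
    contrasts = pd.DataFrame(contrast_rows)
    return AssociationResult(models=models, contrasts=contrasts,
                             skipped=tuple(skipped))


def risk_factor_models(
    flags: pd.DataFrame,
    participants: pd.DataFrame,
    clinical: pd.DataFrame,
    group: str = "CD",
) -> AssociationResult:
    """One logistic model per domain flag on the risk-factor battery.

    Predictors: sex, IQ, maternal smoking, SES, parental delinquency,
    childhood adversity (CECA total) and deviant-peer affiliation (SAHA),
    fitted on the CD subset; Wald chi-square and odds ratios reported per
    predictor.
    """
    demo = participants[["id", "group", "sex", "iq", "ses"]].copy()
    demo["sex_male"] = (demo["sex"].astype(str) == "M").astype(float)
    merged = flags.drop(columns=["group"], errors="ignore").merge(
        demo, on="id"
    ).merge(
        clinical[["id", "maternal_smoking", "parental_delinquency", "ceca_total",
                  "saha_deviant_peers"]],
        on="id",
    )
    sub = merged[merged["group"] == group]
    if sub.empty:
        raise ValueError(f"no participants in group {group!r}")
    rows = []
    skipped = []
    x = sub[list(RISK_PREDICTORS)].astype(float)
    constant_cols = [c for c in x.columns if x[c].nunique() < 2]
    if constant_cols:
        skipped.extend(f"predictor:{c}" for c in constant_cols)
        x = x.drop(columns=constant_cols)
    for flag_col, domain in zip(FLAG_COLUMNS, DOMAINS):
        y = sub[flag_col].astype(float).to_numpy()
        if y.min() == y.max():
            skipped.append(f"{domain} (flag constant)")
            continue
        try:
            for row in _tidy_logistic(f"{domain}_deficit", x, y):
                rows.append(row)
        except (SeparationError, np.linalg.LinAlgError, RuntimeError) as exc:
            skipped.append(f"{domain} ({exc.__class__.__name__})")
    return AssociationResult(
        models=pd.DataFrame(rows),
        contrasts=pd.DataFrame(
            columns=["flag", "outcome", "kind", "deficient", "intact",
                     "statistic", "p"]
        ),
        skipped=tuple(skipped),
    )
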
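"""Covariate adjustment of raw performance variables.

Each of the 20 raw scores is regressed on age, IQ and sex by ordinary
least squares; residuals are standardized by the fit-sample residual SD,
yielding z-scores that are orthogonal to the covariates over the fit
sample.  The fit sample is either the pooled case-control sample (the
replication default) or the controls only (the normative alternative);
residuals are computed and standardized for *all* rows either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVARIATES = ("age", "iq", "sex_male")


class DegenerateInputError(ValueError):
    """A score column has (near-)zero variance and cannot be standardized."""


class RankDeficiencyError(ValueError):
    """The covariate design matrix is rank-deficient (collinear covariates)."""


@dataclass
class ZScoreTable:
    """Adjusted, standardized scores plus the fitted adjustment model.

    ``z`` keeps the raw table's column names and row order; each column has
    mean 0 and SD 1 over the fit sample.  ``coefficients`` is a tidy table
    (variable, term, estimate) retaining the OLS fit for audit, and
    ``residual_sd`` the per-variable fit-sample residual SD used for
    standardization.
    """

    z: pd.DataFrame
    coefficients: pd.DataFrame
    residual_sd: pd.Series
    fit_sample: str = "pooled"
    degenerate_columns: tuple[str, ...] = field(default_factory=tuple)

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.z.copy()
        out.columns = [f"{c}_z" for c in out.columns]
        return out


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    if covariates[["age", "iq"]].isna().any().any() or covariates["sex"].isna().any():
        raise ValueError("missing covariates: adjustment is complete-case only")
    male = (covariates["sex"].astype(str) == "M").astype(float).to_numpy()
    x = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(dtype=float),
            covariates["iq"].to_numpy(dtype=float),
            male,
        ]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError(
            "covariate design matrix is rank-deficient (collinear covariates)"
        )
    return x


def residualize(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    fit_sample: str = "pooled",
    groups: pd.Series | None = None,
) -> ZScoreTable:
    """Age-, IQ- and sex-adjust all score columns into standardized residuals.

    Parameters
    ----------
    scores:
        Wide table of raw performance variables (numeric columns only).
    covariates:
        Must contain ``age``, ``iq`` and ``sex`` ("F"/"M"), aligned by row
        order with ``scores``.
    fit_sample:
        "pooled" fits the regressions on all rows; "controls_only" fits on
        the rows where ``groups == "TDC"`` (``groups`` then required).
    """
    if len(scores) != len(covariates):
        raise ValueError("scores and covariates must have the same number of rows")
    if fit_sample == "pooled":
        mask = np.ones(len(scores), dtype=bool)
    elif fit_sample == "controls_only":
        if groups is None:
            raise ValueError("fit_sample='controls_only' requires group labels")
        mask = (np.asarray(groups).astype(str) == "TDC")
        if not mask.any():
            raise ValueError("no control rows available for fitting")
    else:
        raise ValueError(f"unknown fit_sample {fit_sample!r}")

    x = _design_matrix(covariates.reset_index(drop=True))
    y = scores.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing scores: adjustment is complete-case only")

    variances = y[mask].var(axis=0)
    degenerate = [c for c, v in zip(scores.columns, variances) if v < 1e-24]
    if degenerate:
        raise DegenerateInputError(
            f"zero-variance score column(s) over the fit sample: {degenerate}"
        )

    beta, *_ = np.linalg.lstsq(x[mask], y[mask], rcond=None)
    resid = y - x @ beta
    sd = resid[mask].std(axis=0, ddof=0)
    flat = [c for c, s in zip(scores.columns, sd) if s < 1e-12]
    if flat:
        raise DegenerateInputError(
            "score column(s) exactly linear in the covariates "
            f"(zero residual variance): {flat}"
        )
    z = pd.DataFrame(
        (resid - resid[mask].mean(axis=0)) / sd,
        columns=scores.columns,
        index=scores.index,
    )
    terms = ("intercept", "age", "iq", "sex_male")
    coef = pd.DataFrame(
        [
            {"variable": col, "term": term, "estimate": beta[t, j]}
            for j, col in enumerate(scores.columns)
            for t, term in enumerate(terms)
        ]
    )
    return ZScoreTable(
        z=z,
        coefficients=coef,
        residual_sd=pd.Series(sd, index=scores.columns),
        fit_sample=fit_sample,
    )
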
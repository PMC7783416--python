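"""Synthetic case-control cohort generator.

Produces participants (demographics + age bracket), latent ability profiles
(three correlated domain abilities with a deficit-class mixture over the
eight Venn cells) and clinical records (YPI/RPQ items, diagnoses, risk
factors).  The latent design is the minimal generative model under which
the downstream person-centered classifier's estimand -- the prevalence of
each deficit cell -- is well defined and recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit

from . import scales
from .config import (
    CELL_FLAGS,
    CELLS,
    DOMAINS,
    ClinicalParams,
    CohortConfig,
)

GROUPS = ("CD", "TDC")
COMORBIDITIES = ("ODD", "ADHD", "SUD", "MDD", "PTSD", "GAD")

ABILITY_COLUMNS = tuple(f"ability_{d}" for d in DOMAINS)
TRUE_FLAG_COLUMNS = tuple(f"true_{d}_deficit" for d in DOMAINS)


@dataclass
class Cohort:
    """A generated cohort: one row per participant in each table.

    ``participants`` carries demographics and the latent profile
    (abilities, deficit class); ``clinical`` carries questionnaire items,
    diagnostic fields and risk factors.  Row order matches across tables.
    """

    participants: pd.DataFrame
    clinical: pd.DataFrame
    config: CohortConfig = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.participants)

    def abilities(self) -> np.ndarray:
        return self.participants[list(ABILITY_COLUMNS)].to_numpy()


def assign_bracket(ages: np.ndarray, config: CohortConfig) -> pd.Categorical:
    """Assign the unique age bracket containing each age (closed on the left)."""
    labels = list(config.bracket_labels)
    idx = np.searchsorted(config.bracket_edges, ages, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    return pd.Categorical.from_codes(idx, categories=labels)


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal draws truncated below by redrawing (exclusion, not censoring)."""
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def _draw_deficit_cells(
    rng: np.random.Generator,
    base_probs: np.ndarray,
    tilt_logits: np.ndarray,
) -> np.ndarray:
    """Draw cell indices; per-participant logit tilts re-weight cells.

    ``tilt_logits`` has shape (n, 3): the log-odds adjustment applied to
    every cell containing the corresponding domain, then renormalized.
    """
    n = tilt_logits.shape[0]
    flags = np.array([CELL_FLAGS[c] for c in CELLS], dtype=float)  # (8, 3)
    logw = np.log(np.where(base_probs > 0, base_probs, 1e-300))
    logits = logw[None, :] + tilt_logits @ flags.T  # (n, 8)
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w[:, base_probs == 0] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)


def generate_participants(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Demographics plus latent profiles for n_cd + n_tdc participants."""
    frames = []
    corr = np.asarray(config.domain_corr, dtype=float)
    chol = np.linalg.cholesky(corr)
    betas = np.asarray(config.covariate_betas, dtype=float)
    for group, n in (("CD", config.n_cd), ("TDC", config.n_tdc)):
        age = rng.uniform(*config.age_range, size=n)
        female = rng.random(n) < config.sex_ratio_by_group[group]
        iq_mean, iq_sd = config.iq_mean_sd_by_group[group]
        iq = _draw_truncated_normal(rng, iq_mean, iq_sd, config.iq_floor, n)
        ses_mean, ses_sd = config.ses_mean_sd_by_group[group]
        ses = rng.normal(ses_mean, ses_sd, n)

        probs_name = "deficit_class_probs_cd" if group == "CD" else "deficit_class_probs_tdc"
        base_probs = np.asarray(getattr(config, probs_name), dtype=float)
        tilt = np.zeros((n, 3))
        if group == "CD":
            male = (~female).astype(float)
            tilt += male[:, None] * np.asarray(config.class_tilt_sex_male)
            tilt += (100.0 - iq)[:, None] * np.asarray(config.class_tilt_low_iq)
        cell_idx = _draw_deficit_cells(rng, base_probs, tilt)
        deficit = np.array([CELL_FLAGS[CELLS[i]] for i in cell_idx], dtype=float)

        x = np.column_stack([age - 14.0, iq - 100.0, (~female).astype(float)])
        u = rng.standard_normal((n, 3)) @ chol.T
        ability = x @ betas + config.noise_sd * u
        ability -= config.deficit_shift * deficit
        if group == "CD":
            ability += config.group_shift_cd

        frame = pd.DataFrame(
            {
                "group": group,
                "age": age,
                "sex": np.where(female, "F", "M"),
                "iq": iq,
                "ses": ses,
                "deficit_class": [CELLS[i] for i in cell_idx],
            }
        )
        for j, col in enumerate(ABILITY_COLUMNS):
            frame[col] = ability[:, j]
        for j, col in enumerate(TRUE_FLAG_COLUMNS):
            frame[col] = deficit[:, j].astype(bool)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"P{i:05d}" for i in range(len(out))])
    out["bracket"] = assign_bracket(out["age"].to_numpy(), config)
    return out


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------


def _lpe_probability(mu: float, threshold: float, n_items: int = 5) -> float:
    """P(LPE) under the graded model with CU latent ~ N(mu, 1).

    A trait is endorsed when any of its ``n_items`` items is answered at
    the top response, each with probability sigmoid(c - threshold) given
    the latent c; LPE requires >= 2 of 3 traits.
    """

    def integrand(u: float) -> float:
        c = mu + u
        p4 = expit(c - threshold)
        pe = 1.0 - (1.0 - p4) ** n_items
        p_lpe = 3 * pe**2 * (1 - pe) + pe**3
        return float(np.exp(-0.5 * u * u) / np.sqrt(2 * np.pi) * p_lpe)

    val, _ = quad(integrand, -8, 8, limit=200)
    return val


def calibrate_cu_mean(target: float, threshold: float) -> float:
    """Solve for the CU latent mean giving the target LPE prevalence."""
    if not 0 < target < 1:
        raise ValueError("LPE target prevalence must lie in (0, 1)")
    return brentq(lambda m: _lpe_probability(m, threshold) - target, -8.0, 8.0)


def _graded_items(
    rng: np.random.Generator,
    latent: np.ndarray,
    thresholds: np.ndarray,
    n_items: int,
) -> np.ndarray:
    """Ordered-logit draws: response = base + #{j : U_j < sigmoid(c - a_j)}."""
    c = latent[:, None, None]
    a = thresholds[None, None, :]
    p_ge = expit(c - a)  # (n, 1, k) cumulative exceedance probabilities
    u = rng.random((latent.shape[0], n_items, 1))
    return (u < p_ge).sum(axis=2)


def simulate_clinical(
    participants: pd.DataFrame,
    params: ClinicalParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Questionnaire items, diagnostic fields and risk factors per participant.

    YPI responses come from a graded response model on a participant CU
    latent whose group means are calibrated so the scored LPE proxy hits
    the configured prevalence targets.  Risk factors are drawn conditional
    on the latent deficit flags, which plants the configured odds ratios.
    """
    n = len(participants)
    group = participants["group"].to_numpy()
    is_cd = group == "CD"
    ypi_thresholds = np.asarray(params.ypi_thresholds, dtype=float)
    top_threshold = float(ypi_thresholds[-1])

    cu_mu = {
        g: calibrate_cu_mean(params.lpe_target_by_group[g], top_threshold)
        for g in GROUPS
    }
    cu_latent = rng.standard_normal(n) + np.where(is_cd, cu_mu["CD"], cu_mu["TDC"])

    ypi = np.ones((n, scales.N_YPI_ITEMS), dtype=int)
    ypi += _graded_items(rng, cu_latent, ypi_thresholds, scales.N_YPI_ITEMS)

    agg_mu = np.where(
        is_cd,
        params.rpq_latent_mean_by_group["CD"],
        params.rpq_latent_mean_by_group["TDC"],
    )
    agg_latent = rng.standard_normal(n) + agg_mu
    rpq = np.zeros((n, scales.N_RPQ_ITEMS), dtype=int)
    for sub, items in (
        ("reactive", scales.RPQ_REACTIVE),
        ("proactive", scales.RPQ_PROACTIVE),
    ):
        th = np.asarray(params.rpq_thresholds[sub], dtype=float)
        rpq[:, np.asarray(items) - 1] = _graded_items(rng, agg_latent, th, len(items))

    symptoms = np.where(
        is_cd,
        3 + rng.binomial(12, params.cd_symptom_extra_p, n),
        np.where(
            rng.random(n) < params.tdc_subthreshold_p, 1 + rng.binomial(1, 0.3, n), 0
        ),
    )
    onset_idx = (
        rng.random(n)[:, None] > np.cumsum(params.onset_probs)[None, :]
    ).sum(axis=1)
    onset = np.where(
        is_cd,
        np.array(["childhood", "adolescence", "unspecified"])[onset_idx],
        "none",
    )

    record = pd.DataFrame({"id": participants["id"].to_numpy()})
    for j in range(scales.N_YPI_ITEMS):
        record[f"ypi_{j + 1:02d}"] = ypi[:, j]
    for j in range(scales.N_RPQ_ITEMS):
        record[f"rpq_{j + 1:02d}"] = rpq[:, j]
    record["cd_symptom_count"] = symptoms
    record["onset_type"] = onset
    for dx in COMORBIDITIES:
        p = np.where(is_cd, params.comorbidity_p_cd[dx], 0.0)
        record[f"dx_{dx.lower()}"] = rng.random(n) < p

    lrn_flag = participants["true_learning_deficit"].to_numpy().astype(float)
    smoke_base = np.where(
        is_cd, params.smoking_base_by_group["CD"], params.smoking_base_by_group["TDC"]
    )
    smoke_logit = np.log(smoke_base / (1 - smoke_base))
    smoke_logit = smoke_logit + np.where(is_cd, params.smoking_lrn_log_or * lrn_flag, 0.0)
    record["maternal_smoking"] = rng.random(n) < expit(smoke_logit)
    delinq_p = np.where(
        is_cd,
        params.delinquency_base_by_group["CD"],
        params.delinquency_base_by_group["TDC"],
    )
    record["parental_delinquency"] = rng.random(n) < delinq_p
    ceca_mean = np.where(
        is_cd, params.ceca_mean_by_group["CD"], params.ceca_mean_by_group["TDC"]
    )
    record["ceca_total"] = rng.poisson(ceca_mean)
    saha_p = np.where(
        is_cd, params.saha_item_p_by_group["CD"], params.saha_item_p_by_group["TDC"]
    )
    record["saha_deviant_peers"] = 9 + rng.binomial(27, saha_p)
    return record


def generate_cohort(
    config: CohortConfig,
    clinical_params: ClinicalParams | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate a full cohort (participants + clinical records).

    Reproducible: the same config and seed give a bit-identical cohort.
    ``seed`` overrides ``config.seed`` when given.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    participants = generate_participants(config, rng)
    clinical = simulate_clinical(
        participants, clinical_params or ClinicalParams(), rng
    )
    return Cohort(participants=participants, clinical=clinical, config=config)
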
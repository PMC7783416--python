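"""Configuration objects for cohort simulation and the analysis pipeline.

All tunable quantities live in small frozen-ish dataclasses that can be
round-tripped through YAML.  Validation happens eagerly in
``__post_init__`` so that malformed configurations fail at construction,
not deep inside a simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

DOMAINS = ("recognition", "learning", "regulation")

#: Canonical order of the 2^3 deficit cells (subsets of {REC, LRN, REG}).
CELLS = (
    "none",
    "REC",
    "LRN",
    "REG",
    "REC+LRN",
    "REC+REG",
    "LRN+REG",
    "REC+LRN+REG",
)

#: Cell -> (recognition, learning, regulation) deficit indicator.
CELL_FLAGS: dict[str, tuple[int, int, int]] = {
    "none": (0, 0, 0),
    "REC": (1, 0, 0),
    "LRN": (0, 1, 0),
    "REG": (0, 0, 1),
    "REC+LRN": (1, 1, 0),
    "REC+REG": (1, 0, 1),
    "LRN+REG": (0, 1, 1),
    "REC+LRN+REG": (1, 1, 1),
}


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


def _independent_cell_probs(q: float) -> tuple[float, ...]:
    """Cell probabilities when the three domains are deficient independently."""
    probs = []
    for cell in CELLS:
        flags = CELL_FLAGS[cell]
        p = 1.0
        for f in flags:
            p *= q if f else (1.0 - q)
        probs.append(p)
    return tuple(probs)


@dataclass
class CohortConfig:
    """Design of a synthetic case-control cohort.

    Latent model: each participant has a 3-vector of domain abilities
    (recognition, learning, regulation) in SD units,

        ability = group_shift + B @ (age-14, iq-100, male) + noise_sd * u
                  - deficit_shift * deficit_indicator,

    with ``u ~ MVN(0, domain_corr)`` and the deficit indicator drawn from a
    group-specific mixture over the 8 Venn cells.  ``deficit_shift`` is the
    latent decrement of a deficient domain; the per-group cell mixtures are
    the generative counterpart of the deficit-overlap diagram the classifier
    is later asked to recover.
    """

    n_cd: int = 542
    n_tdc: int = 710
    age_range: tuple[float, float] = (9.0, 19.0)
    #: Bracket edges partition the age range; brackets are closed on the left
    #: ([9,13), [13,16), [16,19)), labelled 9-12 / 13-15 / 16-18.
    bracket_edges: tuple[float, ...] = (9.0, 13.0, 16.0, 19.0)
    sex_ratio_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.585, "TDC": 0.675}
    )  # proportion female
    iq_mean_sd_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CD": (94.9, 12.4), "TDC": (103.5, 12.2)}
    )
    ses_mean_sd_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CD": (-0.29, 0.93), "TDC": (0.28, 1.03)}
    )
    iq_floor: float = 70.0  # exclusion criterion: IQ < 70
    deficit_class_probs_cd: tuple[float, ...] = (
        0.563,
        0.157,
        0.077,
        0.110,
        0.023,
        0.040,
        0.020,
        0.010,
    )
    deficit_class_probs_tdc: tuple[float, ...] = field(
        default_factory=lambda: _independent_cell_probs(0.10)
    )
    domain_corr: tuple[tuple[float, ...], ...] = (
        (1.0, 0.3, 0.3),
        (0.3, 1.0, 0.3),
        (0.3, 0.3, 1.0),
    )
    deficit_shift: float = 1.8  # SD units (latent decrement per deficient domain)
    group_shift_cd: float = -0.15  # small mean shift for CD, all domains
    #: rows = covariates (age-14, iq-100, male), columns = domains.
    covariate_betas: tuple[tuple[float, ...], ...] = (
        (0.05, 0.05, 0.05),
        (0.015, 0.015, 0.015),
        (-0.05, 0.0, -0.05),
    )
    noise_sd: float = 1.0  # residual SD of latent abilities
    #: Optional per-domain logit tilt of the deficit-cell mixture for males
    #: (CD only); used to plant a sex -> recognition-deficit association.
    class_tilt_sex_male: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: Per-domain logit tilt per IQ point below 100 (CD only).
    class_tilt_low_iq: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cd <= 0 or self.n_tdc <= 0:
            raise ConfigError("group sizes n_cd and n_tdc must be positive")
        lo, hi = self.age_range
        edges = tuple(float(e) for e in self.bracket_edges)
        if not (edges[0] == lo and edges[-1] == hi and np.all(np.diff(edges) > 0)):
            raise ConfigError("bracket_edges must partition the age range")
        for name in ("deficit_class_probs_cd", "deficit_class_probs_tdc"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.shape != (8,):
                raise ConfigError(f"{name} must have 8 entries (one per Venn cell)")
            if np.any(probs < 0):
                raise ConfigError(f"{name} must be non-negative")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must sum to 1 (got {probs.sum()!r})")
        corr = np.asarray(self.domain_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("domain_corr must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise ConfigError("domain_corr must be positive-definite")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigError("domain_corr must have a unit diagonal")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        betas = np.asarray(self.covariate_betas, dtype=float)
        if betas.shape != (3, 3):
            raise ConfigError("covariate_betas must be 3x3 (age/iq/sex by domain)")

    @property
    def bracket_labels(self) -> tuple[str, ...]:
        labels = []
        edges = self.bracket_edges
        for lo, hi in zip(edges[:-1], edges[1:]):
            labels.append(f"{int(lo)}-{int(hi) - 1}")
        return tuple(labels)


@dataclass
class ClinicalParams:
    """Generative settings for questionnaire items, diagnoses and risk factors.

    The YPI CU-item model is a graded (ordered-logit) response model on a
    participant-level CU latent trait; its group means are calibrated
    numerically so that the prevalence of the LPE proxy matches
    ``lpe_target_by_group``.
    """

    lpe_target_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.437, "TDC": 0.183}
    )
    #: Ordered-logit thresholds for YPI items: P(y >= j+1) = sigmoid(c - a_j).
    ypi_thresholds: tuple[float, float, float] = (-0.5, 1.0, 2.2)
    #: Ordered-logit thresholds for RPQ items per subscale.
    rpq_thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"reactive": (-0.9, 1.0), "proactive": (0.5, 2.0)}
    )
    rpq_latent_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.8, "TDC": -0.3}
    )
    cd_symptom_extra_p: float = 0.204  # CD count = 3 + Binomial(12, p)
    tdc_subthreshold_p: float = 0.05  # TDCs with 1-2 subthreshold symptoms
    onset_probs: tuple[float, float, float] = (0.430, 0.533, 0.037)
    comorbidity_p_cd: dict[str, float] = field(
        default_factory=lambda: {
            "ODD": 0.782,
            "ADHD": 0.384,
            "SUD": 0.174,
            "MDD": 0.148,
            "PTSD": 0.067,
            "GAD": 0.030,
        }
    )
    smoking_base_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.28, "TDC": 0.15}
    )
    #: log odds ratio of maternal smoking given a learning deficit (CD only).
    smoking_lrn_log_or: float = float(np.log(3.2))
    delinquency_base_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.20, "TDC": 0.06}
    )
    ceca_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 6.0, "TDC": 3.0}
    )
    saha_item_p_by_group: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.42, "TDC": 0.22}
    )


@dataclass
class TaskParams:
    """Psychometric parameters of the three task simulators.

    Slopes are on the latent-ability (SD) scale; intercepts set baseline
    difficulty.  Defaults were chosen so that each variable group reaches
    the internal-consistency level typical of these paradigms
    (Cronbach's alpha >= 0.70 on a default cohort).
    """

    # Emotion Hexagon: P(correct) = sigmoid(intercept_morph + slope * ability)
    hex_intercept_90: float = 2.2
    hex_intercept_70: float = 1.3
    hex_slope: float = 1.1
    hex_timeout_p: float = 0.01
    hex_other_prototype_mass: float = 0.7  # error mass on the continuum partner
    # Passive Avoidance: per-stimulus response propensity, updated on feedback
    pa_init_propensity: float = 0.5
    pa_lr_intercept: float = -0.3
    pa_lr_ability: float = 1.2  # learning-rate sensitivity to ability (punishment)
    pa_reward_ability_frac: float = 0.25  # reward learning uses this fraction
    pa_lr_magnitude: float = 0.8  # scaled by magnitude/2000
    pa_bias_sd: float = 1.0  # SD of the response-bias trait (logit units)
    # Emotional Go/Nogo: P(false alarm) = sigmoid(base + offset - slope*ability)
    gonogo_base: float = -1.4
    gonogo_slope: float = 1.0
    gonogo_go_response_p: float = 0.97
    gonogo_interference: dict[str, float] = field(
        default_factory=lambda: {
            "neutral-happy": 0.00,
            "neutral-fearful": 0.10,
            "happy-neutral": 0.05,
            "fearful-neutral": 0.15,
            "happy-fearful": 0.25,
            "fearful-happy": 0.25,
        }
    )


@dataclass
class AnalysisOptions:
    """Options of the deterministic analysis stages."""

    q: float = 0.10  # normative deficit quantile
    fit_sample: str = "pooled"  # {"pooled", "controls_only"} for adjustment
    quantile_method: str = "linear"  # {"linear", "nearest_rank"}
    boundary_inclusive: bool = True  # score == cutoff counts as deficient
    n_boot: int = 2000  # bootstrap resamples for mean-correlation CIs
    k_components: int = 3
    logistic_cutoff: float = 0.5
    min_controls_per_bracket: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigError("q must lie in (0, 1)")
        if self.fit_sample not in ("pooled", "controls_only"):
            raise ConfigError("fit_sample must be 'pooled' or 'controls_only'")
        if self.quantile_method not in ("linear", "nearest_rank"):
            raise ConfigError("quantile_method must be 'linear' or 'nearest_rank'")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    tasks: TaskParams = field(default_factory=TaskParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def _coerce(cls, data: dict):
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_types)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if isinstance(value, dict):
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
        kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    unknown = set(data) - {"cohort", "clinical", "tasks", "analysis"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(
        cohort=_coerce(CohortConfig, data.get("cohort", {})),
        clinical=_coerce(ClinicalParams, data.get("clinical", {})),
        tasks=_coerce(TaskParams, data.get("tasks", {})),
        analysis=_coerce(AnalysisOptions, data.get("analysis", {})),
    )


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
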
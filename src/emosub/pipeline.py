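"""End-to-end orchestration: simulate -> score -> adjust -> factor ->
classify -> stats -> correlates, with seeded substreams, per-stage CSV
outputs, a consolidated JSON + text report, and a hash-chained run
manifest.

A single global seed deterministically spawns independent substreams for
the cohort generator, the task simulators and the bootstrap, so stage
outputs are bit-reproducible given (config, seed).  All analysis stages
downstream of task simulation are deterministic functions of their
inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adjust, correlates, deficits, factors, stats, tasks
from .cohortgen import Cohort, generate_cohort
from .config import DOMAINS, PipelineConfig, config_to_dict
from .tasks import DOMAIN_PARTITION

REPORT_SECTIONS = (
    "diagnostics",
    "factor_solution",
    "anova",
    "logistic",
    "thresholds",
    "venn",
    "independence_expectation",
    "clinical_correlates",
    "risk_factors",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    stages: list = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add_stage(self, name: str, outputs: list[dict]) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, index=False, float_format="%.10g")
    return {"path": path.name, "rows": int(len(df)), "sha256": _sha256(path)}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class PipelineResult:
    cohort: Cohort
    scores: pd.DataFrame
    ztable: adjust.ZScoreTable
    diagnostics: factors.CorrDiagnostics
    solution: factors.FactorSolution
    factor_scores: pd.DataFrame  # performance-oriented, columns = domains
    thresholds: deficits.NormativeThresholds
    flags: pd.DataFrame
    venn: deficits.VennSummary
    anova: stats.AnovaResult
    logistic: stats.LogisticResult
    clinical_scores: pd.DataFrame
    associations: correlates.AssociationResult
    risk_models: correlates.AssociationResult
    manifest: RunManifest | None = None

    def report_dict(self) -> dict:
        opts = {}
        return {
            "diagnostics": self.diagnostics.to_dict(),
            "factor_solution": {
                "loadings": self.solution.loadings.round(6).to_dict(),
                "eigenvalues": list(self.solution.eigenvalues),
                "variance_explained": list(self.solution.variance_explained),
                "total_variance_explained": self.solution.total_variance_explained,
                "domain_assignment": self.solution.domain_assignment,
            },
            "anova": self.anova.to_dict(),
            "logistic": self.logistic.to_dict(),
            "thresholds": {
                "cutoffs": self.thresholds.cutoffs.to_dict(),
                "n_controls": self.thresholds.n_controls.to_dict(),
                "q": self.thresholds.q,
                "method": self.thresholds.method,
            },
            "venn": self.venn.to_dict(),
            "independence_expectation": deficits.independence_expectation(
                self.thresholds.q, k=3
            ),
            "clinical_correlates": {
                "models": self.associations.models.to_dict(orient="records"),
                "contrasts": self.associations.contrasts.to_dict(orient="records"),
                "skipped": list(self.associations.skipped),
            },
            "risk_factors": {
                "models": self.risk_models.models.to_dict(orient="records"),
                "skipped": list(self.risk_models.skipped),
            },
            **opts,
        }


def run_analysis(
    cohort: Cohort,
    scores: pd.DataFrame,
    config: PipelineConfig,
    boot_rng: np.random.Generator | None = None,
) -> PipelineResult:
    """The deterministic analysis stages, given a cohort and score table."""
    opts = config.analysis
    participants = cohort.participants

    ztable = adjust.residualize(
        scores[list(tasks.SCORE_COLUMNS)],
        participants[["age", "iq", "sex"]],
        fit_sample=opts.fit_sample,
        groups=participants["group"],
    )
    diagnostics = factors.corr_diagnostics(
        ztable.z, DOMAIN_PARTITION, n_boot=opts.n_boot, rng=boot_rng
    )
    solution = factors.fit_pca_varimax(
        ztable.z, k=opts.k_components, domain_partition=DOMAIN_PARTITION
    )
    ar = factors.anderson_rubin_scores(ztable.z, solution)
    perf = factors.orient_for_performance(ar, solution)
    perf = perf[[d for d in DOMAINS if d in perf.columns]]

    thresholds = deficits.estimate_thresholds(
        perf,
        participants,
        q=opts.q,
        method=opts.quantile_method,
        min_controls=opts.min_controls_per_bracket,
    )
    flags = deficits.classify(
        perf, thresholds, participants, boundary_inclusive=opts.boundary_inclusive
    )
    venn = deficits.venn_summary(flags)

    anova = stats.rm_anova(perf, participants["group"])
    logistic = stats.logistic_discrimination(
        perf, participants["group"], cutoff=opts.logistic_cutoff
    )

    clinical_scores = correlates.score_clinical_table(cohort.clinical)
    clin = cohort.clinical.merge(clinical_scores, on="id")
    associations = correlates.deficit_associations(flags, clin)
    risk_models = correlates.risk_factor_models(flags, participants, cohort.clinical)
    return PipelineResult(
        cohort=cohort,
        scores=scores,
        ztable=ztable,
        diagnostics=diagnostics,
        solution=solution,
        factor_scores=perf,
        thresholds=thresholds,
        flags=flags,
        venn=venn,
        anova=anova,
        logistic=logistic,
        clinical_scores=clinical_scores,
        associations=associations,
        risk_models=risk_models,
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full pipeline; optionally write all stage outputs.

    ``seed`` overrides ``config.cohort.seed``.  When ``outdir`` is given,
    per-stage CSVs, the JSON/text report and the run manifest are written
    there.
    """
    if seed is None:
        seed = config.cohort.seed
    root = np.random.SeedSequence(seed)
    cohort_ss, task_ss, boot_ss = root.spawn(3)

    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=seed,
        version=__version__,
        started=time.time(),
    )

    try:
        cohort = generate_cohort(
            config.cohort, config.clinical, seed=cohort_ss
        )
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    try:
        scores = tasks.batch_score_table(
            cohort.abilities(),
            np.random.default_rng(task_ss),
            config.tasks,
            ids=cohort.participants["id"],
        )
    except Exception as exc:
        raise PipelineError("tasks", str(exc)) from exc
    try:
        result = run_analysis(
            cohort,
            scores,
            config,
            boot_rng=np.random.default_rng(boot_ss),
        )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("analysis", str(exc)) from exc
    result.manifest = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.add_stage(
            "cohort",
            [
                _write_csv(cohort.participants, outdir / "participants.csv"),
                _write_csv(cohort.clinical, outdir / "clinical_items.csv"),
            ],
        )
        manifest.add_stage("tasks", [_write_csv(scores, outdir / "scores.csv")])
        zframe = result.ztable.to_csv_frame()
        zframe.insert(0, "id", cohort.participants["id"].to_numpy())
        manifest.add_stage(
            "adjust",
            [
                _write_csv(zframe, outdir / "zscores.csv"),
                _write_csv(result.ztable.coefficients, outdir / "adjustment_coefficients.csv"),
            ],
        )
        loadings = result.solution.loadings.copy()
        loadings.loc["Eigenvalues"] = result.solution.eigenvalues
        loadings.loc["Proportion of variance"] = result.solution.variance_explained
        loadings_out = loadings.reset_index(names="variable")
        fs = result.factor_scores.copy()
        fs.insert(0, "id", cohort.participants["id"].to_numpy())
        manifest.add_stage(
            "factors",
            [
                _write_csv(loadings_out, outdir / "loadings.csv"),
                _write_csv(fs, outdir / "factor_scores.csv"),
            ],
        )
        thresholds_out = result.thresholds.cutoffs.reset_index(names="bracket")
        manifest.add_stage(
            "deficits",
            [
                _write_csv(thresholds_out, outdir / "thresholds.csv"),
                _write_csv(result.flags, outdir / "deficit_flags.csv"),
            ],
        )
        manifest.add_stage(
            "correlates",
            [
                _write_csv(result.clinical_scores, outdir / "clinical_scores.csv"),
                _write_csv(result.associations.models, outdir / "associations.csv"),
                _write_csv(result.risk_models.models, outdir / "risk_models.csv"),
            ],
        )
        report = result.report_dict()
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default, sort_keys=True)
        )
        (outdir / "report.txt").write_text(format_report(result))
        manifest.finished = time.time()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2, default=_json_default)
        )
    return result


def format_report(result: PipelineResult) -> str:
    """Human-readable summary of every analysis section."""
    lines = []
    d = result.diagnostics
    lines.append("=== Correlational and component diagnostics ===")
    lines.append(
        f"mean r (Olkin-Pratt) within domains  = {d.mean_r_within:.3f} "
        f"(95% CI {d.mean_r_within_ci[0]:.3f}, {d.mean_r_within_ci[1]:.3f})"
    )
    lines.append(
        f"mean r (Olkin-Pratt) between domains = {d.mean_r_between:.3f} "
        f"(95% CI {d.mean_r_between_ci[0]:.3f}, {d.mean_r_between_ci[1]:.3f})"
    )
    lines.append(f"Fisher z contrast = {d.fisher_z:.2f}, p = {d.fisher_p:.3g}")
    lines.append(
        f"KMO = {d.kmo_overall:.2f} (per-variable min "
        f"{d.kmo_per_variable.min():.2f}); Bartlett chi2({d.bartlett_df}) = "
        f"{d.bartlett_chi2:.2f}, p = {d.bartlett_p:.3g}"
    )
    s = result.solution
    lines.append("")
    lines.append("=== Rotated component solution (varimax, Kaiser) ===")
    lines.append(
        "eigenvalues (post-rotation): "
        + ", ".join(f"{v:.2f}" for v in s.eigenvalues)
        + f"; total variance explained = {100 * s.total_variance_explained:.1f}%"
    )
    lines.append(f"component -> domain: {s.domain_assignment}")
    lines.append("")
    lines.append("=== Dimensional comparison (mixed ANOVA on factor scores) ===")
    for name, row in result.anova.effects.iterrows():
        lines.append(
            f"{name}: F({row['df1']:.0f},{row['df2']:.0f}) = {row['F']:.2f}, "
            f"p = {row['p']:.3g}, partial eta2 = {row['partial_eta_sq']:.3f} "
            f"(95% CI {row['eta_ci_lo']:.4f}, {row['eta_ci_hi']:.4f}) "
            f"[{row['magnitude']}]"
        )
    lines.append(f"Greenhouse-Geisser epsilon = {result.anova.gg_epsilon:.3f}")
    lo = result.logistic
    lines.append("")
    lines.append("=== Logistic discrimination (group ~ domain scores) ===")
    lines.append(
        f"model chi2({lo.model_df}) = {lo.model_chi2:.2f}, p = {lo.model_p:.3g}; "
        f"Hosmer-Lemeshow chi2({lo.hl_df}) = {lo.hl_chi2:.2f}, p = {lo.hl_p:.3g}"
    )
    lines.append(
        f"sensitivity (CD) = {100 * lo.sensitivity:.1f}% "
        f"(95% CI {100 * lo.sensitivity_ci[0]:.1f}, {100 * lo.sensitivity_ci[1]:.1f}); "
        f"specificity (TDC) = {100 * lo.specificity:.1f}% "
        f"(95% CI {100 * lo.specificity_ci[0]:.1f}, {100 * lo.specificity_ci[1]:.1f})"
    )
    v = result.venn
    lines.append("")
    lines.append("=== Deficit subgroups (bottom {:.0f}% normative cutoff) ===".format(
        100 * result.thresholds.q))
    for g in v.proportions.index:
        agg = v.aggregates.loc[g]
        lines.append(
            f"{g}: >=1 deficit {100 * agg['>=1']:.1f}% | exactly 1 "
            f"{100 * agg['exactly_1']:.1f}% | exactly 2 {100 * agg['exactly_2']:.1f}% "
            f"| all 3 {100 * agg['all_3']:.1f}% | none {100 * agg['none']:.1f}%"
        )
        margins = v.margins.loc[g]
        lines.append(
            "    per-domain: "
            + ", ".join(f"{d} {100 * margins[d]:.1f}%" for d in margins.index)
        )
    exp = deficits.independence_expectation(result.thresholds.q)
    lines.append(
        f"independence expectation: >=1 {100 * exp['ge_1']:.1f}%, "
        f"all 3 {100 * exp['all_k']:.1f}%"
    )
    lines.append("")
    lines.append("=== Clinical correlates and risk factors (CD subset) ===")
    sig = result.associations.models
    if len(sig):
        n_sig = int((sig.loc[sig["predictor"] != "intercept", "p"] < 0.05).sum())
        lines.append(
            f"deficit-flag association models: {len(sig)} coefficients, "
            f"{n_sig} flag coefficients with p < 0.05 (uncorrected)"
        )
    rm = result.risk_models.models
    if len(rm):
        hits = rm[(rm["predictor"] != "intercept") & (rm["p"] < 0.05)]
        for _, row in hits.iterrows():
            lines.append(
                f"risk model {row['outcome']}: {row['predictor']} OR = "
                f"{row['estimate']:.2f}, Wald chi2 = {row['statistic']:.2f}, "
                f"p = {row['p']:.3g}"
            )
    return "\n".join(lines) + "\n"
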
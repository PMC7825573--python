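"""End-to-end analysis pipeline: cohort -> scan -> fit -> validation -> risk table -> NTCP.

The pipeline reproduces the full modelling chain on either a real cohort
(CSV inputs) or a synthetic one: Mann-Whitney group comparison of mean
bladder dose, the AIC V_dose scan, the final univariate logistic fit at the
selected dose, bootstrap + Hosmer-Lemeshow internal validation, inversion
into a clinical risk table, and an EUD-based NTCP fit on the same outcomes.
All stage outputs land in an output directory together with a manifest that
makes the run reproducible from config + seed alone.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dvh import cumulative_to_differential, read_cohort
from .errors import CohortValidationError, PipelineStageError
from .models import (
    EUDParams,
    LogisticRiskModel,
    compute_eud,
    fit_logistic_univariate,
    fit_ntcp,
    invert_ntcp,
)
from .dvh import volume_at_dose
from .risk_table import build_risk_table
from .scan import compare_groups, grade_at_least, scan_vdose
from .synthetic import CohortSpec, generate_cohort
from .validation import bootstrap_validate

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    dvh_file: str | None = None
    outcome_file: str | None = None
    cohort_spec: CohortSpec | None = None
    outcome_threshold: int = 2
    subset_min_grade: int | None = None
    grid_lo_gy: float | None = None
    grid_hi_gy: float | None = None
    grid_step_gy: float = 1.0
    refine_step_gy: float | None = 0.1
    a_volume: float = 1.4
    bootstrap_B: int = 1000
    seed: int = 0
    hl_bins: int = 10
    risk_levels: tuple[float, ...] = (0.10, 0.20, 0.50)
    outdir: str = "bladtox_run"

    def validate(self) -> None:
        have_files = self.dvh_file is not None or self.outcome_file is not None
        if have_files and self.cohort_spec is not None:
            raise CohortValidationError("give either input files or a cohort spec, not both")
        if not have_files and self.cohort_spec is None:
            raise CohortValidationError("one of input files or a cohort spec is required")
        if have_files and (self.dvh_file is None or self.outcome_file is None):
            raise CohortValidationError("both dvh_file and outcome_file are required")
        if self.bootstrap_B < 1:
            raise CohortValidationError("bootstrap_B must be at least 1")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineStageError(name, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write reports under ``config.outdir``.

    Returns the manifest dictionary.  Any stage failure raises
    :class:`~bladtox.errors.PipelineStageError` carrying the stage name;
    outputs written before the failure are retained next to a FAILED marker.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "bladtox",
        "version": __version__,
        "config": config.to_jsonable(),
        "seed": config.seed,
    }
    try:
        return _run(config, outdir, manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(str(exc) + "\n")
        raise


def _run(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    # --- load or generate -------------------------------------------------
    @_stage("cohort")
    def load():
        if config.cohort_spec is not None:
            gen = generate_cohort(config.cohort_spec)
            gen.write(outdir / "cohort")
            return gen.records
        return read_cohort(config.dvh_file, config.outcome_file)

    cohort = load()
    manifest["n_patients"] = len(cohort)
    subset = grade_at_least(config.subset_min_grade) if config.subset_min_grade is not None else None
    analysed = [r for r in cohort if subset(r)] if subset else cohort
    manifest["n_analysed"] = len(analysed)

    # --- group comparison --------------------------------------------------
    @_stage("group_comparison")
    def mw():
        u, p = compare_groups(
            analysed, lambda r: r.dvh.mean_dose_gy(), split=config.outcome_threshold
        )
        return {"statistic_u": u, "p_value": p, "summary": "mean_bladder_dose_gy"}

    manifest["mann_whitney"] = mw()

    # --- V_dose scan ---------------------------------------------------------
    @_stage("vdose_scan")
    def scan():
        grid = None
        if config.grid_lo_gy is not None and config.grid_hi_gy is not None:
            grid = np.arange(config.grid_lo_gy, config.grid_hi_gy + 1e-9, config.grid_step_gy)
        return scan_vdose(
            analysed,
            outcome_rule=config.outcome_threshold,
            grid=grid,
            refine_step_gy=config.refine_step_gy,
        )

    result = scan()
    result.to_frame().to_csv(outdir / "scan.csv", index=False)
    (outdir / "scan_selection.json").write_text(
        json.dumps(
            {"selected_dose_gy": result.selected_dose_gy, "rule": result.selection_rule},
            indent=2,
        )
        + "\n"
    )
    manifest["selected_dose_gy"] = result.selected_dose_gy
    if result.selected_dose_gy is None:
        logger.warning("no grid dose reached significance; downstream stages use the default predictor")
    predictor = result.selected_dose_gy if result.selected_dose_gy is not None else LogisticRiskModel().predictor_dose_gy

    # --- final fit --------------------------------------------------------
    @_stage("final_fit")
    def final_fit():
        x = np.array([volume_at_dose(r.dvh, predictor) for r in analysed])
        y = np.array([1.0 if r.grade >= config.outcome_threshold else 0.0 for r in analysed])
        return fit_logistic_univariate(x, y)

    fit = final_fit()
    (outdir / "fit.json").write_text(json.dumps(fit.as_dict(), indent=2) + "\n")
    manifest["final_fit"] = {"intercept": fit.intercept, "slope": fit.slope, "p": fit.wald_p_slope, "aic": fit.aic}

    # --- internal validation ----------------------------------------------
    @_stage("validation")
    def validate():
        return bootstrap_validate(
            analysed,
            predictor,
            outcome_rule=config.outcome_threshold,
            B=config.bootstrap_B,
            seed=config.seed,
            hl_bins=config.hl_bins,
        )

    report = validate()
    report.write(outdir / "validation.json", outdir / "calibration.csv")
    manifest["validation"] = json.loads(report.to_json())

    # --- risk table ---------------------------------------------------------
    @_stage("risk_table")
    def risk():
        model = LogisticRiskModel(
            intercept_a=fit.intercept, slope_b=fit.slope, predictor_dose_gy=predictor
        )
        table = build_risk_table(model, levels=config.risk_levels)
        table.to_csv(outdir / "risk_table.csv")
        (outdir / "risk_table.txt").write_text(table.render() + "\n")
        return table

    table = risk()
    manifest["risk_table"] = table.to_frame().to_dict(orient="records")

    # --- EUD / NTCP ----------------------------------------------------------
    @_stage("ntcp")
    def ntcp_stage():
        params = EUDParams(a_volume=config.a_volume)
        euds = np.array([compute_eud(cumulative_to_differential(r.dvh), params) for r in analysed])
        y = np.array([1.0 if r.grade >= config.outcome_threshold else 0.0 for r in analysed])
        nfit = fit_ntcp(euds, y)
        payload = {
            "td50_gy": nfit.model.td50,
            "gamma50": nfit.model.gamma50,
            "loglik": nfit.loglik,
            "converged": nfit.converged,
            "n": nfit.n,
            "a_volume": config.a_volume,
            "eud_at_ntcp_50": invert_ntcp(0.5, nfit.model),
        }
        (outdir / "ntcp.json").write_text(json.dumps(payload, indent=2) + "\n")
        return payload

    manifest["ntcp"] = ntcp_stage()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
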
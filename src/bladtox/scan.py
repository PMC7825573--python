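"""AIC-driven search for the most predictive dose-volume threshold.

For each candidate dose d on a grid, the scan computes every patient's
V_d (fraction of bladder volume receiving at least d Gy), fits the
univariate logistic model toxicity ~ V_d, and records its AIC and Wald
slope p-value.  The selected threshold is the dose whose model has the
lowest AIC among those with p < 0.05; if no candidate reaches significance
the scan reports no selection rather than failing.  An optional fine pass
(default 0.1 Gy) refines the grid around the coarse optimum.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import PatientRecord, volume_at_dose
from .errors import CohortValidationError, DegenerateOutcomeError, InsufficientDataError
from .models import LogisticFit, fit_logistic_univariate

__all__ = [
    "ScanResult",
    "scan_vdose",
    "compare_groups",
    "univariate_covariate_screen",
    "grade_at_least",
]

logger = logging.getLogger(__name__)


def grade_at_least(threshold: int) -> Callable[[PatientRecord], bool]:
    """Outcome rule: positive when toxicity grade >= threshold."""

    def rule(record: PatientRecord) -> bool:
        return record.grade >= threshold

    rule.threshold = threshold  # type: ignore[attr-defined]
    return rule


@dataclass
class ScanResult:
    """Per-dose logistic fits over the scanned grid plus the selected dose."""

    grid_gy: np.ndarray
    fits: list[LogisticFit | None]
    selected_dose_gy: float | None
    selection_rule: dict
    skipped_gy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, f in zip(self.grid_gy, self.fits):
            if f is None:
                continue
            rows.append(
                {
                    "dose_gy": d,
                    "intercept": f.intercept,
                    "slope": f.slope,
                    "se_slope": f.se_slope,
                    "p_slope": f.wald_p_slope,
                    "aic": f.aic,
                    "n_used": f.n,
                }
            )
        return pd.DataFrame(rows)

    @property
    def selected_fit(self) -> LogisticFit | None:
        if self.selected_dose_gy is None:
            return None
        idx = int(np.argmin(np.abs(self.grid_gy - self.selected_dose_gy)))
        return self.fits[idx]


def _fit_grid(cohort, y, grid):
    """Fit the univariate logistic at each grid dose; None where degenerate."""
    fits: list[LogisticFit | None] = []
    skipped: list[float] = []
    for d in grid:
        x = np.array([volume_at_dose(rec.dvh, d) for rec in cohort])
        if np.ptp(x) < 1e-12:
            logger.info("dose %.2f Gy skipped: V_dose constant across patients", d)
            fits.append(None)
            skipped.append(float(d))
            continue
        fits.append(fit_logistic_univariate(x, y))
    return fits, skipped


def _select(grid, fits, p_cutoff):
    """Lowest AIC among significant converged fits; AIC ties -> lowest dose."""
    best_idx = None
    for i, f in enumerate(fits):
        if f is None or not f.converged:
            continue
        if not (f.wald_p_slope < p_cutoff):
            continue
        if best_idx is None or f.aic < fits[best_idx].aic - 1e-12:
            best_idx = i
    return best_idx


def scan_vdose(
    cohort: Sequence[PatientRecord],
    outcome_rule: Callable[[PatientRecord], bool] | int = 2,
    grid: np.ndarray | None = None,
    *,
    subset: Callable[[PatientRecord], bool] | None = None,
    p_cutoff: float = 0.05,
    refine_step_gy: float | None = 0.1,
) -> ScanResult:
    """Run the AIC scan and select the most predictive V_dose threshold.

    Parameters
    ----------
    cohort : sequence of PatientRecord
    outcome_rule : callable or int
        Positivity rule; an integer ``k`` is shorthand for grade >= k.
    grid : ndarray, optional
        Candidate doses in Gy.  Default: 1 Gy steps from 5 Gy to the 99th
        percentile of per-patient maximum doses.
    subset : callable, optional
        Pre-filter on records (e.g. restrict to patients with any toxicity
        before discriminating grade >= 2 from grade 1).
    p_cutoff : float
        Wald significance bound the selected model must satisfy.
    refine_step_gy : float or None
        When set, a fine pass at this step is run over +-1 coarse step
        around the provisional optimum and merged into the result.
    """
    if isinstance(outcome_rule, int):
        outcome_rule = grade_at_least(outcome_rule)
    records = [r for r in cohort if subset(r)] if subset is not None else list(cohort)
    if len(records) < 20:
        raise InsufficientDataError("need at least 20 patients for the scan")
    y = np.array([1.0 if outcome_rule(r) else 0.0 for r in records])
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome rule yields a single class")

    if grid is None:
        max_doses = np.array([r.dvh.max_dose_gy for r in records])
        hi = float(np.percentile(max_doses, 99))
        grid = np.arange(5.0, hi + 1e-9, 1.0)
    grid = np.sort(np.asarray(grid, dtype=float))

    fits, skipped = _fit_grid(records, y, grid)
    best = _select(grid, fits, p_cutoff)

    if best is not None and refine_step_gy is not None and grid.size > 1:
        step = float(np.min(np.diff(np.sort(grid)))) if grid.size > 1 else 0.0
        lo = max(grid[best] - step, 0.0)
        hi = grid[best] + step
        fine = np.arange(lo, hi + 1e-9, refine_step_gy)
        fine = np.setdiff1d(np.round(fine, 6), np.round(grid, 6))
        if fine.size:
            fine_fits, fine_skipped = _fit_grid(records, y, fine)
            order = np.argsort(np.concatenate([grid, fine]))
            all_grid = np.concatenate([grid, fine])[order]
            all_fits = [(fits + fine_fits)[i] for i in order]
            grid, fits = all_grid, all_fits
            skipped += fine_skipped
            best = _select(grid, fits, p_cutoff)

    selected = float(grid[best]) if best is not None else None
    return ScanResult(
        grid_gy=grid,
        fits=fits,
        selected_dose_gy=selected,
        selection_rule={"criterion": "min AIC", "p_cutoff": p_cutoff, "tie_break": "lowest dose"},
        skipped_gy=skipped,
    )


def compare_groups(
    cohort: Sequence[PatientRecord],
    summary: Callable[[PatientRecord], float],
    split: Callable[[PatientRecord], bool] | int = 2,
):
    """Two-sided Mann-Whitney rank-sum test on a per-patient dosimetric scalar.

    ``split`` partitions the cohort (an integer ``k`` means grade >= k vs
    the rest); ``summary`` extracts the scalar compared between groups
    (e.g. mean bladder dose or V51).  Uses the normal approximation with
    tie and continuity corrections.  Returns (U statistic of the positive
    group, two-sided p).
    """
    if isinstance(split, int):
        split = grade_at_least(split)
    pos = [summary(r) for r in cohort if split(r)]
    neg = [summary(r) for r in cohort if not split(r)]
    if not pos or not neg:
        raise CohortValidationError("both comparison groups must be non-empty")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", use_continuity=True, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def univariate_covariate_screen(
    cohort: Sequence[PatientRecord],
    covariate_names: Sequence[str],
    outcome_rule: Callable[[PatientRecord], bool] | int = 2,
) -> pd.DataFrame:
    """Univariate logistic screen of clinical covariates against toxicity.

    Complete-case per covariate; no multiplicity correction is applied, so
    each row carries its own unadjusted Wald p-value.
    """
    if isinstance(outcome_rule, int):
        outcome_rule = grade_at_least(outcome_rule)
    rows = []
    for name in covariate_names:
        pairs = [
            (float(r.covariates[name]), 1.0 if outcome_rule(r) else 0.0)
            for r in cohort
            if r.covariates and name in r.covariates
        ]
        if not pairs:
            raise CohortValidationError(f"covariate {name!r} missing for every patient")
        x, y = map(np.array, zip(*pairs))
        fit = fit_logistic_univariate(x, y)
        rows.append(
            {
                "covariate": name,
                "n_used": fit.n,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "se_slope": fit.se_slope,
                "p_slope": fit.wald_p_slope,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
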
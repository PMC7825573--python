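"""Internal validation: bootstrap AUC, Hosmer-Lemeshow calibration, ROC data.

Internal validation follows the resampling scheme in which B datasets of the
original size are drawn with replacement from the development cohort, the
univariate logistic model is refit on each, and its AUC computed on the same
resample; the headline statistic is the median of the B AUC values (the mean
is reported alongside).  Calibration is assessed with the Hosmer-Lemeshow
chi-square over deciles of predicted risk and with per-decile
(predicted, observed) pairs for a calibration plot.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .dvh import PatientRecord, volume_at_dose
from .errors import BootstrapInstabilityError, DegenerateOutcomeError, InsufficientDataError
from .models import fit_logistic_univariate
from .scan import grade_at_least

__all__ = [
    "ValidationReport",
    "auc",
    "bootstrap_validate",
    "hosmer_lemeshow",
    "calibration_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Bootstrap and calibration summary for a fitted univariate risk model."""

    auc_apparent: float
    auc_bootstrap_median: float
    auc_bootstrap_mean: float
    auc_bootstrap_distribution: np.ndarray
    B: int
    seed: int
    n_redrawn: int
    hl_chi2: float
    hl_df: int
    hl_p: float
    calibration_bins: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "auc_apparent": self.auc_apparent,
                "auc_median": self.auc_bootstrap_median,
                "auc_mean": self.auc_bootstrap_mean,
                "B": self.B,
                "seed": self.seed,
                "n_redrawn": self.n_redrawn,
                "hl_chi2": self.hl_chi2,
                "hl_df": self.hl_df,
                "hl_p": self.hl_p,
            }
        )

    def write(self, json_path: str | Path, calibration_csv: str | Path) -> None:
        Path(json_path).write_text(self.to_json() + "\n")
        self.calibration_bins.to_csv(calibration_csv, index=False)


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) with ties at 1/2."""
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("AUC needs both outcome classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _quantile_groups(probs: np.ndarray, bins: int) -> np.ndarray:
    """Decile-style group labels via quantile cut, ties grouped together."""
    cats = pd.qcut(probs, q=bins, labels=False, duplicates="drop")
    return np.asarray(cats)


def _hl_terms(probs, labels, bins):
    groups = _quantile_groups(probs, bins)
    n_groups = int(groups.max()) + 1
    chi2 = 0.0
    ok = True
    table = []
    for g in range(n_groups):
        m = groups == g
        n_g = int(m.sum())
        o = float(labels[m].sum())
        e = float(probs[m].sum())
        table.append((float(probs[m].mean()), o / n_g, n_g))
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            ok = False
            break
        chi2 += (o - e) ** 2 / denom
    return chi2, n_groups, ok, table


def hosmer_lemeshow(probs, labels, bins: int = 10):
    """Hosmer-Lemeshow goodness-of-fit test on predicted probabilities.

    Observations are grouped into ``bins`` quantile groups of predicted risk
    (ties grouped); the statistic is sum_g (O_g - E_g)^2 / (E_g (1 - E_g/n_g))
    with df = groups - 2 and an upper-tail chi-square p-value.  Groups whose
    expected counts degenerate trigger an automatic reduction in the number
    of bins (logged), never an error.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size != y.size:
        raise ValueError("probs and labels must have equal length")
    if p.size < 2 * bins:
        raise InsufficientDataError(f"need at least {2 * bins} observations for {bins} bins")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    b = bins
    while b >= 3:
        chi2, n_groups, ok, _ = _hl_terms(p, y, b)
        if ok and n_groups >= 3:
            df = n_groups - 2
            return float(chi2), int(df), float(stats.chi2.sf(chi2, df))
        b -= 1
        logger.info("Hosmer-Lemeshow: reducing to %d bins (degenerate expected counts)", b)
    raise InsufficientDataError("could not form at least 3 usable risk groups")


def calibration_curve(probs, labels, bins: int = 10) -> pd.DataFrame:
    """Per-risk-group (mean predicted, observed rate, count) for calibration plots."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size < 2 * bins:
        raise InsufficientDataError(f"need at least {2 * bins} observations for {bins} bins")
    groups = _quantile_groups(p, bins)
    rows = []
    for g in range(int(groups.max()) + 1):
        m = groups == g
        rows.append(
            {"bin": g, "mean_pred": float(p[m].mean()), "obs_rate": float(y[m].mean()), "n": int(m.sum())}
        )
    return pd.DataFrame(rows)


def bootstrap_validate(
    cohort: Sequence[PatientRecord],
    predictor_dose_gy: float,
    outcome_rule=2,
    *,
    B: int = 1000,
    seed: int = 0,
    subset=None,
    optimism_corrected: bool = False,
    hl_bins: int = 10,
) -> ValidationReport:
    """Bootstrap internal validation of the univariate V_dose risk model.

    Draws ``B`` resamples with replacement at the original size, refits the
    logistic model on each, and scores its AUC on the same resample
    (apparent per-resample performance, the default) or on the original
    cohort when ``optimism_corrected`` is set.  Resamples with a single
    outcome class are redrawn so the distribution always holds B values;
    if more than half of all draws are degenerate the cohort is deemed too
    unstable to validate.
    """
    if isinstance(outcome_rule, int):
        outcome_rule = grade_at_least(outcome_rule)
    records = [r for r in cohort if subset(r)] if subset is not None else list(cohort)
    if B < 1:
        raise ValueError("B must be at least 1")
    x = np.array([volume_at_dose(r.dvh, predictor_dose_gy) for r in records])
    y = np.array([1.0 if outcome_rule(r) else 0.0 for r in records])
    apparent_fit = fit_logistic_univariate(x, y)
    from scipy.special import expit

    probs_apparent = expit(apparent_fit.intercept + apparent_fit.slope * x)
    auc_apparent = auc(probs_apparent, y)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(np.clip(probs_apparent, 1e-12, 1 - 1e-12), y, bins=hl_bins)
    calib = calibration_curve(probs_apparent, y, bins=hl_bins)

    rng = np.random.default_rng(seed)
    n = x.size
    aucs = np.empty(B)
    redraws = 0
    i = 0
    while i < B:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max() or np.ptp(x[idx]) == 0:
            redraws += 1
            if redraws > (B + redraws) / 2:
                raise BootstrapInstabilityError(
                    f"{redraws} degenerate resamples before completing {i} of {B}"
                )
            continue
        fit_b = fit_logistic_univariate(x[idx], yb)
        if optimism_corrected:
            scores = expit(fit_b.intercept + fit_b.slope * x)
            aucs[i] = auc(scores, y)
        else:
            scores = expit(fit_b.intercept + fit_b.slope * x[idx])
            aucs[i] = auc(scores, yb)
        i += 1
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    return ValidationReport(
        auc_apparent=auc_apparent,
        auc_bootstrap_median=float(np.median(aucs)),
        auc_bootstrap_mean=float(np.mean(aucs)),
        auc_bootstrap_distribution=aucs,
        B=B,
        seed=seed,
        n_redrawn=redraws,
        hl_chi2=hl_chi2,
        hl_df=hl_df,
        hl_p=hl_p,
        calibration_bins=calib,
    )
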
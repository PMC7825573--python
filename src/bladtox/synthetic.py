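"""Synthetic bladder-DVH cohorts with a known dose-toxicity ground truth.

Each patient's cumulative DVH is a two-parameter sigmoid in dose,

    cum(d) = s(d) / s(0),   s(d) = 1 / (1 + exp((d - d50) / w)),

which is monotone non-increasing, equals 1 at 0 Gy, and visually matches the
banded DVH families seen for bladders in prostate plans: d50 shifts the curve
(how much of the organ sits in the high-dose region) and w sets its spread.
Toxicity is then drawn from the univariate logistic ground truth
P = sigmoid(a + b * V) on the volume fraction V at the predictor dose, and
positive/negative cases are split into ordinal grades with fixed conditional
mixtures.  Every stage downstream of data collection can therefore be tested
against a known generating model.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dvh import DVHCurve, PatientRecord, cumulative_to_differential, volume_at_dose, write_cohort
from .errors import CohortValidationError
from .models import LogisticRiskModel, logistic_risk

__all__ = [
    "CohortSpec",
    "GeneratedCohort",
    "generate_dvh",
    "generate_cohort",
    "cohort_summary",
    "grade_distribution",
]

#: conditional grade mixtures: negatives split over grades 0/1, positives
#: over grades 2/3/4, in the proportions of the development cohort
DEFAULT_NEGATIVE_MIX = (118 / 161, 43 / 161)
DEFAULT_POSITIVE_MIX = (9 / 14, 4 / 14, 1 / 14)

#: Gleason grade-group shares used for the (outcome-independent) covariates
_GLEASON_P = (0.423, 0.297, 0.126, 0.114, 0.04)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    d50 ~ Normal(mu_d50, sd_d50) Gy and w ~ LogNormal(log_mu_w, sd_log_w)
    parameterize the per-patient DVH sigmoids; ``truth`` is the generating
    logistic risk model on the volume fraction at its predictor dose.
    """

    n: int = 175
    mu_d50: float = 55.0
    sd_d50: float = 8.0
    log_mu_w: float = math.log(6.0)
    sd_log_w: float = 0.3
    truth: LogisticRiskModel = field(default_factory=LogisticRiskModel)
    negative_mix: tuple[float, float] = DEFAULT_NEGATIVE_MIX
    positive_mix: tuple[float, float, float] = DEFAULT_POSITIVE_MIX
    grid_max_gy: float = 85.0
    grid_step_gy: float = 0.5
    with_covariates: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise CohortValidationError("cohort size must be at least 1")
        for mix, k in ((self.negative_mix, 2), (self.positive_mix, 3)):
            if len(mix) != k or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise CohortValidationError("grade mixtures must be non-negative and sum to 1")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GeneratedCohort:
    """A synthetic cohort plus its generating truth, for oracle tests."""

    spec: CohortSpec
    records: list[PatientRecord]
    truth: pd.DataFrame  # patient_id, d50, w, v_predictor, p_true, y

    def write(self, outdir: str | Path) -> None:
        """Emit the standard CSV dialects plus the truth table and spec JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(self.records, outdir / "dvh.csv", outdir / "outcomes.csv")
        self.truth.to_csv(outdir / "truth.csv", index=False)
        (outdir / "cohort_spec.json").write_text(self.spec.to_json() + "\n")


def generate_dvh(d50: float, w: float, grid: np.ndarray, patient_id: str = "") -> DVHCurve:
    """Sigmoid cumulative DVH on the given dose grid, rescaled to 1 at 0 Gy."""
    if w <= 0:
        raise ValueError("DVH steepness w must be positive")
    grid = np.asarray(grid, dtype=float)
    s = 1.0 / (1.0 + np.exp(np.clip((grid - d50) / w, -500, 500)))
    cum = np.clip(s / s[0], 0.0, 1.0)
    return DVHCurve(patient_id=patient_id, dose_gy=grid, cum_volume=cum)


def _covariates(rng: np.random.Generator) -> dict[str, float]:
    age = float(np.clip(np.round(rng.normal(72.0, 6.0)), 53, 86))
    psa = float(np.round(np.exp(rng.normal(np.log(8.0), 0.7)), 1))
    gleason = float(rng.choice(np.arange(1, 6), p=_GLEASON_P))
    dose = float(rng.choice([80.0, 72.0, 67.5], p=[0.8, 0.12, 0.08]))
    return {"age": age, "psa": psa, "gleason_group": gleason, "prescribed_dose_gy": dose}


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw a full synthetic cohort from the spec; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(0.0, spec.grid_max_gy + 1e-9, spec.grid_step_gy)
    d50s = np.clip(rng.normal(spec.mu_d50, spec.sd_d50, size=spec.n), 1.0, None)
    ws = np.exp(rng.normal(spec.log_mu_w, spec.sd_log_w, size=spec.n))
    width = len(str(spec.n))
    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(spec.n):
        pid = f"SYN{i + 1:0{width}d}"
        curve = generate_dvh(d50s[i], ws[i], grid, patient_id=pid)
        v = volume_at_dose(curve, spec.truth.predictor_dose_gy)
        p = logistic_risk(v, spec.truth)
        y = int(rng.random() < p)
        if y:
            grade = int(rng.choice([2, 3, 4], p=spec.positive_mix))
        else:
            grade = int(rng.choice([0, 1], p=spec.negative_mix))
        covs = _covariates(rng) if spec.with_covariates else None
        records.append(PatientRecord(pid, curve, grade, covariates=covs))
        truth_rows.append(
            {"patient_id": pid, "d50": d50s[i], "w": ws[i], "v_predictor": v, "p_true": p, "y": y}
        )
    return GeneratedCohort(spec=spec, records=records, truth=pd.DataFrame(truth_rows))


def grade_distribution(grades: Sequence[int]) -> pd.DataFrame:
    """Counts and percentages per toxicity grade 0-4 (percent to 2 decimals)."""
    grades = list(grades)
    n = len(grades)
    if n == 0:
        raise CohortValidationError("empty grade list")
    rows = []
    for g in range(5):
        c = sum(1 for x in grades if x == g)
        rows.append({"grade": g, "count": c, "percent": round(100.0 * c / n, 2)})
    return pd.DataFrame(rows)


def cohort_summary(cohort: Sequence[PatientRecord], v_dose_gy: float = 51.43) -> dict:
    """Descriptive summary: grade distribution, V_dose quartiles, mean dose by grade."""
    if not cohort:
        raise CohortValidationError("empty cohort")
    grades = [r.grade for r in cohort]
    v = np.array([volume_at_dose(r.dvh, v_dose_gy) for r in cohort])
    mean_doses = np.array([r.dvh.mean_dose_gy() for r in cohort])
    by_grade = {
        g: float(mean_doses[[r.grade == g for r in cohort]].mean())
        for g in sorted(set(grades))
    }
    return {
        "n": len(cohort),
        "grade_distribution": grade_distribution(grades),
        "v_dose_gy": v_dose_gy,
        "v_quartiles": {
            "q1": float(np.percentile(v, 25)),
            "median": float(np.percentile(v, 50)),
            "q3": float(np.percentile(v, 75)),
        },
        "mean_dose_by_grade_gy": by_grade,
    }
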
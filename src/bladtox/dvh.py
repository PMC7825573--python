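"""Cumulative dose-volume histograms: containers, validation, conversion, I/O.

A cumulative DVH gives, for each dose level, the fraction of the organ
volume receiving at least that dose.  All volumes are held internally as
fractions in [0, 1]; the readers convert percent (/100) and absolute cm^3
(/ total organ volume) on the way in.  Dose grids are per-patient and need
not be uniform: every dose query interpolates linearly on the cumulative
curve, the conventional treatment for exported DVH tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, InsufficientDataError, MalformedDVHError

__all__ = [
    "DVHCurve",
    "DifferentialDVH",
    "PatientRecord",
    "volume_at_dose",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "read_cohort",
    "write_cohort",
    "COVARIATE_COLUMNS",
]

#: optional per-patient scalar covariates recognised by the outcome reader
COVARIATE_COLUMNS = ("age", "psa", "gleason_group", "prescribed_dose_gy")

_TOL = 1e-9


@dataclass(frozen=True)
class DVHCurve:
    """One patient's cumulative dose-volume histogram.

    Parameters
    ----------
    patient_id : str
        Identifier carried through all reports.
    dose_gy : ndarray
        Strictly increasing dose grid in Gy, starting at 0 Gy.
    cum_volume : ndarray
        Fraction of organ volume receiving at least each dose; non-increasing,
        within [0, 1], equal to 1 at 0 Gy.
    total_volume_cc : float, optional
        Absolute organ volume in cm^3 when the source table carried one.
    """

    patient_id: str
    dose_gy: np.ndarray
    cum_volume: np.ndarray
    total_volume_cc: float | None = None

    def __post_init__(self):
        dose = np.asarray(self.dose_gy, dtype=float)
        vol = np.asarray(self.cum_volume, dtype=float)
        object.__setattr__(self, "dose_gy", dose)
        object.__setattr__(self, "cum_volume", vol)
        pid = self.patient_id
        if dose.ndim != 1 or vol.ndim != 1 or dose.size != vol.size:
            raise MalformedDVHError(f"{pid}: dose and volume arrays must be 1-D and equal length")
        if dose.size < 1:
            raise MalformedDVHError(f"{pid}: empty DVH")
        if dose[0] < 0 or abs(dose[0]) > _TOL:
            raise MalformedDVHError(f"{pid}: dose grid must start at 0 Gy (got {dose[0]} Gy)")
        if np.any(np.diff(dose) <= 0):
            raise MalformedDVHError(f"{pid}: dose grid is not strictly increasing")
        if abs(vol[0] - 1.0) > _TOL:
            raise MalformedDVHError(f"{pid}: cumulative volume at 0 Gy is {vol[0]!r}, expected 1.0")
        if np.any(np.diff(vol) > _TOL):
            raise MalformedDVHError(f"{pid}: cumulative volume is not non-increasing")
        if np.any(vol < -_TOL) or np.any(vol > 1.0 + _TOL):
            raise MalformedDVHError(f"{pid}: cumulative volume outside [0, 1]")
        if self.total_volume_cc is not None and self.total_volume_cc <= 0:
            raise MalformedDVHError(f"{pid}: total organ volume must be positive")

    @property
    def max_dose_gy(self) -> float:
        return float(self.dose_gy[-1])

    def mean_dose_gy(self) -> float:
        """Volume-weighted mean dose, i.e. the first moment of the differential DVH."""
        ddvh = cumulative_to_differential(self)
        return float(np.dot(ddvh.v, ddvh.bin_center_gy))


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: fraction of volume per dose bin, summing to 1."""

    bin_center_gy: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.bin_center_gy, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "bin_center_gy", d)
        object.__setattr__(self, "v", v)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size == 0:
            raise MalformedDVHError("differential DVH arrays must be 1-D, non-empty, equal length")
        if np.any(np.diff(d) <= 0):
            raise MalformedDVHError("differential DVH bin centers must be strictly increasing")
        if np.any(v < -_TOL):
            raise CohortValidationError("differential DVH has negative bin volumes")
        if abs(v.sum() - 1.0) > 1e-9:
            raise MalformedDVHError(f"differential DVH volumes sum to {v.sum()!r}, expected 1")


@dataclass
class PatientRecord:
    """A patient: DVH plus graded late-toxicity outcome and optional covariates."""

    patient_id: str
    dvh: DVHCurve
    grade: int
    covariates: Mapping[str, float] | None = field(default=None)

    def __post_init__(self):
        if self.grade not in (0, 1, 2, 3, 4):
            raise CohortValidationError(
                f"{self.patient_id}: toxicity grade must be an integer 0-4, got {self.grade!r}"
            )


def volume_at_dose(curve: DVHCurve, dose: float | np.ndarray):
    """Fraction of organ volume receiving at least ``dose`` Gy (the V_dose metric).

    Linear interpolation on the cumulative curve; doses beyond the grid
    maximum return 0 (nothing is recorded above the last grid point).
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative")
    out = np.interp(dose_arr, curve.dose_gy, curve.cum_volume, right=0.0)
    return float(out) if np.isscalar(dose) or dose_arr.ndim == 0 else out


def cumulative_to_differential(curve: DVHCurve) -> DifferentialDVH:
    """Convert a cumulative DVH to differential form.

    Bin i spans grid doses [d_i, d_{i+1}] with volume cum[i] - cum[i+1];
    any residual cumulative volume at the maximum grid dose is absorbed into
    the final bin so the differential volumes always sum to 1.
    """
    if curve.dose_gy.size < 2:
        raise InsufficientDataError(f"{curve.patient_id}: need at least 2 grid points")
    v = -np.diff(curve.cum_volume)
    v = np.clip(v, 0.0, None)
    v[-1] += curve.cum_volume[-1]
    centers = 0.5 * (curve.dose_gy[:-1] + curve.dose_gy[1:])
    v = v / v.sum()
    return DifferentialDVH(bin_center_gy=centers, v=v)


def differential_to_cumulative(ddvh: DifferentialDVH, patient_id: str = "") -> DVHCurve:
    """Invert :func:`cumulative_to_differential`.

    Bin edges are reconstructed from the centers assuming each center is the
    midpoint of its bin and the first edge sits at 0 Gy — the layout produced
    by the forward conversion for any curve gridded from 0 Gy.
    """
    if np.any(ddvh.v < 0):
        raise CohortValidationError("negative differential volumes")
    c = ddvh.bin_center_gy
    edges = np.empty(c.size + 1)
    edges[0] = 0.0
    for i in range(c.size):
        edges[i + 1] = 2.0 * c[i] - edges[i]
    if np.any(np.diff(edges) <= 0):
        raise MalformedDVHError("bin centers are not consistent with a monotone edge grid")
    cum = np.empty(edges.size)
    cum[0] = 1.0
    cum[1:] = 1.0 - np.cumsum(ddvh.v)
    cum = np.clip(cum, 0.0, 1.0)
    return DVHCurve(patient_id=patient_id, dose_gy=edges, cum_volume=cum)


def _normalize_volumes(pid: str, dose: np.ndarray, vol: np.ndarray, unit: str):
    """Return (dose, fraction volumes, total_cc) for one patient's raw rows."""
    total_cc = None
    if unit == "fraction":
        frac = vol
    elif unit == "percent":
        frac = vol / 100.0
    elif unit == "cc":
        total_cc = float(vol.max())
        if total_cc <= 0:
            raise MalformedDVHError(f"{pid}: non-positive total organ volume in cm^3")
        frac = vol / total_cc
    else:
        raise CohortValidationError(f"{pid}: unknown volume_unit {unit!r}")
    # left-extend to 0 Gy: the whole organ receives at least 0 Gy
    if dose.size == 0 or dose[0] > 0:
        dose = np.concatenate([[0.0], dose])
        frac = np.concatenate([[1.0], frac])
    return dose, frac, total_cc


def read_cohort(dvh_file: str | Path, outcome_file: str | Path) -> list[PatientRecord]:
    """Read a cohort from the long-form DVH CSV and the outcome CSV.

    The DVH table has columns ``patient_id, dose_gy, volume, volume_unit``
    (unit one of ``fraction``/``percent``/``cc``); the outcome table maps
    ``patient_id`` to ``grade`` plus optional covariate columns.  Outcome ids
    must cover every DVH id.  Returns one validated record per patient
    present in both files, ordered by patient id.
    """
    dvh_df = pd.read_csv(dvh_file)
    required = {"patient_id", "dose_gy", "volume", "volume_unit"}
    if not required.issubset(dvh_df.columns):
        raise CohortValidationError(f"DVH file missing columns {sorted(required - set(dvh_df.columns))}")
    out_df = pd.read_csv(outcome_file)
    if not {"patient_id", "grade"}.issubset(out_df.columns):
        raise CohortValidationError("outcome file must have columns patient_id, grade")
    out_df = out_df.astype({"patient_id": str}).set_index("patient_id")

    dvh_df = dvh_df.astype({"patient_id": str})
    dvh_ids = list(dict.fromkeys(dvh_df["patient_id"]))
    missing = [pid for pid in dvh_ids if pid not in out_df.index]
    if missing:
        raise CohortValidationError(f"patients with a DVH but no outcome row: {missing}")

    records = []
    for pid in sorted(dvh_ids):
        sub = dvh_df[dvh_df["patient_id"] == pid]
        units = sub["volume_unit"].unique()
        if len(units) != 1:
            raise CohortValidationError(f"{pid}: mixed volume units {list(units)}")
        dose = sub["dose_gy"].to_numpy(dtype=float)
        if np.any(np.diff(dose) <= 0):
            raise MalformedDVHError(f"{pid}: dose column is not strictly increasing")
        vol = sub["volume"].to_numpy(dtype=float)
        dose, frac, total_cc = _normalize_volumes(pid, dose, vol, str(units[0]))
        curve = DVHCurve(patient_id=pid, dose_gy=dose, cum_volume=frac, total_volume_cc=total_cc)
        row = out_df.loc[pid]
        grade_raw = row["grade"]
        grade = int(grade_raw) if float(grade_raw) == int(grade_raw) else grade_raw
        covs = {
            c: float(row[c]) for c in COVARIATE_COLUMNS if c in out_df.columns and pd.notna(row[c])
        }
        records.append(PatientRecord(pid, curve, grade, covariates=covs or None))
    return records


def write_cohort(
    cohort: Sequence[PatientRecord],
    dvh_file: str | Path,
    outcome_file: str | Path,
) -> None:
    """Write the cohort back out in the same CSV dialects, stable ordering."""
    ordered = sorted(cohort, key=lambda r: r.patient_id)
    dvh_rows = []
    for rec in ordered:
        for d, v in zip(rec.dvh.dose_gy, rec.dvh.cum_volume):
            dvh_rows.append((rec.patient_id, d, v, "fraction"))
    pd.DataFrame(dvh_rows, columns=["patient_id", "dose_gy", "volume", "volume_unit"]).to_csv(
        dvh_file, index=False
    )
    out_rows = []
    cov_cols = [c for c in COVARIATE_COLUMNS if any(r.covariates and c in r.covariates for r in ordered)]
    for rec in ordered:
        row = {"patient_id": rec.patient_id, "grade": rec.grade}
        for c in cov_cols:
            row[c] = rec.covariates.get(c) if rec.covariates else None
        out_rows.append(row)
    pd.DataFrame(out_rows).to_csv(outcome_file, index=False)
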
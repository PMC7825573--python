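"""Invert a fitted logistic risk model into dose-volume constraints.

Given P(toxicity) = sigmoid(a + b*X) with X the bladder volume fraction
inside a reference isodose, the volume threshold keeping risk below a level
r is X* = (logit(r) - a) / b.  The table renders the classic clinician-facing
layout: "keep V_dose below X*% to keep risk below r%".
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.special import logit

from .dvh import PatientRecord, volume_at_dose
from .errors import NonInvertibleModelError
from .models import LogisticRiskModel, logistic_risk

__all__ = ["RiskRow", "RiskTable", "volume_for_risk", "build_risk_table", "patient_risk"]


@dataclass(frozen=True)
class RiskRow:
    risk_level: float
    v_threshold: float  # volume fraction; may fall outside [0, 1] (see reachable)
    reachable: bool


@dataclass(frozen=True)
class RiskTable:
    model: LogisticRiskModel
    rows: tuple[RiskRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "risk_percent": [_pct(r.risk_level) for r in self.rows],
                "v_percent": [_pct(r.v_threshold) for r in self.rows],
                "flag": ["" if r.reachable else "unreachable" for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def render(self) -> str:
        """Plain-text rendering: one constraint line per risk level."""
        dose = self.model.predictor_dose_gy
        lines = [f"V{dose:g} volume (%)\tRisk of toxicity"]
        for r in self.rows:
            mark = "" if r.reachable else " [unreachable]"
            lines.append(f"<{_pct(r.v_threshold)}%\t<{_pct(r.risk_level)}%{mark}")
        return "\n".join(lines)


def _pct(fraction: float) -> float:
    """Percentage rounded half-up to one decimal, locale-independent."""
    import decimal

    q = decimal.Decimal(repr(float(fraction) * 100.0)).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return float(q)


def volume_for_risk(risk: float, model: LogisticRiskModel) -> float:
    """Volume fraction X* at which the model's risk equals ``risk``.

    The algebraic inverse (logit(risk) - a) / b; the value is returned
    unclamped, so callers can flag thresholds outside the physical [0, 1]
    range (see :func:`build_risk_table`).
    """
    if not 0.0 < risk < 1.0:
        raise ValueError("risk must lie strictly in (0, 1)")
    if model.slope_b == 0:
        raise NonInvertibleModelError("zero slope: risk does not depend on volume")
    return float((logit(risk) - model.intercept_a) / model.slope_b)


def build_risk_table(
    model: LogisticRiskModel, levels: Sequence[float] = (0.10, 0.20, 0.50)
) -> RiskTable:
    """Tabulate volume thresholds for each risk level (default 10/20/50%)."""
    levels = list(levels)
    if any(not 0 < lv < 1 for lv in levels):
        raise ValueError("risk levels must lie strictly in (0, 1)")
    if sorted(levels) != levels or len(set(levels)) != len(levels):
        raise ValueError("risk levels must be strictly increasing")
    rows = []
    for lv in levels:
        v = volume_for_risk(lv, model)
        rows.append(RiskRow(risk_level=lv, v_threshold=v, reachable=0.0 <= v <= 1.0))
    return RiskTable(model=model, rows=tuple(rows))


def patient_risk(record: PatientRecord, model: LogisticRiskModel) -> float:
    """Predicted toxicity probability for one patient's DVH."""
    v = volume_at_dose(record.dvh, model.predictor_dose_gy)
    return float(logistic_risk(v, model))
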
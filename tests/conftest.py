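from pathlib import Path

import numpy as np
import pytest
from hypothesis import strategies as st

from bladtox.dvh import DVHCurve, PatientRecord

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def step_curve() -> DVHCurve:
    """Three-point curve used in the worked interpolation examples."""
    return DVHCurve("step", [0.0, 40.0, 80.0], [1.0, 0.4, 0.0])


def make_record(patient_id: str, grade: int, value: float | None = None) -> PatientRecord:
    """Minimal patient; `value` lands in covariates['val'] and (clipped to
    [0, 1]) shapes the DVH tail so V_dose varies across records."""
    tail = min(max(value, 0.0), 1.0) if value is not None else 0.0
    dvh = DVHCurve(patient_id, [0.0, 1.0], [1.0, tail])
    covs = {"val": value} if value is not None else None
    return PatientRecord(patient_id, dvh, grade, covariates=covs)


@st.composite
def cumulative_curves(draw, max_points: int = 12):
    """Random valid cumulative DVHs, gridded from 0 Gy and ending at 0 volume."""
    n = draw(st.integers(min_value=2, max_value=max_points))
    steps = draw(
        st.lists(st.floats(0.5, 10.0, allow_nan=False), min_size=n - 1, max_size=n - 1)
    )
    doses = np.concatenate([[0.0], np.cumsum(steps)])
    drops = np.array(
        draw(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=n - 1, max_size=n - 1))
    )
    total = drops.sum()
    if total == 0:
        drops = np.ones(n - 1)
        total = float(n - 1)
    cum = np.concatenate([[1.0], 1.0 - np.cumsum(drops / total)])
    cum = np.clip(cum, 0.0, 1.0)
    cum[-1] = 0.0
    return DVHCurve("hyp", doses, cum)
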
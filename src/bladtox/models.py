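"""Dose-response models: generalized EUD, logistic NTCP, and ML fitting.

The generalized equivalent uniform dose (gEUD) reduces an inhomogeneous dose
distribution to the uniform dose with the same biological effect,

    EUD = (sum_i v_i * D_i^a)^(1/a),

a power mean over differential-DVH bins with a structure-specific volume
exponent ``a`` (1.4 for bladder).  Complication probability is modelled with
the logistic NTCP form

    NTCP(EUD) = 1 / (1 + (TD50 / EUD)^(4*gamma50)),

where TD50 is the uniform dose giving a 50% complication rate and gamma50 is
the normalized slope of the dose-response curve at TD50
(gamma50 = TD50 * |dNTCP/dD| at D = TD50).

The module also carries the published per-patient risk model — a univariate
logistic on the bladder volume fraction X inside a reference isodose,
P = sigmoid(a + b*X) — together with maximum-likelihood fitting for both
model families.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit

from .dvh import DifferentialDVH
from .errors import (
    CollinearPredictorError,
    DegenerateOutcomeError,
    InsufficientDataError,
)

__all__ = [
    "EUDParams",
    "NTCPModel",
    "NTCPFit",
    "LogisticRiskModel",
    "LogisticFit",
    "compute_eud",
    "ntcp",
    "invert_ntcp",
    "gamma50_check",
    "fit_ntcp",
    "logistic_risk",
    "fit_logistic_univariate",
]

#: bladder volume-effect exponent from the radiobiology literature
BLADDER_A_VOLUME = 1.4


@dataclass(frozen=True)
class EUDParams:
    """Volume-effect exponent for the generalized EUD power mean."""

    a_volume: float = BLADDER_A_VOLUME

    def __post_init__(self):
        if self.a_volume == 0:
            raise ValueError("the EUD volume exponent must be non-zero")


@dataclass(frozen=True)
class NTCPModel:
    """Logistic NTCP dose-response parameterized by TD50 (Gy) and gamma50."""

    td50: float
    gamma50: float

    def __post_init__(self):
        if self.td50 <= 0:
            raise ValueError("TD50 must be positive")
        if self.gamma50 <= 0:
            raise ValueError("gamma50 must be positive")

    def to_json(self) -> str:
        return json.dumps({"td50_gy": self.td50, "gamma50": self.gamma50})


@dataclass(frozen=True)
class NTCPFit:
    """Result of maximum-likelihood NTCP fitting."""

    model: NTCPModel
    loglik: float
    converged: bool
    n: int


@dataclass(frozen=True)
class LogisticRiskModel:
    """Published clinical risk model: P(toxicity) = sigmoid(a + b*X).

    X is the *fraction* (not percent) of bladder volume inside the
    ``predictor_dose_gy`` isodose; with the published coefficients the
    tabulated dose-volume risk thresholds are only reproducible on the
    fraction scale.
    """

    intercept_a: float = -2.5
    slope_b: float = 4.3
    predictor_dose_gy: float = 51.43

    def __post_init__(self):
        if not np.isfinite(self.slope_b):
            raise ValueError("slope must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept_a": self.intercept_a,
                "slope_b": self.slope_b,
                "predictor_dose_gy": self.predictor_dose_gy,
            }
        )


@dataclass(frozen=True)
class LogisticFit:
    """Univariate logistic regression fit with Wald inference and AIC."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    wald_p_slope: float
    loglik: float
    aic: float
    n: int
    converged: bool

    def as_dict(self) -> dict:
        return asdict(self)


def compute_eud(ddvh: DifferentialDVH, params: EUDParams = EUDParams()) -> float:
    """Generalized EUD: the power mean (sum v_i D_i^a)^(1/a) over DVH bins.

    Lies between the minimum and maximum bin dose for every exponent; tends
    to the maximum dose as a -> +inf (serial organ) and to the minimum as
    a -> -inf (parallel organ).
    """
    d = ddvh.bin_center_gy
    v = ddvh.v
    if d.size == 0:
        raise InsufficientDataError("empty differential DVH")
    if np.any(d < 0):
        raise ValueError("bin doses must be non-negative")
    a = params.a_volume
    # work in log space to dodge overflow for large |a|
    with np.errstate(divide="ignore"):
        logd = np.log(d)
    if np.any(np.isneginf(logd) & (v > 0)) and a < 0:
        return 0.0  # a zero-dose bin dominates the negative-exponent mean
    keep = v > 0
    terms = np.log(v[keep]) + a * logd[keep]
    m = terms.max()
    log_sum = m + np.log(np.exp(terms - m).sum())
    return float(np.exp(log_sum / a))


def ntcp(eud, model: NTCPModel):
    """Complication probability at a given EUD (Gy); strictly increasing."""
    eud_arr = np.asarray(eud, dtype=float)
    if np.any(eud_arr <= 0):
        raise ValueError("EUD must be positive")
    out = 1.0 / (1.0 + (model.td50 / eud_arr) ** (4.0 * model.gamma50))
    return float(out) if eud_arr.ndim == 0 else out


def invert_ntcp(p: float, model: NTCPModel) -> float:
    """EUD (Gy) at which the model reaches complication probability ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie strictly in (0, 1)")
    return float(model.td50 / ((1.0 - p) / p) ** (1.0 / (4.0 * model.gamma50)))


def gamma50_check(model: NTCPModel) -> float:
    """Normalized slope TD50*|dNTCP/dD| at D=TD50 by central difference.

    For the logistic NTCP form the analytic value is exactly gamma50, so
    this serves as a self-consistency check of the parameterization.
    """
    h = 1e-4 * model.td50
    slope = (ntcp(model.td50 + h, model) - ntcp(model.td50 - h, model)) / (2.0 * h)
    return float(model.td50 * abs(slope))


def fit_ntcp(euds, outcomes, *, td50_init: float | None = None, gamma50_init: float = 1.0) -> NTCPFit:
    """Maximum-likelihood NTCP fit on per-patient (EUD, binary outcome) pairs.

    Bernoulli likelihood with p_i = ntcp(EUD_i); optimized over
    (log TD50, log gamma50) so the positivity constraints are built in.
    Non-convergence is flagged, not raised.
    """
    e = np.asarray(euds, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if e.size != y.size or e.size < 10:
        raise InsufficientDataError("need at least 10 (EUD, outcome) pairs")
    if np.any(e <= 0):
        raise ValueError("EUD values must be positive")
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes must be present")
    if td50_init is None:
        td50_init = float(np.median(e))
    log_e = np.log(e)

    def nll(theta):
        log_td50, log_g = theta
        g4 = 4.0 * np.exp(log_g)
        z = g4 * (log_e - log_td50)  # logit of NTCP
        # log-likelihood of a Bernoulli with logit z
        return float(np.sum(np.logaddexp(0.0, z)) - np.dot(y, z))

    res = optimize.minimize(
        nll,
        x0=np.array([np.log(td50_init), np.log(gamma50_init)]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 2000},
    )
    model = NTCPModel(td50=float(np.exp(res.x[0])), gamma50=float(np.exp(res.x[1])))
    return NTCPFit(model=model, loglik=-float(res.fun), converged=bool(res.success), n=int(e.size))


def logistic_risk(x, model: LogisticRiskModel):
    """Toxicity probability sigmoid(a + b*x) for volume fraction x in [0, 1]."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise ValueError("volume fraction must lie in [0, 1]")
    out = expit(model.intercept_a + model.slope_b * x_arr)
    return float(out) if x_arr.ndim == 0 else out


def _separation_fallback(y, X, n):
    """Penalty-free BFGS refit used when Newton hits complete separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
    se = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        wald_p_slope=float("nan"),
        loglik=float(res.llf),
        aic=float(res.aic),
        n=n,
        converged=False,
    )


def fit_logistic_univariate(x, y) -> LogisticFit:
    """ML fit of P(y=1) = sigmoid(intercept + slope*x) with Wald inference.

    Complete separation is flagged (``converged=False``, slope p-value NaN)
    rather than raised; a constant predictor raises
    :class:`~bladtox.errors.CollinearPredictorError`.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size or x_arr.size < 10:
        raise InsufficientDataError("need at least 10 observations")
    if y_arr.min() == y_arr.max():
        raise DegenerateOutcomeError("both outcome classes must be present")
    if np.ptp(x_arr) == 0:
        raise CollinearPredictorError("predictor is constant")
    X = sm.add_constant(x_arr)
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=PerfectSeparationWarning)
            res = sm.Logit(y_arr, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return _separation_fallback(y_arr, X, int(x_arr.size))
    converged = bool(res.mle_retvals.get("converged", True))
    # quasi-separation escapes Newton occasionally; a wild slope is the tell
    if converged and abs(res.params[1]) > 1e3:
        converged = False
    return LogisticFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        wald_p_slope=float(res.pvalues[1]) if converged else float("nan"),
        loglik=float(res.llf),
        aic=float(res.aic),
        n=int(x_arr.size),
        converged=converged,
    )
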
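"""TOF-to-IOP calibration: linear and power-law models, validation, sensitivity.

The phantom protocol fits a straight line between reference IOP and
time-of-flight on a *teaching* set and scores the fit on a held-out
*validation* set whose reference pressures never enter the fit.  The eye
data follow a power law ``IOP = a TOF^b`` — for an ideal tension wave on a
Laplace-pressurized sphere the surface travel time scales as ``P^(-1/2)``,
i.e. ``b = -2`` once the constant air-path delay is removed.  Sensitivity is
reported in the field's convention of microseconds of TOF per mmHg of IOP,
computed from the model's inverse.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ParameterError, ProtocolError

__all__ = [
    "CalibrationSet",
    "CalibrationModel",
    "ValidationReport",
    "fit_linear",
    "fit_power",
    "predict_iop",
    "inverse_tof",
    "evaluate_validation",
    "sensitivity",
    "subtract_air_delay",
]


@dataclass(frozen=True)
class CalibrationSet:
    """Paired (TOF, reference IOP) observations with ids and a role."""

    tof_s: tuple[float, ...]
    iop_mmHg: tuple[float, ...]
    ids: tuple[str, ...]
    role: str = "teaching"  # teaching | validation

    def __post_init__(self) -> None:
        n = len(self.tof_s)
        if not (n == len(self.iop_mmHg) == len(self.ids)):
            raise ParameterError("tof_s, iop_mmHg and ids must have equal length")
        if any(p <= 0 for p in self.iop_mmHg):
            raise ParameterError("all reference IOP values must be > 0 mmHg")
        if self.role not in ("teaching", "validation"):
            raise ParameterError(f"role must be teaching|validation, got {self.role!r}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, role: str = "teaching",
                   tof_column: str = "tof_s",
                   iop_column: str = "reference_iop_mmHg") -> "CalibrationSet":
        """Build a set from an extraction results table, dropping rejected rows."""
        if "qc" in table.columns:
            table = table[table["qc"].isin(["accepted", "manually_corrected"])]
        table = table.dropna(subset=[tof_column, iop_column])
        return cls(tof_s=tuple(float(v) for v in table[tof_column]),
                   iop_mmHg=tuple(float(v) for v in table[iop_column]),
                   ids=tuple(str(v) for v in table["sample_id"]),
                   role=role)

    @property
    def n(self) -> int:
        return len(self.tof_s)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.tof_s, dtype=float), np.asarray(self.iop_mmHg, dtype=float)

    def provenance_hash(self) -> str:
        payload = json.dumps([self.ids, self.tof_s, self.iop_mmHg, self.role],
                             sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CalibrationModel:
    """A fitted TOF -> IOP mapping, linear or power-law.

    Linear params: ``slope`` (mmHg/s), ``intercept`` (mmHg).
    Power params: ``a``, ``b`` in ``IOP = a * tof_s**b`` (TOF in seconds).
    """

    kind: str  # linear | power
    params: dict[str, float]
    tof_units: str = "s"
    diagnostics: dict = field(default_factory=dict)
    teaching_ids: tuple[str, ...] = ()
    provenance_hash: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "params": self.params, "tof_units": self.tof_units,
            "diagnostics": self.diagnostics, "teaching_ids": list(self.teaching_ids),
            "provenance_hash": self.provenance_hash,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"],
                   tof_units=d.get("tof_units", "s"),
                   diagnostics=d.get("diagnostics", {}),
                   teaching_ids=tuple(d.get("teaching_ids", ())),
                   provenance_hash=d.get("provenance_hash", ""))


@dataclass
class ValidationReport:
    """Held-out prediction errors for a fitted model."""

    ids: tuple[str, ...]
    predicted_iop_mmHg: tuple[float, ...]
    errors_mmHg: tuple[float, ...]
    mean_absolute_error_mmHg: float
    max_absolute_error_mmHg: float
    rms_error_mmHg: float


def _require_fittable(calset: CalibrationSet) -> tuple[np.ndarray, np.ndarray]:
    tof, iop = calset.arrays()
    if calset.n < 2 or np.unique(tof).size < 2:
        raise FitError("need at least 2 distinct TOF values to fit")
    return tof, iop


def fit_linear(calset: CalibrationSet) -> CalibrationModel:
    """Ordinary least squares of IOP on TOF."""
    tof, iop = _require_fittable(calset)
    res = stats.linregress(tof, iop)
    pred = res.intercept + res.slope * tof
    sse = float(np.sum((iop - pred) ** 2))
    return CalibrationModel(
        kind="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        diagnostics={"r_squared": float(res.rvalue ** 2), "sse": sse,
                     "n": calset.n},
        teaching_ids=calset.ids,
        provenance_hash=calset.provenance_hash())


def fit_power(calset: CalibrationSet) -> CalibrationModel:
    """Nonlinear least squares of ``IOP = a * TOF^b`` in original units.

    Initialized from the log-log linear fit; converges on relative parameter
    change below 1e-10 within 200 iterations or raises with diagnostics.
    """
    tof, iop = _require_fittable(calset)
    if np.any(tof <= 0):
        raise FitError("power fit requires all TOF values > 0")
    slope, log_a = np.polyfit(np.log(tof), np.log(iop), 1)
    p0 = (math.exp(log_a), slope)
    try:
        with warnings.catch_warnings():
            # covariance is undefined for an exactly-interpolating fit
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(lambda x, a, b: a * np.power(x, b),
                                         tof, iop, p0=p0, xtol=1e-10,
                                         maxfev=200 * 3)
    except RuntimeError as exc:
        raise FitError(f"power fit did not converge (init a={p0[0]:.4g}, "
                       f"b={p0[1]:.4g}): {exc}") from exc
    a, b = (float(popt[0]), float(popt[1]))
    if a <= 0:
        raise FitError(f"power fit produced non-positive scale a={a:.4g}")
    pred = a * tof ** b
    sse = float(np.sum((iop - pred) ** 2))
    ss_tot = float(np.sum((iop - iop.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationModel(
        kind="power", params={"a": a, "b": b},
        diagnostics={"r_squared": r2, "sse": sse, "n": calset.n,
                     "init_a": p0[0], "init_b": p0[1]},
        teaching_ids=calset.ids,
        provenance_hash=calset.provenance_hash())


def predict_iop(model: CalibrationModel, tof_s):
    """Evaluate the model at one or more TOF values (seconds) -> IOP (mmHg)."""
    tof = np.asarray(tof_s, dtype=float)
    if model.kind == "linear":
        out = model.params["intercept"] + model.params["slope"] * tof
    elif model.kind == "power":
        if np.any(tof <= 0):
            raise ParameterError("power model prediction requires tof > 0")
        out = model.params["a"] * tof ** model.params["b"]
    else:
        raise ParameterError(f"unknown model kind {model.kind!r}")
    return float(out) if np.isscalar(tof_s) else out


def inverse_tof(model: CalibrationModel, iop_mmHg):
    """Invert the model: TOF (seconds) at a given IOP (mmHg)."""
    iop = np.asarray(iop_mmHg, dtype=float)
    if model.kind == "linear":
        slope = model.params["slope"]
        if slope == 0:
            raise ParameterError("linear model with zero slope is not invertible")
        out = (iop - model.params["intercept"]) / slope
    elif model.kind == "power":
        a, b = model.params["a"], model.params["b"]
        if b == 0:
            raise ParameterError("power model with b = 0 is not invertible")
        if np.any(iop <= 0):
            raise ParameterError("power model inverse requires iop > 0")
        out = (iop / a) ** (1.0 / b)
    else:
        raise ParameterError(f"unknown model kind {model.kind!r}")
    return float(out) if np.isscalar(iop_mmHg) else out


def evaluate_validation(model: CalibrationModel,
                        validation: CalibrationSet) -> ValidationReport:
    """Score a fitted model on held-out pairs, enforcing the blinding protocol.

    Raises if any validation id also appears among the ids the model was
    fitted on (the analyst must be blinded to validation pressures).
    """
    overlap = set(model.teaching_ids) & set(validation.ids)
    if overlap:
        raise ProtocolError(
            f"validation ids overlap the teaching set: {sorted(overlap)}")
    tof, iop = validation.arrays()
    pred = np.asarray(predict_iop(model, tof), dtype=float)
    err = pred - iop
    return ValidationReport(
        ids=validation.ids,
        predicted_iop_mmHg=tuple(float(v) for v in pred),
        errors_mmHg=tuple(float(v) for v in err),
        mean_absolute_error_mmHg=float(np.mean(np.abs(err))),
        max_absolute_error_mmHg=float(np.max(np.abs(err))),
        rms_error_mmHg=float(np.sqrt(np.mean(err ** 2))))


def sensitivity(model: CalibrationModel, iop_lo_mmHg: float,
                iop_hi_mmHg: float) -> float:
    """Secant TOF-per-IOP slope over [lo, hi], in microseconds per mmHg.

    Uses the model's inverse (TOF as a function of IOP); negative whenever
    TOF decreases with pressure.  For power models with b < 0 the magnitude
    shrinks as IOP grows — the source of the heteroscedastic agreement at
    high pressures.
    """
    if not iop_lo_mmHg < iop_hi_mmHg:
        raise ParameterError("require iop_lo < iop_hi")
    t_lo = inverse_tof(model, iop_lo_mmHg)
    t_hi = inverse_tof(model, iop_hi_mmHg)
    return (t_hi - t_lo) / (iop_hi_mmHg - iop_lo_mmHg) * 1e6


def subtract_air_delay(tof_s: Sequence[float] | np.ndarray,
                       air_delay_s: float) -> np.ndarray:
    """Remove the constant air-path delay, leaving the surface travel time.

    The pressure dependence lives entirely in the surface term, so power-law
    fitting is done on air-delay-corrected TOFs by default.
    """
    out = np.asarray(tof_s, dtype=float) - air_delay_s
    if np.any(out <= 0):
        raise ParameterError("air delay exceeds at least one TOF value")
    return out
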
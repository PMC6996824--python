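"""Method-agreement statistics: Bland-Altman, Pearson correlation, residuals.

Bland-Altman analysis summarizes the differences between two measurement
methods by their mean (bias) and spread; the reproducibility coefficient
RPC = 1.96 x SD of the differences bounds 95% of differences around the
bias, and the limits of agreement are bias ± RPC.  The SD uses the n-1
denominator, the standard choice for sampled differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationModel, CalibrationSet, predict_iop
from .errors import ParameterError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "ResidualSummary",
    "bland_altman",
    "pearson_r2",
    "residual_summary",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two same-length measurement series (mmHg) with pair ids."""

    method_a: tuple[float, ...]
    method_b: tuple[float, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.method_a) != len(self.method_b):
            raise ParameterError("paired series must have equal length")
        if len(self.method_a) < 2:
            raise ParameterError("need at least 2 pairs")
        if not self.ids:
            object.__setattr__(self, "ids",
                               tuple(str(i) for i in range(len(self.method_a))))
        if len(self.ids) != len(self.method_a):
            raise ParameterError("ids must match the series length")
        a, b = self.arrays()
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ParameterError("paired values must be finite")

    @classmethod
    def from_sequences(cls, a: Sequence[float], b: Sequence[float],
                       ids: Sequence[str] | None = None) -> "PairedMeasurements":
        return cls(tuple(float(v) for v in a), tuple(float(v) for v in b),
                   tuple(ids) if ids is not None else ())

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.method_a, dtype=float),
                np.asarray(self.method_b, dtype=float))

    @property
    def n(self) -> int:
        return len(self.method_a)


@dataclass
class AgreementReport:
    """Bland-Altman summary of method A minus method B."""

    n: int
    bias_mmHg: float
    sd_diff_mmHg: float
    rpc_mmHg: float
    loa_low_mmHg: float
    loa_high_mmHg: float
    pearson_r2: float | None = None
    differences: tuple[float, ...] = ()


@dataclass
class ResidualSummary:
    """Residuals of a calibration model on observed pairs."""

    ids: tuple[str, ...]
    residuals_mmHg: tuple[float, ...]
    sse: float
    rms_residual_mmHg: float


def bland_altman(pairs: PairedMeasurements,
                 with_correlation: bool = True) -> AgreementReport:
    """Bland-Altman agreement of method A against method B.

    Differences are a - b; bias is their mean, the SD uses the n-1
    denominator, RPC = 1.96 SD, and the limits of agreement are bias ± RPC.
    """
    a, b = pairs.arrays()
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    rpc = 1.96 * sd
    r2 = None
    if with_correlation:
        try:
            r2 = pearson_r2(pairs)
        except ParameterError:
            r2 = None
    return AgreementReport(n=pairs.n, bias_mmHg=bias, sd_diff_mmHg=sd,
                           rpc_mmHg=rpc, loa_low_mmHg=bias - rpc,
                           loa_high_mmHg=bias + rpc, pearson_r2=r2,
                           differences=tuple(float(d) for d in diff))


def pearson_r2(pairs: PairedMeasurements) -> float:
    """Squared Pearson correlation between the two series."""
    a, b = pairs.arrays()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("correlation undefined for a constant series")
    r, _ = stats.pearsonr(a, b)
    return float(r ** 2)


def residual_summary(model: CalibrationModel,
                     calset: CalibrationSet) -> ResidualSummary:
    """Observed-minus-predicted residuals of a model on (TOF, IOP) pairs.

    Both the sum of squared residuals (mmHg^2) and the RMS residual (mmHg)
    are reported; published "SSE" figures in this area are sometimes quoted
    in mmHg, i.e. as an RMS-like quantity, so neither is guessed at.
    """
    tof, iop = calset.arrays()
    pred = np.asarray(predict_iop(model, tof), dtype=float)
    res = iop - pred
    return ResidualSummary(ids=calset.ids,
                           residuals_mmHg=tuple(float(v) for v in res),
                           sse=float(np.sum(res ** 2)),
                           rms_residual_mmHg=float(np.sqrt(np.mean(res ** 2))))
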
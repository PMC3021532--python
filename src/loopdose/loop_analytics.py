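"""Per-cycle observables: hysteresis-loop area, dose cumulant, cycle statistics,
and the derived dose-effect features (optimal dose, effective duty cycle)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .model_core import InterventionSpec, ValidationError, Waveform

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import Trajectory

__all__ = [
    "CycleRecord",
    "loop_area",
    "dose_cumulant",
    "cycle_stats",
    "dose_effect_derivative",
    "optimal_dose_cumulant",
    "effective_duty_cycle",
]


@dataclass
class CycleRecord:
    """Measured quantities of one steady therapy cycle.

    ``S`` is the hysteresis-loop area of x against h, ``I`` the dose
    delivered per cycle, ``mean_x`` the time-averaged density and
    ``delta_x`` the max-min excursion.  Unconverged cells may carry NaN
    observables.
    """

    S: float
    I: float
    mean_x: float
    delta_x: float
    h0: float
    d: float
    T: float
    waveform: Waveform
    eradicated: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        self.waveform = Waveform(self.waveform)
        for name in ("S", "I", "mean_x", "delta_x"):
            v = getattr(self, name)
            if math.isfinite(v) and v < -1e-12:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if math.isfinite(self.I) and self.I > self.h0 * self.T * (1 + 1e-9):
            raise ValidationError(f"I={self.I} exceeds h0*T={self.h0 * self.T}")


def loop_area(traj: "Trajectory", closure_rtol: float = 1e-3) -> float:
    """Area enclosed by the (h, x) loop of one closed cycle.

    Uses the shoelace formula on the sampled polygon, which equals
    |contour integral of x dh| in the dense-sampling limit.  The first and
    last samples must be the same cycle phase (the polygon is closed by
    wrapping); jumps of a rectangular drive are handled because both the
    pre- and post-jump samples are vertices.
    """
    h = np.asarray(traj.h, dtype=float)
    x = np.asarray(traj.x, dtype=float)
    if len(h) < 3:
        raise ValidationError("loop_area needs at least 3 samples")
    scale_h = max(float(np.max(np.abs(h))), 1e-30)
    scale_x = max(float(np.max(np.abs(x))), 1e-30)
    if abs(h[-1] - h[0]) > closure_rtol * scale_h or abs(x[-1] - x[0]) > closure_rtol * scale_x:
        raise ValidationError("trajectory is not a closed cycle (first/last samples differ)")
    hx = np.append(h, h[0])
    xx = np.append(x, x[0])
    area = 0.5 * float(np.sum(hx[:-1] * xx[1:] - hx[1:] * xx[:-1]))
    return abs(area)


def dose_cumulant(spec: InterventionSpec) -> float:
    """Dose delivered per cycle, the integral of h(t) over one period.

    Closed forms: rectangular -> h0*d*T; half-sine -> (2/pi)*h0*d*T.
    """
    if spec.waveform is Waveform.NONE or spec.h0 == 0:
        return 0.0
    if spec.waveform is Waveform.RECTANGULAR:
        return spec.h0 * spec.d * spec.T
    return (2.0 / math.pi) * spec.h0 * spec.d * spec.T


def cycle_stats(traj: "Trajectory") -> tuple[float, float]:
    """Time-weighted cycle average of x and its max-min excursion."""
    t = np.asarray(traj.t, dtype=float)
    x = np.asarray(traj.x, dtype=float)
    if len(t) == 0:
        raise ValidationError("empty trajectory")
    if len(t) == 1:
        return float(x[0]), 0.0
    mean_x = float(np.trapezoid(x, t) / (t[-1] - t[0]))
    delta_x = float(np.max(x) - np.min(x))
    return mean_x, delta_x


def _extract(records: Sequence, x_attr: str, y_attr: str = "mean_x") -> tuple[np.ndarray, np.ndarray]:
    """Pull (x, y) columns from CycleRecords or plain (x, y) pairs."""
    xs, ys = [], []
    for r in records:
        if hasattr(r, x_attr):
            xs.append(float(getattr(r, x_attr)))
            ys.append(float(getattr(r, y_attr)))
        else:
            xi, yi = r
            xs.append(float(xi))
            ys.append(float(yi))
    return np.asarray(xs), np.asarray(ys)


def _finite_differences(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central differences at interior points, one-sided at the ends."""
    if len(x) < 3:
        raise ValidationError("need at least 3 points for derivatives")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("abscissae must be strictly increasing (no duplicates)")
    deriv = np.empty_like(y)
    deriv[0] = (y[1] - y[0]) / (x[1] - x[0])
    deriv[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    deriv[1:-1] = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    return deriv


def dose_effect_derivative(records: Sequence) -> list[tuple[float, float]]:
    """Numerical derivative of mean density with respect to dose cumulant.

    ``records`` is a sequence of CycleRecords (or (I, mean_x) pairs)
    sorted by strictly increasing I at fixed amplitude.
    """
    I, mx = _extract(records, "I")
    deriv = _finite_differences(I, mx)
    return list(zip(I.tolist(), deriv.tolist()))


def _flat_tail_onset(x: np.ndarray, y: np.ndarray, flatness_frac: float) -> float | None:
    """Smallest abscissa beyond which the response slope stays flat.

    The slope is deemed flat where |dy/dx| <= flatness_frac * max|dy/dx|.
    Returns the point just before the earliest all-flat tail, or None if
    the curve never flattens (e.g. the steepest slope is at the end).
    """
    deriv = np.abs(_finite_differences(x, y))
    thr = flatness_frac * float(np.max(deriv))
    flat = deriv <= thr
    # suffix_flat[k] == all(flat[k:])
    for k in range(1, len(x)):
        if np.all(flat[k:]):
            return float(x[k - 1])
    return None


def optimal_dose_cumulant(records: Sequence, flatness_frac: float = 0.1) -> float | None:
    """Dose cumulant above which mean tumor burden stays flat (I_O)."""
    I, mx = _extract(records, "I")
    return _flat_tail_onset(I, mx, flatness_frac)


def effective_duty_cycle(records: Sequence, flatness_frac: float = 0.1) -> float | None:
    """Duty cycle above which further dosing barely lowers the burden (d_e)."""
    d, mx = _extract(records, "d")
    return _flat_tail_onset(d, mx, flatness_frac)
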
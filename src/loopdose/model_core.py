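"""Forced tumor-immune growth model: ODE right-hand side and therapy waveforms.

The autonomous model is a logistic growth law with a saturating immune
predation term,

    dx/dt = a*x*(1 - b*x) - beta*x**2 / (eps + x**2),

to which a periodic therapy term ``h(t)`` is coupled either additively
(``-h(t)``, a constant-rate kill while the drug is on) or multiplicatively
(``-h(t)*x``, a per-capita kill).  ``h(t)`` is a pulse train with period
``T``, amplitude ``h0`` and duty cycle ``d`` (on-fraction of each cycle).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "Coupling",
    "Waveform",
    "ModelParams",
    "InterventionSpec",
    "ValidationError",
    "waveform_value",
    "rhs",
    "rhs_derivative",
    "untreated_steady_states",
    "stable_untreated_state",
]


class ValidationError(ValueError):
    """Raised when a parameter set violates its invariants."""


class Coupling(str, enum.Enum):
    """How the intervention enters the ODE."""

    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"


class Waveform(str, enum.Enum):
    """Therapy pulse shape within the on-window [0, T0)."""

    RECTANGULAR = "rectangular"
    HALFSINE = "halfsine"
    NONE = "none"


@dataclass(frozen=True)
class ModelParams:
    """Constants of the autonomous model.

    Attributes
    ----------
    a : float
        Per-capita linear growth rate (1/time).
    b : float
        Logistic saturation coefficient (1/density); carrying capacity 1/b.
    beta : float
        Immune attack strength.
    eps : float
        Immune activation threshold (density squared).
    coupling : Coupling
        How ``h(t)`` enters the ODE (additive kill by default).
    """

    a: float = 1.0
    b: float = 0.10
    beta: float = 1.0
    eps: float = 1.0
    coupling: Coupling = Coupling.ADDITIVE

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError(f"require a > 0 and b > 0, got a={self.a}, b={self.b}")
        if self.beta < 0:
            raise ValidationError(f"require beta >= 0, got {self.beta}")
        if not self.eps > 0:
            raise ValidationError(f"require eps > 0, got {self.eps}")
        object.__setattr__(self, "coupling", Coupling(self.coupling))


@dataclass(frozen=True)
class InterventionSpec:
    """One periodic therapy schedule.

    The pulse is on during ``[0, T0)`` with ``T0 = d*T`` and off during
    ``[T0, T)``; evaluation is periodic with period ``T``.
    """

    waveform: Waveform = Waveform.RECTANGULAR
    h0: float = 0.5
    T: float = 10.0
    d: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", Waveform(self.waveform))
        if self.h0 < 0:
            raise ValidationError(f"require h0 >= 0, got {self.h0}")
        if not self.T > 0:
            raise ValidationError(f"require T > 0, got {self.T}")
        if not (0 < self.d <= 1):
            raise ValidationError(f"require 0 < d <= 1, got {self.d}")

    @property
    def T0(self) -> float:
        """On-duration of each cycle."""
        return self.d * self.T


def waveform_value(spec: InterventionSpec, t):
    """Evaluate the intervention level ``h(t)``.

    Accepts a scalar or array ``t`` (any real; evaluated mod ``T``).
    Rectangular pulses are ``h0`` on ``[0, T0)``; half-sine pulses are
    ``h0*sin(pi*t/T0)`` on ``[0, T0)``; both vanish on ``[T0, T)``.
    """
    t = np.asarray(t, dtype=float)
    if spec.waveform is Waveform.NONE or spec.h0 == 0:
        return np.zeros_like(t) if t.ndim else 0.0
    tm = np.mod(t, spec.T)
    on = tm < spec.T0
    if spec.waveform is Waveform.RECTANGULAR:
        h = np.where(on, spec.h0, 0.0)
    else:  # half-sine
        h = np.where(on, spec.h0 * np.sin(np.pi * tm / spec.T0), 0.0)
        h = np.maximum(h, 0.0)  # guard rounding at the window edges
    return h if t.ndim else float(h)


def rhs(params: ModelParams, spec: InterventionSpec, t: float, x: float) -> float:
    """Time derivative of the tumor density under the forced model."""
    growth = params.a * x * (1.0 - params.b * x)
    immune = params.beta * x * x / (params.eps + x * x)
    h = waveform_value(spec, t)
    kill = h if params.coupling is Coupling.ADDITIVE else h * x
    return growth - immune - kill


def rhs_derivative(params: ModelParams, x: float, h: float = 0.0) -> float:
    """d(rhs)/dx at density ``x`` for a frozen intervention level ``h``."""
    growth = params.a - 2.0 * params.a * params.b * x
    denom = params.eps + x * x
    immune = 2.0 * params.beta * params.eps * x / (denom * denom)
    kill = 0.0 if params.coupling is Coupling.ADDITIVE else h
    return growth - immune - kill


_NO_THERAPY = InterventionSpec(waveform=Waveform.NONE, h0=0.0, T=1.0, d=0.5)


def untreated_steady_states(params: ModelParams) -> list[tuple[float, bool]]:
    """All real nonnegative fixed points of the unforced model.

    Returns ``(density, stable)`` pairs sorted by density; stability is the
    sign of d(rhs)/dx at the root.  ``x = 0`` is always included.  Nonzero
    roots solve ``a*(1 - b*x)*(eps + x**2) - beta*x = 0``; they are found
    from the cubic's companion matrix and polished by Newton iteration on
    the full right-hand side.

    Raises
    ------
    RuntimeError
        If a root fails to polish to |rhs| < 1e-9.
    """
    a, b, beta, eps = params.a, params.b, params.beta, params.eps
    # ascending coefficients of a*(1-b*x)*(eps+x^2) - beta*x
    poly = np.polynomial.Polynomial([a * eps, -(a * b * eps + beta), a, -a * b])
    roots = poly.roots()
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and r.real > 1e-12
    )

    out: list[tuple[float, bool]] = [(0.0, rhs_derivative(params, 0.0) < 0)]
    f = lambda x: rhs(params, _NO_THERAPY, 0.0, x)
    for r in real:
        try:
            r = float(optimize.newton(f, r, fprime=lambda x: rhs_derivative(params, x), tol=1e-13, maxiter=100))
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"steady-state polish failed near x={r}: {exc}") from exc
        residual = abs(f(r))
        if not (math.isfinite(r) and residual < 1e-9):
            raise RuntimeError(
                f"steady-state root near x={r} did not converge (|rhs|={residual:.3e})"
            )
        out.append((r, rhs_derivative(params, r) < 0))
    # dedupe near-coincident roots (double roots at fold points)
    deduped: list[tuple[float, bool]] = []
    for x, s in out:
        if not deduped or abs(x - deduped[-1][0]) > 1e-8:
            deduped.append((x, s))
    return deduped


def stable_untreated_state(params: ModelParams) -> float:
    """Largest stable fixed point of the unforced model (treatment-naive tumor)."""
    stable = [x for x, s in untreated_steady_states(params) if s]
    if not stable:
        raise RuntimeError("no stable untreated steady state found")
    return stable[-1]
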
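"""Synthetic inputs with known ground truth for every analysis stage.

These generators stand in for the ODE simulations: analytic hysteresis
loops with closed-form area, response surfaces drawn from a known quadratic
dose-effectiveness law, and sigmoidal dose-effect curves with a known
flat-tail onset.  Every stochastic fixture is reproducible from its seed,
and each generator returns its ground truth alongside the data so tests
never recompute expectations with the code under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np

from .loop_analytics import CycleRecord
from .model_core import ModelParams, ValidationError, Waveform
from .scaling_collapse import ResponseSurface
from .simulator import Trajectory

__all__ = [
    "FixtureSpec",
    "DoseEffectPoint",
    "make_ellipse_loop",
    "make_rect_loop",
    "make_quadratic_surface",
    "make_sigmoid_curve",
    "make_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # ellipse_loop | rect_loop | quadratic_surface | sigmoid_curve
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    n_samples: int = 2000

    _KINDS = ("ellipse_loop", "rect_loop", "quadratic_surface", "sigmoid_curve")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown fixture kind {self.kind!r}; expected one of {self._KINDS}")


class DoseEffectPoint(NamedTuple):
    """Minimal dose-effect record (duck-types CycleRecord for analytics)."""

    I: float
    d: float
    mean_x: float


def make_ellipse_loop(
    h0: float, x0: float, phi: float, c: float, n_samples: int = 2000
) -> tuple[Trajectory, dict]:
    """Closed elliptical loop h = h0*sin(t), x = c + x0*sin(t - phi).

    The enclosed area is exactly pi*h0*x0*sin(phi).
    """
    if h0 <= 0 or x0 <= 0:
        raise ValidationError("h0 and x0 must be positive")
    if not (0 <= phi <= math.pi):
        raise ValidationError(f"phase lag must lie in [0, pi], got {phi}")
    if c < x0:
        raise ValidationError(f"offset c={c} < x0={x0} would make x negative")
    t = np.linspace(0.0, 2.0 * math.pi, n_samples + 1)
    h = h0 * np.sin(t)
    x = c + x0 * np.sin(t - phi)
    traj = Trajectory(t=t, x=x, h=h, converged=True, n_transient_cycles=0)
    return traj, {"area": math.pi * h0 * x0 * math.sin(phi), "mean_x": float(c), "delta_x": 2.0 * x0}


def make_rect_loop(h0: float, x_low: float, x_high: float, n_samples: int = 2000) -> tuple[Trajectory, dict]:
    """Ideal rectangular loop: two vertical branches at h=0 and h=h0.

    Traversal: drop from x_high to x_low at h=h0, return at h=0.
    Its area is exactly h0*(x_high - x_low).
    """
    if h0 <= 0:
        raise ValidationError("h0 must be positive")
    if not (0 <= x_low < x_high):
        raise ValidationError("require 0 <= x_low < x_high")
    n = max(n_samples // 4, 2)
    down = np.linspace(x_high, x_low, n)
    up = np.linspace(x_low, x_high, n)
    x = np.concatenate([down, np.full(2, x_low), up, np.full(2, x_high)])
    h = np.concatenate([np.full(n, h0), [h0, 0.0], np.zeros(n), [0.0, h0]])
    t = np.linspace(0.0, 1.0, len(x))
    traj = Trajectory(t=t, x=x, h=h, converged=True, n_transient_cycles=0)
    return traj, {"area": h0 * (x_high - x_low)}


def make_quadratic_surface(
    m: float,
    n: float,
    h0_grid,
    d_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
    T: float = 10.0,
) -> tuple[ResponseSurface, dict]:
    """Response surface whose exact collapse is a known quadratic law.

    Dose cumulants follow the rectangular closed form I = h0*d*T, so the
    per-row reduced abscissae I' = d/max(d) are row-independent.  Loop
    areas are set to S = h0 * q(I')/max(q) for q(x) = m*x**2 + n*x, plus
    optional per-row-scaled Gaussian noise (``S += h0*sigma*N(0,1)``,
    clipped at 0).  Because max-normalization rescales q by its grid
    maximum, the coefficients recovered by the collapse are
    (m, n)/max(q) — returned as ground truth ``m_true``/``n_true``; the
    vertex ``x_star = -n/(2m)`` is invariant under that rescaling.
    """
    if not (m < 0 < n):
        raise ValidationError(f"require m < 0 < n for an interior peak, got m={m}, n={n}")
    h0_grid = np.asarray(h0_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(h0_grid <= 0) or np.any(d_grid <= 0) or np.any(d_grid > 1):
        raise ValidationError("h0_grid must be positive and d_grid in (0, 1]")
    rng = np.random.default_rng(seed)
    I_prime = d_grid / d_grid.max()
    q = m * I_prime**2 + n * I_prime
    if np.any(q < 0):
        # the reduction pins the largest abscissa at I'=1, so laws with
        # m + n < 0 would demand negative loop areas there
        raise ValidationError(
            f"law m={m}, n={n} is negative at reduced dose(s) "
            f"{I_prime[q < 0].tolist()}; need m + n >= 0 for a realizable surface"
        )
    q_max = float(q.max())
    # cells within 3 sigma of the row maximum stay noise-free so the
    # max-normalization anchor is never displaced (a noisy anchor would bias
    # every point in the row and, with it, the recovered coefficients)
    anchored = q >= q.max() - 3.0 * noise_sigma * q.max()
    records: list[list[CycleRecord]] = []
    for h0 in h0_grid:
        noise = rng.normal(0.0, noise_sigma, size=len(d_grid)) if noise_sigma > 0 else np.zeros(len(d_grid))
        noise[anchored] = 0.0
        row = []
        for j, d in enumerate(d_grid):
            S = max(h0 * (q[j] / q_max + noise[j]), 0.0)
            row.append(
                CycleRecord(
                    S=float(S),
                    I=float(h0 * d * T),
                    mean_x=0.0,
                    delta_x=float(S / h0),
                    h0=float(h0),
                    d=float(d),
                    T=T,
                    waveform=Waveform.RECTANGULAR,
                    eradicated=False,
                    converged=True,
                )
            )
        records.append(row)
    surface = ResponseSurface(
        h0_grid=h0_grid,
        d_grid=d_grid,
        records=records,
        waveform=Waveform.RECTANGULAR,
        T=T,
        params=ModelParams(),
    )
    truth = {
        "m_raw": m,
        "n_raw": n,
        "m_true": m / q_max,
        "n_true": n / q_max,
        "x_star": -n / (2.0 * m),
        "y_star": (-n * n / (4.0 * m)) / q_max,
    }
    return surface, truth


def make_sigmoid_curve(
    midpoint: float, slope: float, ceiling: float, I_grid, flatness_frac: float = 0.1
) -> tuple[list[DoseEffectPoint], dict]:
    """Decreasing sigmoidal dose-effect curve with a known flat-tail onset.

    mean_x = ceiling / (1 + exp(slope*(I - midpoint))).  The ground-truth
    onset is found by a brute-force scan of the flatness definition over
    finite-difference slopes (independent of the analytics implementation).
    """
    I = np.asarray(I_grid, dtype=float)
    if len(I) < 3 or np.any(np.diff(I) <= 0):
        raise ValidationError("I_grid must be strictly increasing with >= 3 points")
    mx = ceiling / (1.0 + np.exp(np.clip(slope * (I - midpoint), -700, 700)))
    # brute-force scan: slopes by plain difference quotients, then the
    # earliest index whose entire tail is below the flatness threshold
    slopes = np.empty_like(mx)
    slopes[0] = (mx[1] - mx[0]) / (I[1] - I[0])
    slopes[-1] = (mx[-1] - mx[-2]) / (I[-1] - I[-2])
    for k in range(1, len(I) - 1):
        slopes[k] = (mx[k + 1] - mx[k - 1]) / (I[k + 1] - I[k - 1])
    thr = flatness_frac * np.max(np.abs(slopes))
    onset = None
    for k in range(1, len(I)):
        if all(abs(s) <= thr for s in slopes[k:]):
            onset = float(I[k - 1])
            break
    records = [DoseEffectPoint(I=float(Ii), d=float(Ii / I[-1]), mean_x=float(mi)) for Ii, mi in zip(I, mx)]
    return records, {"flat_tail_onset": onset, "midpoint": midpoint}


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator; returns (data, truth)."""
    p = dict(spec.parameters)
    if spec.kind == "ellipse_loop":
        return make_ellipse_loop(
            p["h0"], p["x0"], p["phi"], p["c"], n_samples=spec.n_samples
        )
    if spec.kind == "rect_loop":
        return make_rect_loop(p["h0"], p["x_low"], p["x_high"], n_samples=spec.n_samples)
    if spec.kind == "quadratic_surface":
        return make_quadratic_surface(
            p["m"],
            p["n"],
            p.get("h0_grid", np.arange(0.1, 1.01, 0.1)),
            p.get("d_grid", np.arange(0.1, 0.91, 0.1)),
            noise_sigma=p.get("noise_sigma", 0.0),
            seed=spec.seed,
            T=p.get("T", 10.0),
        )
    return make_sigmoid_curve(
        p["midpoint"], p["slope"], p["ceiling"], p["I_grid"], flatness_frac=p.get("flatness_frac", 0.1)
    )
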
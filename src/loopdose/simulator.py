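"""Integration of the forced model to its steady periodic regime.

Each therapy cycle is integrated in two segments split at the waveform
discontinuity ``t = T0`` so the solver never steps across the jump.  Cycles
are discarded until two consecutive cycles agree pointwise to within
``periodicity_tol``; the final converged cycle is returned densely sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .loop_analytics import CycleRecord, cycle_stats, dose_cumulant, loop_area
from .model_core import (
    InterventionSpec,
    ModelParams,
    ValidationError,
    Waveform,
    rhs,
    stable_untreated_state,
    waveform_value,
)
from .scaling_collapse import ResponseSurface

__all__ = ["SolverConfig", "Trajectory", "IntegrationError", "integrate_to_limit_cycle", "sweep_grid"]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver produces a non-finite state."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the cycle integrator."""

    rtol: float = 1e-8
    atol: float = 1e-10
    n_samples_per_cycle: int = 2000
    max_cycles: int = 200
    min_transient_cycles: int = 5
    periodicity_tol: float = 1e-6
    x_floor: float = 1e-8
    eradication_threshold: float = 1e-6
    x0: float | None = None  # None -> stable untreated steady state
    method: str = "RK45"


@dataclass
class Trajectory:
    """One densely sampled steady cycle of the forced model.

    ``t`` spans ``[0, T]`` inclusive (the first and last samples are the
    same cycle phase), ``x`` is the tumor density and ``h`` the intervention
    level at each sample.
    """

    t: np.ndarray
    x: np.ndarray
    h: np.ndarray
    converged: bool
    n_transient_cycles: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.h)):
            raise ValidationError("t, x, h must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("t must be strictly increasing")
        if np.any(self.x < 0):
            raise ValidationError("x must be nonnegative")


def _cycle_grid(spec: InterventionSpec, n_samples: int) -> np.ndarray:
    """Uniform phase grid on [0, T] with the discontinuity T0 inserted."""
    grid = np.linspace(0.0, spec.T, n_samples + 1)
    if spec.T0 < spec.T:
        grid = np.union1d(grid, [spec.T0])
    return grid


def _integrate_one_cycle(
    params: ModelParams,
    spec: InterventionSpec,
    x_start: float,
    grid: np.ndarray,
    config: SolverConfig,
) -> np.ndarray:
    """Integrate a single cycle on the phase grid; clamps to 0 at the floor."""
    if x_start <= config.x_floor:
        return np.zeros_like(grid)

    def fun(t, y):
        return [rhs(params, spec, t, max(y[0], 0.0))]

    def hit_floor(t, y):
        return y[0] - config.x_floor

    hit_floor.terminal = True
    hit_floor.direction = -1.0

    breaks = [0.0, spec.T] if spec.T0 >= spec.T else [0.0, spec.T0, spec.T]
    xs: list[np.ndarray] = []
    x = x_start
    dead = False
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if dead:
            xs.append(np.zeros(len(t_eval) - (1 if t1 != breaks[-1] else 0)))
            continue
        sol = solve_ivp(
            fun,
            (t0, t1),
            [x],
            t_eval=t_eval,
            rtol=config.rtol,
            atol=config.atol,
            method=config.method,
            events=hit_floor,
            dense_output=False,
        )
        if not sol.success and sol.status != 1:
            raise IntegrationError(f"solve_ivp failed on [{t0}, {t1}]: {sol.message}")
        seg = np.maximum(sol.y[0], 0.0)
        if not np.all(np.isfinite(seg)):
            raise IntegrationError(f"non-finite state on [{t0}, {t1}]")
        if sol.status == 1:  # hit the eradication floor mid-segment
            dead = True
            seg = np.zeros(len(t_eval))
            n_done = len(sol.t)
            seg[:n_done] = np.maximum(sol.y[0], 0.0)
            x = 0.0
        else:
            x = float(seg[-1])
        # drop the segment's right endpoint except on the last segment (shared node)
        xs.append(seg[:-1] if t1 != breaks[-1] else seg)
    return np.concatenate(xs)


def integrate_to_limit_cycle(
    params: ModelParams,
    spec: InterventionSpec,
    config: SolverConfig | None = None,
) -> Trajectory:
    """Integrate cycle by cycle until the orbit is periodic, return the last cycle.

    The initial condition defaults to the stable untreated steady state.
    Convergence requires at least ``min_transient_cycles`` discarded cycles
    and two consecutive cycles agreeing to ``periodicity_tol`` at every
    phase sample; if ``max_cycles`` is exhausted the last cycle is returned
    with ``converged=False``.
    """
    config = config or SolverConfig()
    grid = _cycle_grid(spec, config.n_samples_per_cycle)
    x0 = config.x0 if config.x0 is not None else stable_untreated_state(params)

    prev: np.ndarray | None = None
    x_start = float(x0)
    converged = False
    n_cycles = 0
    xc = np.full_like(grid, x_start)
    while n_cycles < config.max_cycles:
        xc = _integrate_one_cycle(params, spec, x_start, grid, config)
        n_cycles += 1
        if prev is not None and n_cycles > config.min_transient_cycles:
            if float(np.max(np.abs(xc - prev))) < config.periodicity_tol:
                converged = True
                break
        prev = xc
        x_start = float(xc[-1])

    h = np.asarray(waveform_value(spec, grid), dtype=float)
    return Trajectory(t=grid, x=xc, h=h, converged=converged, n_transient_cycles=n_cycles - 1)


def _cell_record(
    params: ModelParams,
    spec: InterventionSpec,
    config: SolverConfig,
) -> CycleRecord:
    traj = integrate_to_limit_cycle(params, spec, config)
    eradicated = bool(np.min(traj.x) < config.eradication_threshold)
    mean_x, delta_x = cycle_stats(traj)
    try:
        S = loop_area(traj) if traj.converged else float("nan")
    except ValidationError:
        S = float("nan")
    return CycleRecord(
        S=S,
        I=dose_cumulant(spec),
        mean_x=mean_x,
        delta_x=delta_x,
        h0=spec.h0,
        d=spec.d,
        T=spec.T,
        waveform=spec.waveform,
        eradicated=eradicated,
        converged=traj.converged,
    )


def sweep_grid(
    params: ModelParams,
    waveform: Waveform | str,
    h0_values,
    d_values,
    T: float = 10.0,
    config: SolverConfig | None = None,
) -> ResponseSurface:
    """Run the limit-cycle integration over an (h0 x d) grid.

    Per-cell failures are recorded as unconverged cells with NaN
    observables; the sweep itself never aborts.  The pipeline is fully
    deterministic: identical inputs give identical surfaces.
    """
    waveform = Waveform(waveform)
    h0_values = np.asarray(h0_values, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    if h0_values.size == 0 or d_values.size == 0:
        raise ValidationError("h0_values and d_values must be nonempty")
    if np.any(np.diff(h0_values) <= 0) or np.any(np.diff(d_values) <= 0):
        raise ValidationError("grids must be strictly increasing")
    config = config or SolverConfig()
    if config.x0 is None:
        # resolve once so every cell shares the same initial condition
        config = replace(config, x0=stable_untreated_state(params))

    records: list[list[CycleRecord]] = []
    for h0 in h0_values:
        row = []
        for d in d_values:
            spec = InterventionSpec(waveform=waveform, h0=float(h0), T=T, d=float(d))
            try:
                rec = _cell_record(params, spec, config)
            except IntegrationError:
                rec = CycleRecord(
                    S=float("nan"),
                    I=dose_cumulant(spec),
                    mean_x=float("nan"),
                    delta_x=float("nan"),
                    h0=spec.h0,
                    d=spec.d,
                    T=spec.T,
                    waveform=spec.waveform,
                    eradicated=False,
                    converged=False,
                )
            row.append(rec)
        records.append(row)
    return ResponseSurface(
        h0_grid=h0_values,
        d_grid=d_values,
        records=records,
        waveform=waveform,
        T=T,
        params=params,
    )
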
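"""Dose-cumulant / therapy-effect matrices, data reduction onto a single
curve, and the quadratic dose-effectiveness fit.

Each amplitude row of the response surface yields a series of loop areas
over the duty-cycle grid.  Normalizing the area by amplitude gives the
therapy-effect matrix ``Y = S/h0``; per-row max-normalization of both the
dose cumulant and the effect collapses all rows into the unit square, where
a single two-parameter quadratic ``y = m*x**2 + n*x`` is fitted through the
origin by ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .loop_analytics import CycleRecord
from .model_core import ModelParams, ValidationError, Waveform

__all__ = [
    "ResponseSurface",
    "ReducedPoint",
    "QuadraticFit",
    "CollapseResult",
    "PeakDutyCycle",
    "therapy_effect",
    "peak_duty_cycle",
    "reduce_series",
    "fit_quadratic_through_origin",
    "collapse",
]


@dataclass
class ResponseSurface:
    """Grid of per-cycle observables over (amplitude x duty-cycle)."""

    h0_grid: np.ndarray
    d_grid: np.ndarray
    records: list[list[CycleRecord]]
    waveform: Waveform
    T: float
    params: ModelParams

    def __post_init__(self) -> None:
        self.h0_grid = np.asarray(self.h0_grid, dtype=float)
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.waveform = Waveform(self.waveform)
        if len(self.records) != len(self.h0_grid):
            raise ValidationError("records rows must match h0_grid")
        for i, row in enumerate(self.records):
            if len(row) != len(self.d_grid):
                raise ValidationError(f"row {i} length must match d_grid")
            for j, rec in enumerate(row):
                if not math.isclose(rec.h0, self.h0_grid[i], rel_tol=1e-12, abs_tol=1e-12):
                    raise ValidationError(f"cell ({i},{j}) h0={rec.h0} != grid {self.h0_grid[i]}")
                if not math.isclose(rec.d, self.d_grid[j], rel_tol=1e-12, abs_tol=1e-12):
                    raise ValidationError(f"cell ({i},{j}) d={rec.d} != grid {self.d_grid[j]}")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.h0_grid), len(self.d_grid)

    def matrix(self, attr: str) -> np.ndarray:
        """Cell attribute as a (len(h0_grid), len(d_grid)) float matrix."""
        return np.array([[float(getattr(r, attr)) for r in row] for row in self.records])

    def usable_mask(self) -> np.ndarray:
        """Cells that converged, were not eradicated, and carry finite S."""
        out = np.ones(self.shape, dtype=bool)
        for i, row in enumerate(self.records):
            for j, rec in enumerate(row):
                out[i, j] = rec.converged and not rec.eradicated and math.isfinite(rec.S)
        return out


class ReducedPoint(NamedTuple):
    I_prime: float
    Y_prime: float
    i: int
    j: int


class QuadraticFit(NamedTuple):
    m: float
    n: float
    r_squared: float
    stderr_m: float
    stderr_n: float


class PeakDutyCycle(NamedTuple):
    per_row: list[float]
    consensus: float
    d_range: tuple[float, float]


@dataclass
class CollapseResult:
    """Pooled reduced points and the fitted quadratic dose-effectiveness law."""

    reduced_points: list[ReducedPoint]
    m: float
    n: float
    x_star: float
    y_star: float
    r_squared: float
    stderr_m: float
    stderr_n: float
    n_excluded: int


def therapy_effect(surface: ResponseSurface) -> np.ndarray:
    """Amplitude-normalized loop area Y_ij = S_ij / h0_i (NaN where unusable)."""
    zero_rows = np.flatnonzero(surface.h0_grid == 0)
    if zero_rows.size:
        raise ValidationError(f"therapy effect undefined for h0=0 rows: {zero_rows.tolist()}")
    S = surface.matrix("S")
    Y = S / surface.h0_grid[:, None]
    Y[~surface.usable_mask()] = np.nan
    return Y


def peak_duty_cycle(surface: ResponseSurface) -> PeakDutyCycle:
    """Per-amplitude duty cycle maximizing loop area, and the modal consensus.

    Ties (within each row, and between modal counts) break to the smaller
    duty cycle.  Rows with no usable cell are skipped with a warning.
    """
    if len(surface.d_grid) < 3:
        raise ValidationError("need at least 3 duty-cycle columns")
    S = surface.matrix("S")
    S[~surface.usable_mask()] = np.nan
    per_row: list[float] = []
    for i in range(len(surface.h0_grid)):
        row = S[i]
        if np.all(np.isnan(row)):
            warnings.warn(f"row h0={surface.h0_grid[i]} has no usable cells; skipped")
            continue
        best = np.nanmax(row)
        j = int(np.flatnonzero(row == best)[0])  # ties -> smallest d
        per_row.append(float(surface.d_grid[j]))
    if not per_row:
        raise ValidationError("no usable rows for peak duty-cycle")
    values, counts = np.unique(per_row, return_counts=True)
    consensus = float(values[np.argmax(counts)])  # np.unique sorts -> tie breaks small
    return PeakDutyCycle(per_row=per_row, consensus=consensus, d_range=(min(per_row), max(per_row)))


def reduce_series(
    surface: ResponseSurface, Y: np.ndarray | None = None
) -> tuple[list[ReducedPoint], int]:
    """Per-amplitude max-normalization of dose cumulant and therapy effect.

    Each row i is mapped to I' = I/max_j I, Y' = Y/max_j Y using that row's
    finite cells; rows with fewer than 2 finite cells or a nonpositive
    maximum are excluded (counted, with a warning).  Returns the pooled
    points and the number of excluded cells.
    """
    if Y is None:
        Y = therapy_effect(surface)
    I = surface.matrix("I")
    points: list[ReducedPoint] = []
    n_excluded = 0
    for i in range(len(surface.h0_grid)):
        finite = np.isfinite(Y[i])
        if finite.sum() < 2:
            n_excluded += int(len(surface.d_grid))
            warnings.warn(f"row h0={surface.h0_grid[i]} excluded: fewer than 2 finite cells")
            continue
        I_max = float(np.max(I[i][finite]))
        Y_max = float(np.max(Y[i][finite]))
        if I_max <= 0 or Y_max <= 0:
            n_excluded += int(len(surface.d_grid))
            warnings.warn(f"row h0={surface.h0_grid[i]} excluded: zero row maximum")
            continue
        n_excluded += int((~finite).sum())
        for j in np.flatnonzero(finite):
            points.append(
                ReducedPoint(float(I[i, j] / I_max), float(Y[i, j] / Y_max), i, int(j))
            )
    return points, n_excluded


def fit_quadratic_through_origin(points: Sequence) -> QuadraticFit:
    """Least-squares fit of y = m*x**2 + n*x (no intercept).

    ``points`` is a sequence of (x, y) pairs (extra fields ignored).
    R-squared is computed against the zero (no-intercept) null, and the
    coefficient standard errors from the unbiased residual variance.
    """
    pts = [(float(p[0]), float(p[1])) for p in points]
    if len(pts) < 3:
        raise ValidationError("need at least 3 points to fit")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    X = np.column_stack([x * x, x])
    if np.linalg.matrix_rank(X) < 2:
        raise ValidationError("rank-deficient design: x values do not span a quadratic")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    m, n = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = len(pts) - 2
    sigma2 = ss_res / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return QuadraticFit(m, n, r_squared, float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))


def _vertex_reduce(surface: ResponseSurface, Y: np.ndarray) -> tuple[list[ReducedPoint], int]:
    """Alternative reduction: per-row quadratic fit, then vertex normalization
    x' = -m_i*x/n_i, y' = -m_i*y/n_i**2 (sensitivity analysis only)."""
    I = surface.matrix("I")
    points: list[ReducedPoint] = []
    n_excluded = 0
    for i in range(len(surface.h0_grid)):
        finite = np.isfinite(Y[i])
        if finite.sum() < 3:
            n_excluded += int(len(surface.d_grid))
            continue
        fit = fit_quadratic_through_origin(list(zip(I[i][finite], Y[i][finite])))
        if fit.m >= 0 or fit.n <= 0:
            n_excluded += int(len(surface.d_grid))
            warnings.warn(f"row h0={surface.h0_grid[i]} excluded: no interior vertex")
            continue
        n_excluded += int((~finite).sum())
        for j in np.flatnonzero(finite):
            points.append(
                ReducedPoint(
                    float(-fit.m * I[i, j] / fit.n),
                    float(-fit.m * Y[i, j] / fit.n**2),
                    i,
                    int(j),
                )
            )
    return points, n_excluded


def collapse(
    *surfaces: ResponseSurface,
    reduction: str = "max",
) -> CollapseResult:
    """Reduce one or more response surfaces, pool the points, fit the quadratic.

    ``reduction`` is ``"max"`` (per-row max-normalization, default) or
    ``"vertex"`` (per-row vertex normalization).  The vertex of the pooled
    fit is reported as (x_star, y_star) = (-n/2m, -n^2/4m).
    """
    if not surfaces:
        raise ValidationError("need at least one surface")
    if reduction not in ("max", "vertex"):
        raise ValidationError(f"unknown reduction {reduction!r}")
    points: list[ReducedPoint] = []
    n_excluded = 0
    for surf in surfaces:
        Y = therapy_effect(surf)
        reducer = reduce_series if reduction == "max" else _vertex_reduce
        pts, nx = reducer(surf, Y)
        points.extend(pts)
        n_excluded += nx
    fit = fit_quadratic_through_origin([(p.I_prime, p.Y_prime) for p in points])
    if fit.m != 0:
        x_star = -fit.n / (2.0 * fit.m)
        y_star = -fit.n**2 / (4.0 * fit.m)
    else:
        x_star = y_star = float("nan")
    return CollapseResult(
        reduced_points=points,
        m=fit.m,
        n=fit.n,
        x_star=x_star,
        y_star=y_star,
        r_squared=fit.r_squared,
        stderr_m=fit.stderr_m,
        stderr_n=fit.stderr_n,
        n_excluded=n_excluded,
    )
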
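import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import loopdose as ld
from loopdose.fixtures import make_quadratic_surface
from loopdose.loop_analytics import CycleRecord
from loopdose.scaling_collapse import ResponseSurface

from conftest import D_GRID, H0_GRID


def _surface_from_S(S, h0_grid, d_grid, T=10.0, eradicated=None, converged=None):
    """Hand-build a surface with prescribed loop areas."""
    records = []
    for i, h0 in enumerate(h0_grid):
        row = []
        for j, d in enumerate(d_grid):
            row.append(
                CycleRecord(
                    S=float(S[i][j]),
                    I=float(h0 * d * T),
                    mean_x=1.0,
                    delta_x=0.0,
                    h0=float(h0),
                    d=float(d),
                    T=T,
                    waveform="rectangular",
                    eradicated=bool(eradicated[i][j]) if eradicated is not None else False,
                    converged=bool(converged[i][j]) if converged is not None else True,
                )
            )
        records.append(row)
    return ResponseSurface(
        h0_grid=np.asarray(h0_grid, float),
        d_grid=np.asarray(d_grid, float),
        records=records,
        waveform="rectangular",
        T=T,
        params=ld.ModelParams(),
    )


class TestTherapyEffect:
    def test_definitional(self):
        h0s, ds = [0.5, 1.0], [0.2, 0.5, 0.8]
        S = [[h0 for _ in ds] for h0 in h0s]
        surf = _surface_from_S(S, h0s, ds)
        assert np.allclose(ld.therapy_effect(surf), 1.0)

    def test_eradicated_cell_propagates_as_missing(self):
        h0s, ds = [1.0], [0.2, 0.5, 0.8]
        erad = [[False, True, False]]
        surf = _surface_from_S([[1.0, 2.0, 3.0]], h0s, ds, eradicated=erad)
        Y = ld.therapy_effect(surf)
        assert np.isnan(Y[0, 1]) and np.isfinite(Y[0, 0]) and np.isfinite(Y[0, 2])

    def test_argmax_preserved(self, rect_surface):
        S = rect_surface.matrix("S")
        Y = ld.therapy_effect(rect_surface)
        for i in range(rect_surface.shape[0]):
            assert np.argmax(Y[i]) == np.argmax(S[i])

    def test_zero_amplitude_row_rejected(self):
        surf = _surface_from_S([[0.0, 0.0]], [0.0], [0.3, 0.6])
        with pytest.raises(ld.ValidationError, match="h0=0"):
            ld.therapy_effect(surf)


class TestPeakDutyCycle:
    def test_constructed_peak(self):
        surf = _surface_from_S([[1.0, 3.0, 2.0]], [1.0], [0.2, 0.3, 0.4])
        out = ld.peak_duty_cycle(surf)
        assert out.per_row == [0.3] and out.consensus == 0.3

    def test_tie_breaks_to_smaller_d(self):
        surf = _surface_from_S([[1.0, 3.0, 3.0, 2.0]], [1.0], [0.2, 0.3, 0.4, 0.5])
        assert ld.peak_duty_cycle(surf).per_row == [0.3]

    def test_too_few_columns_rejected(self):
        surf = _surface_from_S([[1.0, 2.0]], [1.0], [0.3, 0.6])
        with pytest.raises(ld.ValidationError):
            ld.peak_duty_cycle(surf)

    def test_all_missing_row_skipped_with_warning(self):
        conv = [[True] * 3, [False] * 3]
        surf = _surface_from_S([[1, 3, 2], [1, 2, 3]], [0.5, 1.0], [0.2, 0.3, 0.4], converged=conv)
        with pytest.warns(UserWarning, match="no usable cells"):
            out = ld.peak_duty_cycle(surf)
        assert out.per_row == [0.3]


class TestReduceSeries:
    def test_max_normalization(self):
        surf = _surface_from_S([[1.0, 2.0, 4.0]], [1.0], [0.25, 0.5, 0.75])
        pts, n_excluded = ld.reduce_series(surf)
        assert n_excluded == 0
        assert [p.Y_prime for p in pts] == pytest.approx([0.25, 0.5, 1.0])
        assert [p.I_prime for p in pts] == pytest.approx([1 / 3, 2 / 3, 1.0])

    @given(k=st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, k):
        S = [[1.0, 2.0, 4.0], [3.0, 6.0, 12.0]]
        surf_a = _surface_from_S(S, [0.5, 1.0], [0.25, 0.5, 0.75])
        S_scaled = [S[0], [k * v for v in S[1]]]
        surf_b = _surface_from_S(S_scaled, [0.5, 1.0], [0.25, 0.5, 0.75])
        pa, _ = ld.reduce_series(surf_a)
        pb, _ = ld.reduce_series(surf_b)
        for a, b in zip(pa, pb):
            assert a.I_prime == pytest.approx(b.I_prime, rel=1e-12)
            assert a.Y_prime == pytest.approx(b.Y_prime, rel=1e-12)

    def test_identical_rows_coincide(self):
        S = [[0.5, 1.0, 2.0], [1.5, 3.0, 6.0]]
        surf = _surface_from_S(S, [0.5, 1.0], [0.25, 0.5, 0.75])
        pts, _ = ld.reduce_series(surf)
        row0 = [(p.I_prime, p.Y_prime) for p in pts if p.i == 0]
        row1 = [(p.I_prime, p.Y_prime) for p in pts if p.i == 1]
        assert row0 == pytest.approx(row1)

    def test_points_in_unit_square(self, rect_surface, halfsine_surface):
        for surf in (rect_surface, halfsine_surface):
            pts, _ = ld.reduce_series(surf)
            for p in pts:
                assert 0.0 <= p.I_prime <= 1.0 and 0.0 <= p.Y_prime <= 1.0

    def test_unique_maximum_per_row(self, rect_surface):
        pts, _ = ld.reduce_series(rect_surface)
        for i in range(rect_surface.shape[0]):
            assert sum(1 for p in pts if p.i == i and p.Y_prime == 1.0) == 1

    def test_zero_row_excluded_with_warning(self):
        surf = _surface_from_S([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]], [0.5, 1.0], [0.25, 0.5, 0.75])
        with pytest.warns(UserWarning, match="zero row maximum"):
            pts, n_excluded = ld.reduce_series(surf)
        assert n_excluded == 3
        assert {p.i for p in pts} == {1}


def _normal_equations_fit(x, y):
    """Independent no-intercept quadratic fit via explicit normal equations."""
    s4, s3, s2 = np.sum(x**4), np.sum(x**3), np.sum(x**2)
    sx2y, sxy = np.sum(x * x * y), np.sum(x * y)
    m, n = np.linalg.solve(np.array([[s4, s3], [s3, s2]]), np.array([sx2y, sxy]))
    return m, n


class TestQuadraticFit:
    def test_exact_interpolation(self):
        x = np.array([0.2, 0.5, 0.8, 1.0])
        y = -2 * x**2 + 1.6 * x
        fit = ld.fit_quadratic_through_origin(list(zip(x, y)))
        assert fit.m == pytest.approx(-2.0, abs=1e-12)
        assert fit.n == pytest.approx(1.6, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_vertex_formulas(self):
        m, n = -2.0, 1.6
        assert -n / (2 * m) == pytest.approx(0.4, abs=1e-15)
        assert -(n**2) / (4 * m) == pytest.approx(0.32, abs=1e-15)

    def test_noisy_recovery_within_two_stderr(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.05, 1.0, 200)
        y = -2 * x**2 + 1.6 * x + rng.normal(0, 0.05, 200)
        fit = ld.fit_quadratic_through_origin(list(zip(x, y)))
        m_ref, n_ref = _normal_equations_fit(x, y)
        assert fit.m == pytest.approx(m_ref, abs=1e-10)
        assert fit.n == pytest.approx(n_ref, abs=1e-10)
        assert abs(fit.m - (-2.0)) < 2 * fit.stderr_m
        assert abs(fit.n - 1.6) < 2 * fit.stderr_n

    def test_rank_deficient_rejected(self):
        with pytest.raises(ld.ValidationError):
            ld.fit_quadratic_through_origin([(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)])

    def test_idempotence(self):
        x = np.array([0.1, 0.3, 0.6, 0.9, 1.0])
        fit = ld.fit_quadratic_through_origin(list(zip(x, -1.3 * x**2 + 1.1 * x + 0.05 * np.cos(9 * x))))
        refit = ld.fit_quadratic_through_origin(list(zip(x, fit.m * x**2 + fit.n * x)))
        assert refit.m == pytest.approx(fit.m, abs=1e-12)
        assert refit.n == pytest.approx(fit.n, abs=1e-12)

    def test_agrees_with_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            npts = rng.integers(4, 30)
            x = rng.uniform(0.01, 2.0, npts)
            y = rng.normal(0, 1.0, npts)
            fit = ld.fit_quadratic_through_origin(list(zip(x, y)))
            m_ref, n_ref = _normal_equations_fit(x, y)
            assert fit.m == pytest.approx(m_ref, rel=1e-8, abs=1e-10)
            assert fit.n == pytest.approx(n_ref, rel=1e-8, abs=1e-10)


class TestCollapse:
    def test_two_identical_synthetic_surfaces(self):
        a, truth = make_quadratic_surface(-1.0, 1.0, H0_GRID, D_GRID)
        b, _ = make_quadratic_surface(-1.0, 1.0, H0_GRID, D_GRID)
        res = ld.collapse(a, b)
        assert res.x_star == pytest.approx(0.5, abs=1e-9)
        assert res.m == pytest.approx(truth["m_true"], abs=1e-9)
        assert res.n == pytest.approx(truth["n_true"], abs=1e-9)

    def test_end_to_end_recovery_exact(self):
        surf, truth = make_quadratic_surface(-1.2, 1.3, [0.2, 0.6, 1.0], [0.2, 0.4, 0.6, 0.8])
        res = ld.collapse(surf)
        assert res.m == pytest.approx(truth["m_true"], abs=1e-6)
        assert res.n == pytest.approx(truth["n_true"], abs=1e-6)
        assert res.x_star == pytest.approx(truth["x_star"], abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_two_stderr(self):
        surf, truth = make_quadratic_surface(-1.0, 1.0, H0_GRID, D_GRID, noise_sigma=0.02, seed=42)
        res = ld.collapse(surf)
        assert abs(res.m - truth["m_true"]) < 2 * res.stderr_m
        assert abs(res.n - truth["n_true"]) < 2 * res.stderr_n

    def test_vertex_identities(self, rect_surface, halfsine_surface):
        res = ld.collapse(halfsine_surface, rect_surface)
        assert res.x_star == pytest.approx(-res.n / (2 * res.m), abs=1e-12)
        assert res.y_star == pytest.approx(res.m * res.x_star**2 + res.n * res.x_star, abs=1e-12)
        assert res.m < 0 < res.n
        assert res.x_star > 0

    def test_leave_one_row_out_stability(self, rect_surface, halfsine_surface):
        full = ld.collapse(halfsine_surface, rect_surface)

        def drop(surface, i):
            keep = [k for k in range(len(surface.h0_grid)) if k != i]
            return ResponseSurface(
                h0_grid=surface.h0_grid[keep],
                d_grid=surface.d_grid,
                records=[surface.records[k] for k in keep],
                waveform=surface.waveform,
                T=surface.T,
                params=surface.params,
            )

        for which in (0, 1):
            surfaces = [halfsine_surface, rect_surface]
            for i in range(len(surfaces[which].h0_grid)):
                trial = list(surfaces)
                trial[which] = drop(trial[which], i)
                res = ld.collapse(*trial)
                assert abs(res.m - full.m) < full.stderr_m
                assert abs(res.n - full.n) < full.stderr_n

    def test_vertex_reduction_variant_runs(self, rect_surface):
        res = ld.collapse(rect_surface, reduction="vertex")
        assert np.isfinite(res.m) and np.isfinite(res.n)

    def test_unknown_reduction_rejected(self, rect_surface):
        with pytest.raises(ld.ValidationError):
            ld.collapse(rect_surface, reduction="median")
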
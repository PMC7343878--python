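"""Fixed-point structure, folds, cusp and hysteresis of the refined model."""

import numpy as np
import pytest

from tipcascade import (
    CuspNotFoundError,
    PoissonEmergentCDF,
    PopulationPartition,
    detect_cusp,
    detect_saddle_node,
    find_equilibria,
    fixed_points_analytic,
    hysteresis_loop,
    min_stable_surface,
    replicate_seed,
    simulate_replicate,
)

PAPER_PARAMS = dict(a=0.16, p=0.67, rho=0.4, K=10.0)


class TestFixedPoints:
    def test_no_contingents_single_point(self):
        fps = fixed_points_analytic(0.3, 0.3, 0.5, 10.0)
        assert fps.points == [(0.3, "stable")]

    def test_zero_a_keeps_zero_fixed_point(self):
        fps = fixed_points_analytic(0.0, 0.8, 0.4, 10.0)
        assert any(abs(r) < 1e-9 for r, _ in fps.points)

    def test_reference_setting_has_three_alternating_points(self):
        fps = fixed_points_analytic(**PAPER_PARAMS)
        assert [s for _, s in fps.points] == ["stable", "unstable", "stable"]
        assert all(0.16 <= r <= 0.67 for r, _ in fps.points)

    def test_agrees_with_count_domain_equilibrium_finder(self):
        rng = np.random.default_rng(77)
        N = 1000
        for _ in range(20):
            A = int(rng.integers(0, 500))
            P = int(rng.integers(A, N + 1))
            rho = float(rng.uniform(0.05, 0.95))
            part = PopulationPartition(N=N, A=A, P=P)
            F = PoissonEmergentCDF(K=10.0, rho=rho)
            fps = fixed_points_analytic(part.a, part.p, rho, 10.0)
            eqs = find_equilibria(F.scaled(N), part)
            assert len(eqs) == len(fps.points)
            for e, (r, s) in zip(sorted(eqs, key=lambda e: e.r_star), fps.points):
                assert e.r_star == pytest.approx(r, abs=1e-5)
                assert e.stability == s

    def test_micro_macro_consistency_at_unique_fixed_points(self):
        # settings with one globally stable fixed point: ensemble-mean final
        # share of the network cascade tracks the analytic equilibrium
        for a, p, rho in [(0.05, 0.56, 0.5), (0.30, 0.67, 0.4)]:
            fps = fixed_points_analytic(a, p, rho, 10.0)
            assert len(fps.stable) == 1
            finals = [
                simulate_replicate(10_000, 10.0, a, p, rho, replicate_seed(13, 0, rep)).r_star
                for rep in range(5)
            ]
            assert np.mean(finals) == pytest.approx(fps.stable[0], abs=0.05)


class TestSaddleNode:
    def test_monotone_branch_has_no_folds(self):
        # p below the cusp: one stable fixed point throughout the a-scan
        folds = detect_saddle_node("a", (0.01, 0.29), {"p": 0.3, "rho": 0.4, "K": 10.0},
                                   steps=31)
        assert folds == []

    def test_fold_pair_brackets_bistable_window(self):
        fixed = {"p": 0.67, "rho": 0.4, "K": 10.0}
        folds = detect_saddle_node("a", (0.01, 0.6), fixed, steps=121)
        assert len(folds) == 2
        lo, hi = folds
        inside = fixed_points_analytic(0.5 * (lo + hi), 0.67, 0.4, 10.0)
        assert len(inside.stable) == 2
        below = fixed_points_analytic(lo - 0.02, 0.67, 0.4, 10.0)
        above = fixed_points_analytic(hi + 0.02, 0.67, 0.4, 10.0)
        assert len(below.stable) == 1
        assert len(above.stable) == 1

    def test_lower_branch_fold_in_reported_window(self):
        folds = detect_saddle_node("a", (0.01, 0.6), {"p": 0.67, "rho": 0.4, "K": 10.0},
                                   steps=121)
        assert 0.15 <= folds[-1] <= 0.22  # where min(r*) jumps sharply

    def test_fold_exists_in_threshold_fraction(self):
        folds = detect_saddle_node("rho", (0.05, 0.95), {"a": 0.16, "p": 0.67, "K": 10.0},
                                   steps=61)
        assert len(folds) >= 1


class TestSurfaceAndCusp:
    def test_diagonal_cells_equal_a(self):
        a_grid = np.array([0.1, 0.3])
        surface = min_stable_surface(a_grid, a_grid, rho=0.4, K=10.0, grid_points=501)
        assert surface[0, 0] == pytest.approx(0.1)
        assert surface[1, 1] == pytest.approx(0.3)
        assert np.isnan(surface[0, 1])  # a > p masked

    def test_jump_row_and_smooth_row(self):
        a_grid = np.linspace(0.10, 0.30, 41)
        rows = {
            p: min_stable_surface(a_grid, [p], rho=0.4, K=10.0, grid_points=2001)[0]
            for p in (0.58, 0.67)
        }
        assert np.max(np.diff(rows[0.67])) > 0.2  # sharp increase
        assert np.max(np.diff(rows[0.58])) < 0.05  # smooth below the cusp
        jump_at = a_grid[np.argmax(np.diff(rows[0.67]))]
        assert 0.15 <= jump_at <= 0.22

    def test_min_stable_monotone_in_a_p_and_rho(self):
        a_grid = np.linspace(0.05, 0.35, 7)
        p_grid = np.linspace(0.5, 0.9, 5)
        s1 = min_stable_surface(a_grid, p_grid, rho=0.4, K=10.0, grid_points=1001)
        assert np.all(np.diff(s1, axis=1) >= -1e-6)  # nondecreasing in a
        assert np.all(np.diff(s1, axis=0) >= -1e-6)  # nondecreasing in p
        s2 = min_stable_surface(a_grid, p_grid, rho=0.6, K=10.0, grid_points=1001)
        assert np.all(s2 <= s1 + 1e-6)  # nonincreasing in rho

    def test_cusp_exists_at_moderate_threshold(self):
        cusp = detect_cusp(np.linspace(0.45, 0.95, 11), rho=0.4, K=10.0)
        assert cusp.p_c < 0.67  # bistable at p=0.67, smooth at p=0.58
        assert cusp.p_c > 0.45
        assert 0.0 < cusp.a_c < cusp.p_c

    def test_no_cusp_when_thresholds_too_hard(self):
        with pytest.raises(CuspNotFoundError):
            detect_cusp([0.3, 0.6, 0.9], rho=0.95, K=10.0)

    def test_degenerate_grid_below_fold_region(self):
        with pytest.raises(CuspNotFoundError):
            detect_cusp([0.1, 0.2], rho=0.4, K=10.0)


class TestHysteresis:
    def test_unique_branch_no_loop(self):
        loop = hysteresis_loop("a", (0.01, 0.3),
                               fixed_params={"p": 0.56, "rho": 0.8, "K": 10.0}, steps=31)
        assert loop.loop_area == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(
            loop.up["r_star"], loop.down.iloc[::-1]["r_star"], atol=1e-6
        )

    def test_bistable_sweep_in_a_encloses_area(self):
        loop = hysteresis_loop("a", (0.02, 0.4),
                               fixed_params={"p": 0.67, "rho": 0.4, "K": 10.0}, steps=61)
        assert loop.loop_area > 0.01
        gap = loop.up["r_star"].to_numpy() - loop.down.iloc[::-1]["r_star"].to_numpy()
        assert np.min(gap) < -0.1  # up-sweep stays low where down-sweep is high

    def test_hysteresis_in_threshold_fraction_band(self):
        loop = hysteresis_loop("rho", (0.2, 0.8),
                               fixed_params={"a": 0.16, "p": 0.67, "K": 10.0}, steps=61)
        assert loop.loop_area > 0.01
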
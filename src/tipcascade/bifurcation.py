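"""Fixed-point structure of the refined model with the analytic emergent F.

Fixed points solve ``r = a + c * F(r)`` (equivalently ``(r - a)/c = F(r)``,
the diagonal through (a, 0) and (p, 1) intersecting F) with F the
Poisson-limit emergent threshold distribution.  Depending on (a, p, rho, K)
there is either one globally stable fixed point or two stable ones separated
by an unstable one; the boundaries of the bistable region are saddle-node
(fold) bifurcations, they meet at a cusp in the (a, p) plane, and sweeping a
parameter across the folds produces hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .emergent import F_gamma
from .errors import CuspNotFoundError, ParameterError
from .granovetter import SEMISTABLE, STABLE, UNSTABLE

#: Minimum separation (in r) of two stable fixed points to count as bistable;
#: guards against grid noise near the cusp creating spurious folds.
BISTABLE_MIN_SEP = 1e-4


@dataclass
class FixedPointSet:
    """All fixed points of r = a + c*F(r) at one parameter setting."""

    a: float
    p: float
    rho: float
    K: float
    points: list[tuple[float, str]]  # (r_star, stability), sorted by r_star

    @property
    def stable(self) -> list[float]:
        return [r for r, s in self.points if s == STABLE]

    @property
    def unstable(self) -> list[float]:
        return [r for r, s in self.points if s == UNSTABLE]

    @property
    def min_stable(self) -> float | None:
        return min(self.stable) if self.stable else None

    @property
    def max_stable(self) -> float | None:
        return max(self.stable) if self.stable else None

    def is_bistable(self, min_sep: float = BISTABLE_MIN_SEP) -> bool:
        s = self.stable
        return len(s) >= 2 and (max(s) - min(s)) > min_sep


@dataclass(frozen=True)
class CuspPoint:
    """Parameter point where the bistable a-window collapses to zero width."""

    a_c: float
    p_c: float
    rho: float
    K: float


@dataclass
class BifurcationDiagram:
    """Fixed-point branches along one scanned parameter."""

    scan_param: str
    fixed_params: dict
    branches: pd.DataFrame  # columns: scan_value, r_star, stability, feasible
    folds: list[float]

    def to_csv(self, path: str | Path) -> None:
        self.branches.to_csv(path, index=False)


def _check_params(a: float, p: float, rho: float, K: float) -> None:
    if not (0.0 <= a <= p <= 1.0):
        raise ParameterError(f"need 0 <= a <= p <= 1, got a={a}, p={p}")
    if not (0.0 <= rho <= 1.0):
        raise ParameterError(f"rho must lie in [0, 1], got {rho}")
    if K <= 0:
        raise ParameterError(f"mean degree must be positive, got K={K}")


def fixed_points_analytic(
    a: float, p: float, rho: float, K: float, grid_points: int = 10_001
) -> FixedPointSet:
    """All roots of ``h(r) = a + c*F(r) - r`` on [a, p] with stability labels.

    Dense grid scan plus bisection on sign changes; stability follows the
    crossing rule (h > 0 left of the root and h < 0 right of it means the map
    crosses the diagonal from above: stable).  With c = 0 the single fixed
    point r* = a is returned directly.
    """
    _check_params(a, p, rho, K)
    c = p - a
    if c == 0.0:
        return FixedPointSet(a, p, rho, K, [(a, STABLE)])

    grid = np.linspace(a, p, grid_points)
    Fv = F_gamma(grid, K, rho)
    hv = a + c * Fv - grid

    def h(r: float) -> float:
        return a + c * F_gamma(r, K, rho) - r

    span = p - a
    xtol = max(1e-12, 1e-10 * span)
    ztol = 1e-12

    roots: list[float] = [float(g) for g, v in zip(grid, hv) if abs(v) < ztol]
    for i in range(grid_points - 1):
        if hv[i] * hv[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=xtol))

    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 2 * span / (grid_points - 1):
            merged.append(r)

    delta = span / (grid_points - 1)
    points: list[tuple[float, str]] = []
    for r in merged:
        left = h(r - delta) if r - delta >= a else None
        right = h(r + delta) if r + delta <= p else None
        if left is None and right is None:
            lab = STABLE
        elif left is None:
            lab = STABLE if right < 0 else UNSTABLE
        elif right is None:
            lab = STABLE if left > 0 else UNSTABLE
        elif left > 0 and right < 0:
            lab = STABLE
        elif left < 0 and right > 0:
            lab = UNSTABLE
        else:
            lab = SEMISTABLE
        points.append((r, lab))
    return FixedPointSet(a, p, rho, K, points)


def min_stable_surface(a_grid, p_grid, rho: float, K: float, grid_points: int = 4_001):
    """Smallest stable fixed point per (a, p) cell; NaN where a > p.

    Returns an array of shape ``(len(p_grid), len(a_grid))`` (rows index p).
    """
    a_grid = np.atleast_1d(np.asarray(a_grid, dtype=float))
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    surface = np.full((p_grid.size, a_grid.size), np.nan)
    for i, p in enumerate(p_grid):
        for j, a in enumerate(a_grid):
            if a > p:
                continue
            fps = fixed_points_analytic(a, p, rho, K, grid_points=grid_points)
            ms = fps.min_stable
            surface[i, j] = np.nan if ms is None else ms
    return surface


def _stable_count(scan_param: str, value: float, fixed: dict, grid_points: int) -> int:
    params = dict(fixed)
    params[scan_param] = value
    fps = fixed_points_analytic(
        params["a"], params["p"], params["rho"], params["K"], grid_points=grid_points
    )
    return len(fps.stable)


def detect_saddle_node(
    scan_param: str,
    scan_range: tuple[float, float],
    fixed_params: dict,
    steps: int = 201,
    xtol: float = 1e-4,
    grid_points: int = 4_001,
) -> list[float]:
    """Fold (saddle-node) locations along one scanned parameter.

    Scans ``scan_param`` (one of 'a', 'p', 'rho') over ``scan_range``, finds
    where the number of stable fixed points changes and refines each change
    point by bisection to ``xtol``.  Returns an empty list when the stable
    count is constant (no fold).
    """
    if scan_param not in ("a", "p", "rho"):
        raise ParameterError(f"scan parameter must be one of a, p, rho, got {scan_param!r}")
    lo, hi = float(scan_range[0]), float(scan_range[1])
    values = np.linspace(lo, hi, steps)
    counts = [_stable_count(scan_param, v, fixed_params, grid_points) for v in values]

    folds: list[float] = []
    for i in range(steps - 1):
        if counts[i] != counts[i + 1]:
            vlo, vhi, clo = values[i], values[i + 1], counts[i]
            while vhi - vlo > xtol:
                mid = 0.5 * (vlo + vhi)
                if _stable_count(scan_param, mid, fixed_params, grid_points) == clo:
                    vlo = mid
                else:
                    vhi = mid
            folds.append(0.5 * (vlo + vhi))
    return folds


def bifurcation_diagram(
    scan_param: str,
    scan_range: tuple[float, float],
    fixed_params: dict,
    steps: int = 201,
    grid_points: int = 4_001,
) -> BifurcationDiagram:
    """Tidy stable/unstable branches plus fold locations along one parameter."""
    values = np.linspace(scan_range[0], scan_range[1], steps)
    rows = []
    for v in values:
        params = dict(fixed_params)
        params[scan_param] = v
        fps = fixed_points_analytic(
            params["a"], params["p"], params["rho"], params["K"], grid_points=grid_points
        )
        for r, s in fps.points:
            rows.append(
                {
                    "scan_value": v,
                    "r_star": r,
                    "stability": s,
                    "feasible": params["a"] <= r <= params["p"],
                }
            )
    folds = detect_saddle_node(
        scan_param, scan_range, fixed_params, steps=steps, grid_points=grid_points
    )
    return BifurcationDiagram(
        scan_param=scan_param,
        fixed_params=dict(fixed_params),
        branches=pd.DataFrame(rows),
        folds=folds,
    )


def detect_cusp(
    p_grid,
    rho: float,
    K: float,
    a_steps: int = 101,
    xtol: float = 1e-3,
    grid_points: int = 2_001,
) -> CuspPoint:
    """Locate the cusp: the smallest p at which a bistable a-window opens.

    For each p in the (ascending) grid the fold locations over a are
    computed; the cusp is bracketed between the largest p without a bistable
    window (two folds separated by more than ``BISTABLE_MIN_SEP``) and the
    smallest p with one, then refined by bisection.  ``a_c`` is the centre of
    the collapsing window.  Raises :class:`CuspNotFoundError` when no p in
    the grid is bistable.
    """
    p_grid = np.sort(np.atleast_1d(np.asarray(p_grid, dtype=float)))

    def window(p: float) -> tuple[float, float] | None:
        folds = detect_saddle_node(
            "a", (1e-3, p - 1e-3), {"p": p, "rho": rho, "K": K},
            steps=a_steps, xtol=xtol / 10, grid_points=grid_points,
        )
        if len(folds) >= 2 and folds[-1] - folds[0] > BISTABLE_MIN_SEP:
            return folds[0], folds[-1]
        return None

    prev_p, found_p, found_win = None, None, None
    for p in p_grid:
        win = window(p)
        if win is not None:
            found_p, found_win = p, win
            break
        prev_p = p
    if found_p is None:
        raise CuspNotFoundError(f"no bistable window for any p in the grid at rho={rho}, K={K}")
    if prev_p is None:
        # bistable already at the grid's smallest p; report that edge
        return CuspPoint(a_c=0.5 * sum(found_win), p_c=float(found_p), rho=rho, K=K)

    lo, hi, hi_win = prev_p, found_p, found_win
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        win = window(mid)
        if win is None:
            lo = mid
        else:
            hi, hi_win = mid, win
    return CuspPoint(a_c=0.5 * (hi_win[0] + hi_win[1]), p_c=0.5 * (lo + hi), rho=rho, K=K)


@dataclass
class HysteresisLoop:
    """Forward and backward adiabatic sweeps and the area they enclose."""

    scan_param: str
    up: pd.DataFrame  # columns: scan_value, r_star
    down: pd.DataFrame
    loop_area: float


def _relax(r0: float, a: float, p: float, rho: float, K: float, tol: float = 1e-10) -> float:
    """Iterate r -> a + c*F(r) from r0 to its attracting fixed point."""
    c = p - a
    r = min(max(r0, a), p)
    for _ in range(100_000):
        r_next = a + c * F_gamma(r, K, rho)
        if abs(r_next - r) < tol:
            return r_next
        r = r_next
    return r


def hysteresis_loop(
    scan_param: str,
    up_range: tuple[float, float],
    down_range: tuple[float, float] | None = None,
    fixed_params: dict | None = None,
    steps: int = 101,
) -> HysteresisLoop:
    """Adiabatic forward/backward parameter sweeps revealing hysteresis.

    The forward sweep starts from the state the low branch relaxes to at the
    first parameter value and, at each subsequent value, relaxes the previous
    equilibrium under the new map — exactly the quasi-static dynamics of a
    slowly drifting parameter.  The backward sweep does the same from the
    other end (seeded at the high branch).  In a bistable window the two
    traces differ; the enclosed area is the integral of their gap.
    """
    if scan_param not in ("a", "p", "rho"):
        raise ParameterError(f"scan parameter must be one of a, p, rho, got {scan_param!r}")
    fixed_params = dict(fixed_params or {})
    down_range = (up_range[1], up_range[0]) if down_range is None else down_range

    def sweep(values: np.ndarray, seed_low: bool) -> pd.DataFrame:
        rows = []
        r_prev = None
        for v in values:
            params = dict(fixed_params)
            params[scan_param] = v
            a, p, rho, K = params["a"], params["p"], params["rho"], params["K"]
            if r_prev is None:
                r_prev = a if seed_low else p
            r_star = _relax(r_prev, a, p, rho, K)
            rows.append({"scan_value": v, "r_star": r_star})
            r_prev = r_star
        return pd.DataFrame(rows)

    up = sweep(np.linspace(up_range[0], up_range[1], steps), seed_low=True)
    down = sweep(np.linspace(down_range[0], down_range[1], steps), seed_low=False)

    # area between traces on the common parameter axis
    down_sorted = down.sort_values("scan_value")
    gap = np.abs(
        up["r_star"].to_numpy()
        - np.interp(up["scan_value"], down_sorted["scan_value"], down_sorted["r_star"])
    )
    loop_area = float(np.trapezoid(gap, up["scan_value"].to_numpy()))
    return HysteresisLoop(scan_param=scan_param, up=up, down=down, loop_area=loop_area)
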
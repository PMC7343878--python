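"""Macroscopic threshold recursions, equilibria and the classic Gaussian experiment.

The original recursion ``R(t+1) = N * F(R(t))`` maps the current number of
active individuals through the cumulative threshold distribution ``F``.  The
refined recursion ``R(t+1) = A + C * F(R(t))`` restricts dynamics to the
``[A, P]`` interval set by the certainly acting (``A``) and potentially acting
(``P = A + C``) group sizes, producing non-trivial equilibria.  Equilibria are
intersections of the map with the diagonal; those crossed from above are
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import NoFullCascadeError, ParameterError
from .partition import PopulationPartition
from .thresholds import CDFLike, GaussianThresholdCDF, validate_cdf

STABLE = "stable"
UNSTABLE = "unstable"
SEMISTABLE = "semistable"


@dataclass
class RecursionTrajectory:
    """Iterates ``R(0), R(1), ...`` of a macroscopic recursion.

    ``converged`` is True when the last step moved by less than the fixed-point
    tolerance, in which case the final two entries agree to that tolerance.
    """

    R: np.ndarray
    converged: bool

    @property
    def t_max(self) -> int:
        return len(self.R) - 1

    @property
    def final(self) -> float:
        return float(self.R[-1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": np.arange(len(self.R)), "R": self.R}).to_csv(path, index=False)


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of a threshold recursion with its stability label."""

    R_star: float
    r_star: float
    stability: str


def _iterate(map_fn, R0: float, tol: float, max_steps: int) -> RecursionTrajectory:
    R = [float(R0)]
    converged = False
    for _ in range(max_steps):
        R_next = float(map_fn(R[-1]))
        R.append(R_next)
        if abs(R_next - R[-2]) < tol:
            converged = True
            break
    return RecursionTrajectory(R=np.array(R), converged=converged)


def iterate_original(
    F: CDFLike,
    R0: float,
    N: float,
    max_steps: int = 100_000,
    tol: float | None = None,
) -> RecursionTrajectory:
    """Iterate the original recursion ``R(t+1) = N * F(R(t))`` from ``R0``.

    Stops once ``|R(t+1) - R(t)| < tol`` (default ``1e-6 * N``) or after
    ``max_steps`` updates.  ``F`` must be a valid CDF on ``[0, N]``.
    """
    if not (0 <= R0 <= N):
        raise ParameterError(f"R0 must lie in [0, N], got {R0}")
    validate_cdf(F, 0.0, N)
    tol = 1e-6 * N if tol is None else tol
    return _iterate(lambda R: N * float(F(R)), R0, tol, max_steps)


def iterate_refined(
    F: CDFLike,
    part: PopulationPartition,
    R0: float | None = None,
    max_steps: int = 100_000,
    tol: float | None = None,
) -> RecursionTrajectory:
    """Iterate the refined recursion ``R(t+1) = A + C * F(R(t))``.

    ``R0`` defaults to ``A`` (only the certainly acting are active at t=0);
    all iterates lie in ``[A, P]`` because ``F`` maps into [0, 1].  With
    ``A = 0`` and ``C = N`` this reduces exactly to :func:`iterate_original`.
    """
    A, C, N = part.A, part.C, part.N
    R0 = float(A) if R0 is None else float(R0)
    validate_cdf(F, 0.0, N)
    tol = 1e-6 * N if tol is None else tol
    return _iterate(lambda R: A + C * float(F(R)), R0, tol, max_steps)


def _classify(g, lo: float, hi: float, root: float, delta: float) -> str:
    """Stability from the crossing direction of g(R) = map(R) - R at a root."""
    left = g(root - delta) if root - delta >= lo else None
    right = g(root + delta) if root + delta <= hi else None
    if left is None and right is None:
        return STABLE
    if left is None:  # root at the lower boundary A: attracting iff map pulls down
        return STABLE if right < 0 else UNSTABLE
    if right is None:  # root at the upper boundary P
        return STABLE if left > 0 else UNSTABLE
    if left > 0 and right < 0:
        return STABLE
    if left < 0 and right > 0:
        return UNSTABLE
    return SEMISTABLE


def find_equilibria(
    F: CDFLike,
    part: PopulationPartition,
    grid_points: int = 10_001,
    rtol: float = 1e-8,
) -> list[Equilibrium]:
    """All fixed points of ``R = A + C * F(R)`` on ``[A, P]`` with stability.

    Roots of ``g(R) = A + C*F(R) - R`` are bracketed on a dense grid and
    refined by bisection; ``F`` may be flat over wide ranges, so no
    derivative-based steps are used.  Stability follows the graphical rule:
    the map crossing the diagonal from above (g > 0 on the left, g < 0 on the
    right) is stable; tangencies are labelled semistable.
    """
    A, C, N, P = part.A, part.C, part.N, part.P
    validate_cdf(F, 0.0, N)
    if C == 0:
        return [Equilibrium(R_star=float(A), r_star=A / N, stability=STABLE)]

    def g(R: float) -> float:
        return A + C * float(F(R)) - R

    lo, hi = float(A), float(P)
    grid = np.linspace(lo, hi, grid_points)
    gv = A + C * np.asarray(F(grid), dtype=float) - grid
    span = hi - lo
    xtol = max(rtol * span, 1e-14)
    ztol = 1e-9 * N

    roots: list[float] = []
    for i in range(grid_points - 1):
        g0, g1 = gv[i], gv[i + 1]
        if abs(g0) < ztol:
            roots.append(grid[i])
        elif g0 * g1 < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=xtol))
    if abs(gv[-1]) < ztol:
        roots.append(grid[-1])

    # dedupe near-identical roots (flat F can yield whole fixed intervals)
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 2 * span / (grid_points - 1):
            merged.append(r)

    delta = span / (grid_points - 1)
    return [
        Equilibrium(R_star=r, r_star=r / N, stability=_classify(g, lo, hi, r, delta))
        for r in merged
    ]


def equilibria_to_csv(equilibria: list[Equilibrium], path: str | Path) -> None:
    pd.DataFrame(
        {
            "R_star": [e.R_star for e in equilibria],
            "r_star": [e.r_star for e in equilibria],
            "stability": [e.stability for e in equilibria],
        }
    ).to_csv(path, index=False)


def critical_sigma(
    N: int,
    mu: float,
    R0: float = 1.0,
    resolution: float = 0.1,
    sigma_max: float | None = None,
    max_steps: int = 1_000_000,
) -> float:
    """Critical Gaussian threshold spread for a full cascade from ``R0``.

    With cut-off Gaussian thresholds ``F(R) = Phi((R - mu)/sigma)`` the
    original recursion started at a handful of instigators either stalls at a
    low fixed point or, for sigma beyond a tangency of ``N*F`` with the
    diagonal, runs to (almost) the whole population.  This locates that
    critical sigma by bisection on the full-cascade predicate (equilibrium
    ``>= N - 1``) and reports it rounded to ``resolution``.

    If even ``sigma = resolution`` cascades (e.g. ``mu`` near 0) the smallest
    probed value ``resolution`` is returned.  If no sigma up to ``sigma_max``
    (default ``5 * N``) cascades, :class:`NoFullCascadeError` is raised.
    """
    if not (0 < mu < N):
        raise ParameterError(f"mu must lie in (0, N), got {mu}")
    if R0 < 1:
        raise ParameterError(f"need at least one instigator, got R0={R0}")
    sigma_max = 5.0 * N if sigma_max is None else sigma_max

    def full_cascade(sigma: float) -> bool:
        F = GaussianThresholdCDF(mu=mu, sigma=sigma, N=N)
        traj = iterate_original(F, R0=R0, N=N, max_steps=max_steps)
        return traj.final >= N - 1

    lo = resolution
    if full_cascade(lo):
        return lo
    hi = 2 * lo
    while not full_cascade(hi):
        lo = hi
        hi *= 2
        if hi > sigma_max:
            raise NoFullCascadeError(
                f"no sigma <= {sigma_max} yields a full cascade from R0={R0}"
            )
    while hi - lo > resolution / 100:
        mid = 0.5 * (lo + hi)
        if full_cascade(mid):
            hi = mid
        else:
            lo = mid
    return round(round(0.5 * (lo + hi) / resolution) * resolution, 10)
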
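"""Emergent threshold distribution of the network cascade.

A contingent node with ``a_i`` active and ``b_i`` inactive neighbours
activates when ``a_i > rho * (a_i + b_i)``, i.e. ``a_i > rho * b_i / (1 - rho)``
for rho < 1.  On an ER network with the global active count R, the neighbour
counts are independent binomials ``a_i ~ Bin(R, l)`` and ``b_i ~ Bin(P', l)``
with ``P' = N - 1 - R`` (one's own state is not counted), giving the exact
emergent threshold CDF :func:`F_exact`.  For N >> K with K = l*(N-1) held
fixed the binomials become Poissons with rates ``K*r`` and ``K - K*r``,
giving the analytic approximation :func:`F_poisson`; the inner truncated
Poisson sum equals a regularised upper incomplete gamma function, which
:func:`F_gamma` uses directly.

All forms share ``F(0) = 0`` (no active neighbours can exist) and
``F(1) = 1 - exp(-K)`` in the Poisson limit — the deficit is the mass of
isolated nodes, which can never observe an active neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaincc, gammaln
from scipy.stats import binom, poisson

from .cascade import CascadeTrajectory
from .errors import ParameterError, UndefinedCurveError
from .partition import PopulationPartition
from .thresholds import ThresholdCDF

#: Poisson tail mass at which the outer sum over b_i is truncated.
TAIL_MASS = 1e-12


def _check_rho(rho: float) -> None:
    if not (0.0 <= rho <= 1.0):
        raise ParameterError(f"rho must lie in [0, 1], got {rho}")


def _inner_limits(b: np.ndarray, rho: float) -> np.ndarray:
    """Largest non-activating a_i for each b_i: floor(rho*b/(1-rho)).

    The activation inequality is strict, so an exactly-integer
    ``rho*b/(1-rho)`` still does not activate and is included in the
    non-activation sum.  Tiny float noise is swept off before flooring so
    e.g. rho=0.5, b=3 yields exactly 3.
    """
    x = rho * b / (1.0 - rho)
    return np.floor(x + 1e-9).astype(np.int64)


def _b_cutoff(lam: float) -> int:
    """b beyond which the Poisson(lam) tail is below TAIL_MASS."""
    if lam <= 0:
        return 1
    return int(poisson.isf(TAIL_MASS / 10, lam)) + 2


def F_poisson(r, K: float, rho: float):
    """Poisson-limit emergent threshold CDF at active share(s) ``r``.

    Evaluates the truncated double sum
    ``F(r) = 1 - exp(-K) * sum_b ((K - K r)^b / b!) * sum_{a=0}^{floor(rho b/(1-rho))} (K r)^a / a!``
    with the outer sum cut where the Poisson(K - K r) tail falls below 1e-12.
    Vectorised over ``r``.
    """
    _check_rho(rho)
    if K <= 0:
        raise ParameterError(f"mean degree must be positive, got K={K}")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise ParameterError("active share r must lie in [0, 1]")
    if rho >= 1.0:
        out = np.zeros_like(r_arr)
        return float(out[0]) if np.ndim(r) == 0 else out

    b = np.arange(_b_cutoff(K) + 1)  # lam_b <= K, so one cutoff serves all r
    m = _inner_limits(b, rho)

    lam_b = K * (1.0 - r_arr)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pow = b[None, :] * np.log(lam_b)
    log_pow = np.where((b[None, :] == 0) & (lam_b == 0), 0.0, log_pow)
    log_pow = np.where((b[None, :] > 0) & (lam_b == 0), -np.inf, log_pow)
    weight_b = np.exp(log_pow - gammaln(b + 1)[None, :])  # (K-Kr)^b / b!

    # inner sum: cumulative (Kr)^a / a! up to m(b), shared across b via cumsum
    lam_a = K * r_arr
    a_cut = min(int(m.max()), _b_cutoff(K))
    a = np.arange(a_cut + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pow_a = a[None, :] * np.log(lam_a[:, None])
    log_pow_a = np.where((a[None, :] == 0) & (lam_a[:, None] == 0), 0.0, log_pow_a)
    log_pow_a = np.where((a[None, :] > 0) & (lam_a[:, None] == 0), -np.inf, log_pow_a)
    terms_a = np.exp(log_pow_a - gammaln(a + 1)[None, :])
    cum_a = np.cumsum(terms_a, axis=1)  # sum_{a'=0}^{a} (Kr)^a'/a'!
    inner = cum_a[:, np.minimum(m, a_cut)]  # (n_r, n_b)

    out = 1.0 - np.exp(-K) * np.sum(weight_b * inner, axis=1)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.ndim(r) == 0 else out


def F_gamma(r, K: float, rho: float):
    """Incomplete-gamma form of :func:`F_poisson`.

    The inner truncated exponential sum equals
    ``exp(K r) * Q(m + 1, K r)`` with ``Q`` the regularised upper incomplete
    gamma function (the Poisson CDF identity), so this agrees with
    :func:`F_poisson` to numerical precision.
    """
    _check_rho(rho)
    if K <= 0:
        raise ParameterError(f"mean degree must be positive, got K={K}")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise ParameterError("active share r must lie in [0, 1]")
    if rho >= 1.0:
        out = np.zeros_like(r_arr)
        return float(out[0]) if np.ndim(r) == 0 else out

    b = np.arange(_b_cutoff(K) + 1)
    m = _inner_limits(b, rho)
    lam_b = K * (1.0 - r_arr)[:, None]
    lam_a = K * r_arr

    # Poisson(lam_b) pmf and Poisson(lam_a) CDF at m, both via gamma functions
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pmf = b[None, :] * np.log(lam_b) - lam_b - gammaln(b + 1)[None, :]
    log_pmf = np.where((b[None, :] == 0) & (lam_b == 0), 0.0, log_pmf)
    log_pmf = np.where((b[None, :] > 0) & (lam_b == 0), -np.inf, log_pmf)
    pmf_b = np.exp(log_pmf)
    cdf_a = gammaincc(m[None, :] + 1, lam_a[:, None])  # P(Pois(lam_a) <= m)

    out = 1.0 - np.sum(pmf_b * cdf_a, axis=1)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.ndim(r) == 0 else out


def F_exact(R, N: int, link_prob: float, rho: float):
    """Exact binomial emergent threshold CDF at active count(s) ``R``.

    Probability that independent ``a_i ~ Bin(R, l)`` and ``b_i ~ Bin(P', l)``
    with ``P' = N - 1 - R`` satisfy the strict activation condition
    ``a_i > rho * (a_i + b_i)``.  Computed through the complement
    (non-activation) event, summing the b_i binomial pmf against the a_i
    binomial CDF at ``floor(rho * b_i / (1 - rho))``; scipy's binomial
    routines keep this stable up to N ~ 1e5.
    """
    _check_rho(rho)
    if not (0 < link_prob <= 1):
        raise ParameterError(f"linking probability must lie in (0, 1], got {link_prob}")
    R_arr = np.atleast_1d(np.asarray(R))
    if np.any((R_arr < 0) | (R_arr > N - 1)):
        raise ParameterError("active count R must lie in [0, N-1]")

    out = np.empty(R_arr.shape, dtype=float)
    for i, R_i in enumerate(R_arr):
        R_i = int(R_i)
        P_prime = N - 1 - R_i
        if rho >= 1.0 or R_i == 0:
            out[i] = 0.0
            continue
        b_hi = min(P_prime, int(binom.isf(TAIL_MASS / 10, P_prime, link_prob)) + 2) if P_prime else 0
        b = np.arange(b_hi + 1)
        m = _inner_limits(b, rho)
        pmf_b = binom.pmf(b, P_prime, link_prob) if P_prime else np.array([1.0])
        cdf_a = binom.cdf(np.minimum(m, R_i), R_i, link_prob)
        out[i] = 1.0 - float(np.sum(pmf_b * cdf_a))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.ndim(R) == 0 else out


class PoissonEmergentCDF(ThresholdCDF):
    """Analytic emergent threshold distribution (Poisson limit) on r in [0, 1]."""

    kind = "analytic-poisson"

    def __init__(self, K: float, rho: float):
        _check_rho(rho)
        if K <= 0:
            raise ParameterError(f"mean degree must be positive, got K={K}")
        self.K, self.rho = float(K), float(rho)
        self.domain_low, self.domain_high = 0.0, 1.0

    def _evaluate(self, x):
        return np.atleast_1d(F_gamma(np.clip(x, 0.0, 1.0), self.K, self.rho))


class ExactEmergentCDF(ThresholdCDF):
    """Exact binomial emergent threshold distribution on counts R in [0, N-1]."""

    kind = "analytic-exact"

    def __init__(self, N: int, link_prob: float, rho: float):
        self.N, self.link_prob, self.rho = int(N), float(link_prob), float(rho)
        self.domain_low, self.domain_high = 0.0, float(N - 1)

    def _evaluate(self, x):
        R = np.clip(np.round(x).astype(int), 0, self.N - 1)
        return np.atleast_1d(F_exact(R, self.N, self.link_prob, self.rho))


@dataclass
class EmergentThresholdCurve:
    """Sampled threshold curve or scatter: r values against F values."""

    r: np.ndarray
    F: np.ndarray
    method: str
    params: dict

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"r": self.r, "F": self.F})
        df["method"] = self.method
        for key, val in self.params.items():
            df[key] = val
        df.to_csv(path, index=False)


def analytic_curve(K: float, rho: float, grid_points: int = 201, method: str = "gamma") -> EmergentThresholdCurve:
    """Tabulate an analytic emergent threshold curve on a uniform r grid."""
    r = np.linspace(0.0, 1.0, grid_points)
    fn = {"poisson": F_poisson, "gamma": F_gamma}[method]
    return EmergentThresholdCurve(r=r, F=fn(r, K, rho), method=method, params={"K": K, "rho": rho})


def empirical_threshold_curve(
    traj: CascadeTrajectory,
    part: PopulationPartition,
    near_equilibrium_only: bool = True,
) -> EmergentThresholdCurve:
    """Read the emergent threshold distribution off a cascade trajectory.

    Each step yields a point ``(r(t), (r(t+1) - a) / c)``: inverting the
    refined recursion, the ordinate estimates ``F(r(t))``.  With
    ``near_equilibrium_only`` (default) only ``t in {0, t_max - 1}`` are kept
    — the steps where the cascade is at or next to its absorbing state and
    the well-mixed approximation holds; transient-phase points are biased by
    clustering of active nodes and are exposed only when the flag is off.
    """
    if part.C == 0:
        raise UndefinedCurveError("no contingent individuals: (r - a)/c is undefined")
    if traj.t_max < 1:
        raise UndefinedCurveError("trajectory too short to estimate thresholds")
    a, c, N = part.a, part.c, part.N
    r = traj.R / N
    ts = np.arange(traj.t_max)  # pairs (t, t+1)
    if near_equilibrium_only:
        ts = np.unique([0, traj.t_max - 1])
    return EmergentThresholdCurve(
        r=r[ts],
        F=(r[ts + 1] - a) / c,
        method="empirical",
        params={"a": a, "p": part.p, "N": N},
    )
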
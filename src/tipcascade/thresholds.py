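"""Threshold CDFs: the distribution F feeding the macroscopic recursion.

``F`` maps the current number (or share) of active individuals to the
cumulative fraction of the contingent population whose emergent threshold is
met.  Several provenances are supported: a cut-off Gaussian (the classic
choice), a tabulated curve read from CSV, a step function and the identity
(uniform thresholds).  The analytic emergent forms derived from the network
cascade live in :mod:`tipcascade.emergent` and share this interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidDistributionError

#: Anything accepted where a threshold CDF is expected.
CDFLike = Union["ThresholdCDF", Callable[[np.ndarray], np.ndarray]]


class ThresholdCDF:
    """Base class: a monotone map from activity level to [0, 1].

    Subclasses implement ``_evaluate`` on their native domain
    ``[domain_low, domain_high]`` (counts for Gaussian/tabulated forms,
    fractions for the analytic emergent forms).
    """

    kind: str = "abstract"
    domain_low: float = 0.0
    domain_high: float = 1.0

    def _evaluate(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x):
        arr = np.asarray(x, dtype=float)
        out = self._evaluate(np.atleast_1d(arr))
        return float(out[0]) if arr.ndim == 0 else out

    def scaled(self, N: float) -> "ScaledCDF":
        """View of a fraction-domain CDF on the count domain ``[0, N]``."""
        return ScaledCDF(self, N)


@dataclass
class ScaledCDF(ThresholdCDF):
    """Evaluate ``base(x / N)``: lifts a fraction-domain F to counts."""

    base: ThresholdCDF
    N: float

    def __post_init__(self):
        self.kind = self.base.kind
        self.domain_low = self.base.domain_low * self.N
        self.domain_high = self.base.domain_high * self.N

    def _evaluate(self, x):
        return np.atleast_1d(np.asarray(self.base(x / self.N), dtype=float))


class GaussianThresholdCDF(ThresholdCDF):
    """Cut-off Gaussian threshold distribution on the count domain ``[0, N]``.

    ``F(R) = Phi((R - mu) / sigma)`` evaluated on ``[0, N]``: probability mass
    below 0 behaves as threshold-0 individuals (it is included in ``F(R)`` for
    every ``R >= 0``) while mass above ``N`` corresponds to individuals who
    never act, so ``F(N) < 1``.
    """

    kind = "gaussian"

    def __init__(self, mu: float, sigma: float, N: float = 1.0):
        if sigma <= 0:
            raise InvalidDistributionError(f"sigma must be positive, got {sigma}")
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.domain_low, self.domain_high = 0.0, float(N)

    def _evaluate(self, x):
        return norm.cdf((x - self.mu) / self.sigma)


class TabulatedThresholdCDF(ThresholdCDF):
    """Piecewise-linear CDF through tabulated (threshold, cumulative) points."""

    kind = "tabulated"

    def __init__(self, x: np.ndarray, F: np.ndarray):
        x = np.asarray(x, dtype=float)
        F = np.asarray(F, dtype=float)
        if x.size < 2 or x.size != F.size:
            raise InvalidDistributionError("need two equal-length columns with >= 2 rows")
        if np.any(np.diff(x) <= 0):
            raise InvalidDistributionError("threshold grid must be strictly increasing")
        if np.any(np.diff(F) < 0) or F.min() < 0 or F.max() > 1:
            raise InvalidDistributionError("cumulative values must be nondecreasing in [0, 1]")
        self.x, self.F = x, F
        self.domain_low, self.domain_high = float(x[0]), float(x[-1])

    def _evaluate(self, q):
        return np.interp(q, self.x, self.F)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TabulatedThresholdCDF":
        """Read a two-column CSV (threshold, cumulative probability), header required."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise InvalidDistributionError(f"{path}: expected two columns")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"threshold": self.x, "cumulative": self.F}).to_csv(path, index=False)


class StepThresholdCDF(ThresholdCDF):
    """Degenerate CDF jumping 0 -> 1 at ``location`` (all thresholds equal)."""

    kind = "tabulated"

    def __init__(self, location: float, high: float = 1.0):
        self.location = float(location)
        self.domain_low, self.domain_high = 0.0, float(high)

    def _evaluate(self, x):
        return (x >= self.location).astype(float)


class UniformThresholdCDF(ThresholdCDF):
    """Uniform thresholds on ``[0, N]``: ``F(R) = R / N`` (the diagonal)."""

    kind = "tabulated"

    def __init__(self, N: float):
        self.domain_low, self.domain_high = 0.0, float(N)

    def _evaluate(self, x):
        return np.clip(x / self.domain_high, 0.0, 1.0)


def validate_cdf(F: CDFLike, low: float, high: float, samples: int = 513) -> None:
    """Check that ``F`` is nondecreasing with values in [0, 1] on ``[low, high]``.

    Raises :class:`InvalidDistributionError` on violation (sampled check; a
    pathological F oscillating between sample points will pass).
    """
    x = np.linspace(low, high, samples)
    y = np.asarray(F(x), dtype=float)
    if np.any(~np.isfinite(y)) or y.min() < -1e-12 or y.max() > 1 + 1e-12:
        raise InvalidDistributionError("CDF values must lie in [0, 1]")
    if np.any(np.diff(y) < -1e-9):
        raise InvalidDistributionError("CDF must be monotone nondecreasing")
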
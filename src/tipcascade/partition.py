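"""Population partition into certainly acting, contingent and never-acting groups.

The population of size ``N`` splits into ``A`` certainly acting individuals
(active from the outset), ``C`` contingent individuals (activate when their
social condition is met) and ``N - P`` certainly inactive individuals, where
``P = A + C`` is the potentially acting group.  Lower-case ``a``, ``c``, ``p``
are the corresponding population fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PartitionError


@dataclass(frozen=True)
class PopulationPartition:
    """Immutable group sizes ``(N, A, P)`` with derived counts and fractions.

    Parameters
    ----------
    N : int
        Total population size.
    A : int
        Number of certainly acting individuals, ``0 <= A <= P``.
    P : int
        Number of potentially acting individuals (certain plus contingent),
        ``A <= P <= N``.
    """

    N: int
    A: int
    P: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise PartitionError(f"population size must be positive, got N={self.N}")
        if not (0 <= self.A <= self.P <= self.N):
            raise PartitionError(
                f"group sizes must satisfy 0 <= A <= P <= N, "
                f"got A={self.A}, P={self.P}, N={self.N}"
            )

    @property
    def C(self) -> int:
        """Number of contingent individuals, ``P - A``."""
        return self.P - self.A

    @property
    def a(self) -> float:
        """Certainly acting fraction ``A / N``."""
        return self.A / self.N

    @property
    def p(self) -> float:
        """Potentially acting fraction ``P / N``."""
        return self.P / self.N

    @property
    def c(self) -> float:
        """Contingent fraction ``C / N = p - a``."""
        return self.C / self.N

    @classmethod
    def from_fractions(cls, N: int, a: float, p: float) -> "PopulationPartition":
        """Build a partition from fractions, rounding to integer counts.

        ``A = round(a * N)`` and ``P = round(p * N)``; raises
        :class:`PartitionError` if the rounded counts violate the ordering.
        """
        if not (0.0 <= a <= p <= 1.0):
            raise PartitionError(f"fractions must satisfy 0 <= a <= p <= 1, got a={a}, p={p}")
        return cls(N=N, A=int(round(a * N)), P=int(round(p * N)))
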
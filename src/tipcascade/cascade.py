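"""Microscopic network cascade: group assignment, dynamics and parameter sweeps.

Each node is certainly acting, contingent or never-acting.  At t=0 exactly
the certainly acting nodes are active.  In every step each contingent,
still-inactive node activates if its share of active neighbours *strictly*
exceeds the threshold fraction rho; all nodes update synchronously and
activation is irreversible.  The cascade stops when no node activates in a
step, i.e. R(t) = R(t-1).  Zero-degree contingent nodes never activate
(their active share is 0 and 0 > 0 is false).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, PartitionError
from .network import SocialNetwork, generate_er_network
from .partition import PopulationPartition

NEVER, CONTINGENT, CERTAIN = 0, 1, 2
_LABEL_NAMES = {NEVER: "never", CONTINGENT: "contingent", CERTAIN: "certain"}


@dataclass
class GroupAssignment:
    """Per-node labels (never / contingent / certain) for one network."""

    labels: np.ndarray  # int8 codes, length N
    seed: int | None = None

    @property
    def certain(self) -> np.ndarray:
        return self.labels == CERTAIN

    @property
    def contingent(self) -> np.ndarray:
        return self.labels == CONTINGENT

    @property
    def never(self) -> np.ndarray:
        return self.labels == NEVER

    @property
    def counts(self) -> tuple[int, int, int]:
        """(A, C, N - P) label counts."""
        return (
            int(self.certain.sum()),
            int(self.contingent.sum()),
            int(self.never.sum()),
        )

    def label_names(self) -> np.ndarray:
        return np.array([_LABEL_NAMES[int(c)] for c in self.labels])


@dataclass
class CascadeTrajectory:
    """Active counts R(t) of one cascade run, including the repeated final step."""

    R: np.ndarray
    N: int
    active_final: np.ndarray | None = field(default=None, repr=False)
    states: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def t_max(self) -> int:
        return len(self.R) - 1

    @property
    def r_star(self) -> float:
        """Final active share R(t_max) / N."""
        return float(self.R[-1]) / self.N

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": np.arange(len(self.R)), "R": self.R}).to_csv(path, index=False)


@dataclass
class SweepResult:
    """Per-replicate final shares of an (a, p, rho) parameter sweep."""

    runs: pd.DataFrame  # columns: a, p, rho, replicate, r_star
    master_seed: int | None = None

    @property
    def summary(self) -> pd.DataFrame:
        """Median / mean / std of the final share per (a, p, rho) cell."""
        return (
            self.runs.groupby(["a", "p", "rho"])["r_star"]
            .agg(["median", "mean", "std"])
            .reset_index()
        )

    def to_csv(self, path: str | Path) -> None:
        self.runs.to_csv(path, index=False)


def assign_groups(
    net: SocialNetwork, part: PopulationPartition, seed=None
) -> GroupAssignment:
    """Uniform random group assignment consistent with a population partition.

    First a uniform subset of size P is marked potentially active; of those, a
    uniform subset of size A is marked certain and the rest contingent.  Label
    counts match (A, C, N - P) exactly in every draw.
    """
    if part.N != net.n_nodes:
        raise PartitionError(
            f"partition size {part.N} does not match network size {net.n_nodes}"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(part.N, dtype=np.int8)
    potential = rng.choice(part.N, size=part.P, replace=False)
    labels[potential] = CONTINGENT
    certain = rng.choice(potential, size=part.A, replace=False) if part.A else []
    labels[certain] = CERTAIN
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return GroupAssignment(labels=labels, seed=seed_int)


def run_cascade(
    net: SocialNetwork,
    groups: GroupAssignment,
    rho: float,
    record_states: bool = False,
) -> CascadeTrajectory:
    """Run the synchronous strict-threshold cascade to its absorbing state."""
    if not (0.0 <= rho <= 1.0):
        raise ParameterError(f"rho must lie in [0, 1], got {rho}")
    if len(groups.labels) != net.n_nodes:
        raise PartitionError("group assignment does not match network size")

    adj = net.adjacency
    k = net.degrees
    contingent = groups.contingent
    active = groups.certain.copy()

    R = [int(active.sum())]
    states = [np.flatnonzero(active)] if record_states else None
    while True:
        active_neighbors = adj @ active.astype(np.float64)
        newly = contingent & ~active & (active_neighbors > rho * k)
        active = active | newly
        R.append(int(active.sum()))
        if record_states:
            states.append(np.flatnonzero(active))
        if not newly.any():
            break
    return CascadeTrajectory(
        R=np.array(R, dtype=np.int64), N=net.n_nodes, active_final=active, states=states
    )


def replicate_seed(master_seed: int, cell: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed: SeedSequence(master, spawn_key=(cell, replicate))."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell, replicate))


def simulate_replicate(
    N: int,
    mean_degree: float,
    a: float,
    p: float,
    rho: float,
    seed_seq: np.random.SeedSequence,
    link_prob: float | None = None,
) -> CascadeTrajectory:
    """One independent (network, assignment) draw and its cascade."""
    rng = np.random.default_rng(seed_seq)
    graph_seed = int(rng.integers(2**31))
    net = generate_er_network(
        N, mean_degree=None if link_prob else mean_degree, link_prob=link_prob, seed=graph_seed
    )
    part = PopulationPartition.from_fractions(N, a, p)
    groups = assign_groups(net, part, seed=rng)
    return run_cascade(net, groups, rho)


def find_tipping_a(
    N: int,
    mean_degree: float,
    p: float,
    rho: float,
    a_grid,
    n: int = 20,
    seed: int = 0,
    cascade_level: float = 0.9,
) -> float:
    """Critical certainly-acting share at which global cascades set in.

    Runs an ensemble sweep over ``a_grid`` (ascending) and returns the first
    a whose ensemble-median final share exceeds ``cascade_level * p`` — the
    operational definition of the microscopic tipping point.  Raises
    :class:`ParameterError` if no grid value tips.
    """
    a_grid = np.sort(np.atleast_1d(np.asarray(a_grid, dtype=float)))
    sweep = sweep_final_share(N, mean_degree, [rho], a_grid, [p], n=n, seed=seed)
    medians = sweep.runs.groupby("a")["r_star"].median()
    tipped = medians[medians > cascade_level * p]
    if tipped.empty:
        raise ParameterError(
            f"no a in [{a_grid[0]}, {a_grid[-1]}] produces a global cascade"
        )
    return float(tipped.index[0])


def sweep_final_share(
    N: int,
    mean_degree: float,
    rho_values,
    a_grid,
    p_grid,
    n: int = 100,
    seed: int = 0,
) -> SweepResult:
    """Ensemble sweep of the final active share over (a, p, rho) cells.

    For each cell, ``n`` independent (network, assignment) replicates are run;
    networks are regenerated per replicate.  Replicate seeds derive
    deterministically from the master seed via :func:`replicate_seed`, so any
    single replicate is reproducible in isolation.  Cells with ``a > p`` are
    skipped.
    """
    a_grid = np.atleast_1d(np.asarray(a_grid, dtype=float))
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    rho_values = np.atleast_1d(np.asarray(rho_values, dtype=float))
    records = []
    cell = 0
    for rho in rho_values:
        for p in p_grid:
            for a in a_grid:
                if a > p:
                    cell += 1
                    continue
                for rep in range(n):
                    traj = simulate_replicate(
                        N, mean_degree, a, p, rho, replicate_seed(seed, cell, rep)
                    )
                    records.append(
                        {"a": a, "p": p, "rho": rho, "replicate": rep, "r_star": traj.r_star}
                    )
                cell += 1
    return SweepResult(runs=pd.DataFrame.from_records(records), master_seed=seed)
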
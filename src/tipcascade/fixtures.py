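"""Tiny hand-checkable graph fixtures with known cascade outcomes.

Each fixture bundles a small named graph, a group labelling and, per
threshold fraction, the hand-enumerated final active set of the synchronous
strict-threshold cascade.  They serve as ground truth for the simulator and
can be written to disk as plain-text edge lists plus expected-outcome JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CERTAIN, CONTINGENT, NEVER, GroupAssignment
from .network import SocialNetwork


@dataclass
class Fixture:
    """A named tiny graph with labels and hand-enumerated cascade outcomes."""

    name: str
    network: SocialNetwork
    labels: np.ndarray
    expected: dict[float, frozenset[int]]  # rho -> final active node set

    @property
    def groups(self) -> GroupAssignment:
        return GroupAssignment(labels=self.labels.copy())


def _labels(N: int, certain=(), contingent=(), never=()) -> np.ndarray:
    lab = np.full(N, NEVER, dtype=np.int8)
    lab[list(contingent)] = CONTINGENT
    lab[list(certain)] = CERTAIN
    lab[list(never)] = NEVER
    return lab


def builtin_fixtures() -> list[Fixture]:
    """The named fixture set: star, path, complete, two-cliques, isolated node.

    Expected outcomes are enumerated by hand from the strict activation rule
    (share of active neighbours must strictly exceed rho).
    """
    fixtures = []

    # star: certain centre 0, contingent leaves 1-4; each leaf sees share 1/1
    star = SocialNetwork.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
    fixtures.append(
        Fixture(
            name="star",
            network=star,
            labels=_labels(5, certain=[0], contingent=[1, 2, 3, 4]),
            expected={
                0.5: frozenset({0, 1, 2, 3, 4}),  # 1 > 0.5: all leaves at t=1
                0.99: frozenset({0, 1, 2, 3, 4}),  # 1 > 0.99 still
                1.0: frozenset({0}),  # 1 > 1 is false
            },
        )
    )

    # path 0-1-2: certain end, contingent middle (degree 2), never end;
    # middle's share is exactly 1/2, strictly-greater rule blocks it at rho=0.5
    path = SocialNetwork.from_edges(3, [(0, 1), (1, 2)])
    fixtures.append(
        Fixture(
            name="path",
            network=path,
            labels=_labels(3, certain=[0], contingent=[1], never=[2]),
            expected={
                0.5: frozenset({0}),  # 0.5 > 0.5 false: tie does not activate
                0.4: frozenset({0, 1}),  # 0.5 > 0.4: middle joins
            },
        )
    )

    # complete graph K4: one certain, three contingent; shares grow 1/3 -> 1
    complete = SocialNetwork.from_edges(
        4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    )
    fixtures.append(
        Fixture(
            name="complete",
            network=complete,
            labels=_labels(4, certain=[0], contingent=[1, 2, 3]),
            expected={
                0.2: frozenset({0, 1, 2, 3}),  # 1/3 > 0.2 at t=1
                0.4: frozenset({0}),  # 1/3 > 0.4 false; nothing ever moves
            },
        )
    )

    # two triangles bridged by edge 2-3; two certain in the left clique;
    # at rho=0.6 node 2 (share 2/3) joins but the bridge cannot carry on:
    # node 3 sees only 1/3 active
    cliques = SocialNetwork.from_edges(
        6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    )
    fixtures.append(
        Fixture(
            name="two_cliques",
            network=cliques,
            labels=_labels(6, certain=[0, 1], contingent=[2, 3, 4, 5]),
            expected={
                0.6: frozenset({0, 1, 2}),  # confined to the seeded clique
                0.2: frozenset({0, 1, 2, 3, 4, 5}),  # 1/3 > 0.2 crosses the bridge
            },
        )
    )

    # isolated contingent node: degree 0, share 0, 0 > rho*0 is false
    isolated = SocialNetwork.from_edges(3, [(0, 1)])
    fixtures.append(
        Fixture(
            name="isolated_node",
            network=isolated,
            labels=_labels(3, certain=[0], contingent=[1, 2]),
            expected={
                0.0: frozenset({0, 1}),  # node 2 stays out even at rho=0
                0.5: frozenset({0, 1}),  # 1 > 0.5 for node 1
            },
        )
    )
    return fixtures


def generate_fixtures(out_dir: str | Path) -> list[Fixture]:
    """Write the fixture set as edge lists, label CSVs and expected JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = builtin_fixtures()
    for fx in fixtures:
        fx.network.to_edgelist(out / f"{fx.name}.edges")
        pd.DataFrame(
            {"node": np.arange(len(fx.labels)), "label": fx.groups.label_names()}
        ).to_csv(out / f"{fx.name}.labels.csv", index=False)
        payload = {
            str(rho): sorted(active) for rho, active in fx.expected.items()
        }
        (out / f"{fx.name}.expected.json").write_text(json.dumps(payload, indent=2))
    return fixtures
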
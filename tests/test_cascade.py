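"""Microscopic cascade dynamics: fixtures, oracle equivalence, invariants."""

import numpy as np
import pytest

from tipcascade import (
    ParameterError,
    PartitionError,
    PopulationPartition,
    SocialNetwork,
    assign_groups,
    generate_er_network,
    replicate_seed,
    run_cascade,
    simulate_replicate,
    sweep_final_share,
)
from tipcascade.cascade import CERTAIN, CONTINGENT, GroupAssignment

from conftest import brute_force_cascade, random_small_instance


class TestAssignGroups:
    def test_counts_exact_across_draws(self):
        net = generate_er_network(10_000, mean_degree=5.0, seed=0)
        part = PopulationPartition(N=10_000, A=137, P=4_211)
        for seed in range(5):
            groups = assign_groups(net, part, seed=seed)
            assert groups.counts == (137, 4_074, 10_000 - 4_211)

    def test_all_certain_and_all_never_extremes(self):
        net = generate_er_network(50, mean_degree=4.0, seed=1)
        all_cert = assign_groups(net, PopulationPartition(N=50, A=50, P=50), seed=0)
        assert all_cert.certain.all()
        none = assign_groups(net, PopulationPartition(N=50, A=0, P=0), seed=0)
        assert none.never.all()

    def test_size_mismatch_rejected(self):
        net = generate_er_network(50, mean_degree=4.0, seed=1)
        with pytest.raises(PartitionError):
            assign_groups(net, PopulationPartition(N=49, A=0, P=10), seed=0)


class TestRunCascade:
    def test_fixture_outcomes_match_hand_enumeration(self, fixture_set):
        for fx in fixture_set:
            for rho, expected_active in fx.expected.items():
                traj = run_cascade(fx.network, fx.groups, rho)
                assert set(np.flatnonzero(traj.active_final)) == set(expected_active), (
                    f"{fx.name} at rho={rho}"
                )
                assert traj.R[-1] == traj.R[-2]  # stopped at the absorbing state

    def test_matches_brute_force_reference_on_small_graphs(self, fixture_set):
        # named fixtures plus random instances with N <= 8
        cases = [(fx.network, fx.labels, rho) for fx in fixture_set for rho in fx.expected]
        rng = np.random.default_rng(20240)
        cases += [random_small_instance(rng) for _ in range(60)]
        for net, labels, rho in cases:
            traj = run_cascade(net, GroupAssignment(labels=labels.copy()), rho)
            R_ref, active_ref = brute_force_cascade(net, labels, rho)
            assert traj.R.tolist() == R_ref
            assert set(np.flatnonzero(traj.active_final)) == active_ref

    def test_activation_is_irreversible(self):
        traj = simulate_replicate(2_000, 8.0, 0.05, 0.7, 0.3, replicate_seed(7, 0, 0))
        assert np.all(np.diff(traj.R) >= 0)
        assert 0.05 - 1e-9 <= traj.r_star <= 0.7 + 1e-9

    def test_identical_seed_gives_identical_trajectory(self):
        t1 = simulate_replicate(1_000, 6.0, 0.05, 0.6, 0.25, replicate_seed(3, 1, 4))
        t2 = simulate_replicate(1_000, 6.0, 0.05, 0.6, 0.25, replicate_seed(3, 1, 4))
        assert np.array_equal(t1.R, t2.R)
        assert np.array_equal(t1.active_final, t2.active_final)

    def test_no_contingents_final_share_is_a(self):
        net = generate_er_network(500, mean_degree=5.0, seed=2)
        part = PopulationPartition(N=500, A=60, P=60)
        traj = run_cascade(net, assign_groups(net, part, seed=0), rho=0.1)
        assert traj.r_star == 60 / 500

    def test_invalid_rho_rejected(self):
        net = generate_er_network(10, mean_degree=3.0, seed=0)
        groups = assign_groups(net, PopulationPartition(N=10, A=1, P=5), seed=0)
        with pytest.raises(ParameterError):
            run_cascade(net, groups, rho=1.2)


class TestMonotonicity:
    def _fixed_instance(self, seed=11):
        rng = np.random.default_rng(seed)
        net = generate_er_network(800, mean_degree=6.0, seed=int(rng.integers(2**31)))
        labels = np.zeros(800, dtype=np.int8)
        potential = rng.choice(800, size=500, replace=False)
        labels[potential] = CONTINGENT
        return net, labels, potential, rng

    def test_nested_certain_sets_give_nested_final_sets(self):
        net, labels, potential, rng = self._fixed_instance()
        seeds_big = rng.choice(potential, size=60, replace=False)
        seeds_small = seeds_big[:20]  # nested subset
        finals = []
        for seeds in (seeds_small, seeds_big):
            lab = labels.copy()
            lab[seeds] = CERTAIN
            traj = run_cascade(net, GroupAssignment(labels=lab), rho=0.25)
            finals.append(set(np.flatnonzero(traj.active_final)))
        assert finals[0] <= finals[1]

    def test_larger_rho_activates_a_subset(self):
        net, labels, potential, rng = self._fixed_instance(seed=12)
        lab = labels.copy()
        lab[rng.choice(potential, size=40, replace=False)] = CERTAIN
        groups = GroupAssignment(labels=lab)
        low = set(np.flatnonzero(run_cascade(net, groups, rho=0.2).active_final))
        high = set(np.flatnonzero(run_cascade(net, groups, rho=0.5).active_final))
        assert high <= low


class TestSweep:
    def test_a_equals_p_cells_exact(self):
        sweep = sweep_final_share(200, 5.0, [0.3], [0.2], [0.2], n=4, seed=5)
        assert np.allclose(sweep.runs["r_star"], 0.2)

    def test_runs_bounded_by_a_and_p(self):
        sweep = sweep_final_share(500, 6.0, [0.2, 0.6], [0.05, 0.2], [0.5], n=3, seed=9)
        part_eps = 1.0 / 500 + 1e-12  # fraction rounding to integer counts
        for _, row in sweep.runs.iterrows():
            assert row.r_star >= row.a - part_eps
            assert row.r_star <= row.p + part_eps

    def test_sweep_is_reproducible(self):
        s1 = sweep_final_share(300, 5.0, [0.3], [0.05, 0.1], [0.5], n=3, seed=21)
        s2 = sweep_final_share(300, 5.0, [0.3], [0.05, 0.1], [0.5], n=3, seed=21)
        assert s1.runs.equals(s2.runs)
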
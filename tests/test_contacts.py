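"""Contact probabilities, dCNA and community detection, checked against
brute-force oracles (per-frame double loops; exhaustive partition
enumeration for modularity)."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_trajectory
from gatekin.contacts import (
    ContactMap,
    ContactNetworkError,
    build_consensus_network,
    community_difference,
    compute_contact_probabilities,
    contact_difference,
    detect_communities,
    dynamic_contact_mask,
)
from gatekin.synthetic import (
    generate_two_state_trajectory,
    variant_like_spec,
    wild_type_like_spec,
)


def brute_force_pc(traj, cutoff=4.5, min_sep=3):
    """Independent per-frame, per-pair minimum heavy-atom distance count."""
    heavy = traj.topology.heavy
    res = traj.topology.residue_indices
    n_res = traj.n_residues
    counts = {}
    for f in range(traj.n_frames):
        pos = traj.coordinates[f]
        for i in range(n_res):
            ai = np.flatnonzero((res == i) & heavy)
            for j in range(i + min_sep, n_res):
                aj = np.flatnonzero((res == j) & heavy)
                dmin = np.min(
                    np.linalg.norm(pos[ai][:, None, :] - pos[aj][None, :, :], axis=2)
                )
                if dmin < cutoff:
                    counts[(i, j)] = counts.get((i, j), 0) + 1
    return {p: c / traj.n_frames for p, c in counts.items()}


def all_partitions(nodes):
    """Every partition of a node set (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def toy_map(pc_by_pair, n_residues, n_frames=100, min_sep=3, label=""):
    counts = {p: int(round(v * n_frames)) for p, v in pc_by_pair.items()}
    return ContactMap(
        counts=counts, n_frames=n_frames, n_residues=n_residues,
        cutoff=4.5, min_sep=min_sep, condition_label=label,
    )


class TestContactProbabilities:
    def test_fixed_pair_within_cutoff_has_pc_one(self):
        coords = np.array([[[0, 0, 0], [3, 0, 0], [20, 0, 0], [30, 0, 0]]] * 5, float)
        traj = make_trajectory(coords, ["CA"] * 4, [0, 1, 2, 3])
        cmap = compute_contact_probabilities(traj, min_sep=1)
        assert cmap.pc(0, 1) == 1.0

    def test_pc_one_third_on_three_frame_toy(self):
        frames = np.array(
            [
                [[0, 0, 0], [20, 0, 0], [30, 0, 0], [3, 0, 0]],
                [[0, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]],
                [[0, 0, 0], [20, 0, 0], [30, 0, 0], [50, 0, 0]],
            ],
            float,
        )
        traj = make_trajectory(frames, ["CA"] * 4, [0, 1, 2, 3])
        cmap = compute_contact_probabilities(traj)
        oracle = brute_force_pc(traj)
        assert cmap.pc(0, 3) == pytest.approx(1 / 3)
        assert oracle[(0, 3)] == pytest.approx(1 / 3)

    def test_sequence_neighbors_excluded(self):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]] * 3, float)
        traj = make_trajectory(coords, ["CA"] * 4, [0, 1, 2, 3])
        cmap = compute_contact_probabilities(traj, min_sep=3)
        with pytest.raises(ContactNetworkError):
            cmap.pc(0, 1)
        assert set(cmap.counts) == {(0, 3)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_small_ensembles(self, seed):
        from gatekin.synthetic import SyntheticTrajectorySpec

        spec = SyntheticTrajectorySpec(
            n_residues=10, gate_residue=9, probe_residue=8, n_frames=100,
            designed_contact_edges={(0, 3): 0.6, (1, 5): 1.0, (2, 6): 0.3},
            seed=seed,
        )
        traj, _ = generate_two_state_trajectory(spec)
        traj = make_trajectory(  # truncate to <=50 frames for the oracle
            traj.coordinates[:50], traj.topology.atom_names,
            traj.topology.residue_indices,
        )
        cmap = compute_contact_probabilities(traj)
        oracle = brute_force_pc(traj)
        pairs = set(cmap.counts) | set(oracle)
        for p in sorted(pairs):
            assert cmap.pc(*p) == pytest.approx(oracle.get(p, 0.0)), p

    def test_no_heavy_atoms_rejected(self):
        traj = make_trajectory(np.zeros((2, 2, 3)), ["HA", "HB"], [0, 1])
        with pytest.raises(ContactNetworkError):
            compute_contact_probabilities(traj)


class TestDynamicMaskAndDifference:
    def test_boundary_semantics(self):
        a = toy_map({(0, 3): 1.0, (0, 4): 0.5, (1, 4): 0.05}, 6)
        b = toy_map({(0, 3): 1.0, (0, 4): 1.0, (1, 4): 0.08}, 6)
        mask = dynamic_contact_mask(a, b)
        assert (0, 3) not in mask          # (1.0, 1.0): static
        assert (0, 4) in mask              # (0.5, 1.0): dynamic in A
        assert (1, 4) not in mask          # both below 0.1

    def test_identical_maps_give_zero_dpc(self):
        a = toy_map({(0, 3): 0.5, (1, 4): 0.2}, 6)
        diff = contact_difference(a, a)
        assert all(v == 0.0 for v in diff.dpc.values())
        assert set(diff.classification.values()) == {"unchanged"}

    def test_dpc_arithmetic_and_classification(self):
        a = toy_map({(0, 3): 0.2}, 6)
        b = toy_map({(0, 3): 0.9}, 6)
        diff = contact_difference(a, b)
        assert diff.dpc[(0, 3)] == pytest.approx(0.7)
        assert diff.classification[(0, 3)] == "more_often"

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(4)
        pairs = {(i, i + 3): rng.random() for i in range(6)}
        pairs2 = {p: rng.random() for p in pairs}
        a, b = toy_map(pairs, 10), toy_map(pairs2, 10)
        fwd = contact_difference(a, b)
        rev = contact_difference(b, a)
        for p in fwd.dpc:
            assert fwd.dpc[p] == pytest.approx(-rev.dpc[p])

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ContactNetworkError):
            dynamic_contact_mask(toy_map({}, 5), toy_map({}, 6))


class TestConsensusNetwork:
    def test_threshold_inclusive_both_conditions(self):
        a = toy_map({(0, 3): 0.95, (1, 4): 0.95}, 6)
        b = toy_map({(0, 3): 0.91, (1, 4): 0.89}, 6)
        net = build_consensus_network(a, b)
        assert net.graph.has_edge(0, 3)
        assert not net.graph.has_edge(1, 4)

    def test_isolated_residues_retained(self):
        net = build_consensus_network(toy_map({(0, 3): 1.0}, 8), toy_map({(0, 3): 1.0}, 8))
        assert net.graph.number_of_nodes() == 8

    def test_rigid_scaffold_recovered_exactly(self):
        from gatekin.synthetic import SyntheticTrajectorySpec

        scaffold = {(0, 3): 1.0, (0, 4): 1.0, (1, 4): 1.0, (2, 5): 1.0}
        specs = [
            SyntheticTrajectorySpec(
                n_residues=8, gate_residue=7, probe_residue=6, n_frames=150,
                designed_contact_edges=scaffold, seed=s,
            )
            for s in (31, 32)
        ]
        maps = [
            compute_contact_probabilities(generate_two_state_trajectory(s)[0])
            for s in specs
        ]
        net = build_consensus_network(*maps)
        assert set(map(tuple, map(sorted, net.graph.edges))) == set(scaffold)


class TestCommunities:
    def _exhaustive_best_modularity(self, g):
        best, best_mod = None, -np.inf
        for part in all_partitions(sorted(g.nodes)):
            mod = nx.algorithms.community.modularity(g, [set(c) for c in part])
            if mod > best_mod + 1e-12:
                best, best_mod = part, mod
        return best, best_mod

    def test_barbell_splits_at_bridge(self):
        g = nx.Graph()
        for base in (0, 4):
            g.add_edges_from(
                (base + i, base + j) for i in range(4) for j in range(i + 1, 4)
            )
        g.add_edge(3, 4)
        from gatekin.contacts import ConsensusNetwork

        part = detect_communities(ConsensusNetwork(graph=g, threshold=0.9))
        assert part.n_communities == 2
        assert {part.membership[i] for i in range(4)} == {0}
        assert {part.membership[i] for i in range(4, 8)} == {1}
        _, best_mod = self._exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(best_mod, abs=1e-12)

    def test_single_clique_stays_whole(self):
        g = nx.complete_graph(5)
        from gatekin.contacts import ConsensusNetwork

        part = detect_communities(ConsensusNetwork(graph=g, threshold=0.9))
        assert part.n_communities == 1
        _, best_mod = self._exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(best_mod, abs=1e-12)

    def test_disconnected_components_never_merged(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (5, 6), (6, 7), (5, 7)])
        from gatekin.contacts import ConsensusNetwork

        part = detect_communities(ConsensusNetwork(graph=g, threshold=0.9))
        assert part.n_communities >= 2
        assert part.membership[0] != part.membership[5]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_modularity_on_random_two_clique_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_edges_from((i, j) for i in range(4) for j in range(i + 1, 4))
        g.add_edges_from((i, j) for i in range(4, 8) for j in range(i + 1, 8))
        bridges = [(int(rng.integers(0, 4)), int(rng.integers(4, 8)))]
        g.add_edges_from(bridges)
        from gatekin.contacts import ConsensusNetwork

        part = detect_communities(ConsensusNetwork(graph=g, threshold=0.9))
        _, best_mod = self._exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(best_mod, abs=1e-12)

    def test_partition_beats_trivial_single_community(self, gated_pair):
        (wt, _), (var, _) = gated_pair
        maps = [compute_contact_probabilities(t) for t in (wt, var)]
        net = build_consensus_network(*maps)
        part = detect_communities(net)
        trivial = nx.algorithms.community.modularity(
            net.graph, [set(net.graph.nodes)]
        )
        assert part.modularity >= trivial

    def test_empty_network_rejected(self):
        from gatekin.contacts import ConsensusNetwork

        with pytest.raises(ContactNetworkError):
            detect_communities(ConsensusNetwork(graph=nx.Graph(), threshold=0.9))


class TestCommunityDifference:
    def _partition(self, membership):
        from gatekin.contacts import CommunityPartition

        return CommunityPartition(membership=membership, modularity=0.0)

    def _diff(self, dpc):
        from gatekin.contacts import ContactDifference

        return ContactDifference(
            dpc=dpc,
            classification={p: "unchanged" for p in dpc},
            mask=frozenset(dpc),
        )

    def test_zero_dpc_gives_zero_nets(self):
        part = self._partition({0: 0, 3: 0, 6: 1, 9: 1})
        cdg = community_difference(part, self._diff({(0, 6): 0.0, (3, 9): 0.0}))
        assert all(v == 0.0 for v in cdg.net.values())

    def test_spanning_pairs_sum(self):
        part = self._partition({0: 0, 1: 0, 6: 1, 7: 1})
        diff = self._diff({(0, 6): 0.5, (1, 7): 0.3, (0, 7): -0.1})
        cdg = community_difference(part, diff)
        assert cdg.net[(0, 1)] == pytest.approx(0.7)

    def test_conservation_sum_over_community_pairs(self, gated_pair):
        (wt, _), (var, _) = gated_pair
        maps = [compute_contact_probabilities(t) for t in (wt, var)]
        mask = dynamic_contact_mask(*maps)
        diff = contact_difference(*maps, mask)
        part = detect_communities(build_consensus_network(*maps))
        cdg = community_difference(part, diff)
        assert sum(cdg.net.values()) == pytest.approx(sum(diff.dpc.values()), abs=1e-12)

    def test_designed_interdomain_closure_positive_net(self, gated_pair):
        # variant-like condition forms inter-domain contacts more often;
        # the two scaffold domains' communities must show a positive net
        (wt, _), (var, _) = gated_pair
        maps = [compute_contact_probabilities(t) for t in (wt, var)]
        mask = dynamic_contact_mask(*maps)
        diff = contact_difference(*maps, mask)
        part = detect_communities(build_consensus_network(*maps))
        cdg = community_difference(part, diff)
        c_a, c_b = part.membership[0], part.membership[9]
        assert c_a != c_b
        key = (min(c_a, c_b), max(c_a, c_b))
        assert cdg.net[key] > 0

    def test_unpartitioned_residues_warn(self):
        part = self._partition({0: 0, 3: 0})
        with pytest.warns(UserWarning):
            cdg = community_difference(part, self._diff({(0, 3): 0.2, (5, 9): 0.4}))
        assert cdg.net[(0, 0)] == pytest.approx(0.2)
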
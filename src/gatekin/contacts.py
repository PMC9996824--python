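"""Contact probabilities and difference contact network analysis (dCNA).

A residue pair is in contact in a frame when the minimum heavy-atom
distance is below a cutoff (default 4.5 A); its contact probability pc is
the fraction of frames in contact.  Comparing two conditions gives the
per-pair difference dpc, evaluated on "dynamic" contacts (pc within
[0.1, 0.9] in at least one condition).  Contacts with pc >= 0.9 in both
conditions form a consensus network, whose Girvan-Newman communities
(modularity-maximum cut of the edge-betweenness dendrogram) aggregate the
dpc values into net inter-community differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Trajectory

__all__ = [
    "ContactMap",
    "ContactDifference",
    "ConsensusNetwork",
    "CommunityPartition",
    "CommunityDiffGraph",
    "ContactNetworkError",
    "compute_contact_probabilities",
    "dynamic_contact_mask",
    "contact_difference",
    "build_consensus_network",
    "detect_communities",
    "community_difference",
]


class ContactNetworkError(ValueError):
    """Invalid input for a contact-network operation."""


@dataclass
class ContactMap:
    """Residue-pair contact probabilities for one condition.

    Only pairs with sequence separation ``|i - j| >= min_sep`` are
    represented; pairs never in contact implicitly have pc = 0.
    """

    counts: dict                      # {(i, j) i<j: frames in contact}
    n_frames: int
    n_residues: int
    cutoff: float
    min_sep: int
    condition_label: str = ""

    def pc(self, i: int, j: int) -> float:
        """Contact probability of an eligible pair (order-insensitive)."""
        i, j = (i, j) if i < j else (j, i)
        if j - i < self.min_sep:
            raise ContactNetworkError(
                f"pair ({i}, {j}) is below the sequence-separation "
                f"threshold min_sep={self.min_sep}"
            )
        return self.counts.get((i, j), 0) / self.n_frames

    def pairs(self):
        """Pairs with nonzero contact probability, sorted."""
        return sorted(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(i, j, c / self.n_frames) for (i, j), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "pc"])


@dataclass
class ContactDifference:
    """Per-pair dpc = pc(condition B) - pc(condition A) on masked pairs."""

    dpc: dict                         # {(i, j): dpc}
    classification: dict              # {(i, j): more_often|less_often|unchanged}
    mask: frozenset
    threshold: float = 0.1
    label_a: str = ""
    label_b: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (i, j, self.dpc[(i, j)], self.classification[(i, j)])
            for (i, j) in sorted(self.dpc)
        ]
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "dpc", "class"])


@dataclass
class ConsensusNetwork:
    """Graph of contacts with pc >= threshold in both conditions; every
    residue is retained as a vertex even when isolated."""

    graph: nx.Graph
    threshold: float

    @property
    def n_residues(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class CommunityPartition:
    """Residue -> community id, with the modularity of the chosen cut."""

    membership: dict                  # {residue: community id}
    modularity: float

    @property
    def communities(self) -> dict:
        """Community id -> sorted residue list."""
        out: dict = {}
        for r, c in self.membership.items():
            out.setdefault(c, []).append(r)
        return {c: sorted(rs) for c, rs in out.items()}

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class CommunityDiffGraph:
    """Communities as vertices; net dpc summed over spanning residue pairs.

    ``net`` maps unordered community pairs (a <= b, a == b for
    intra-community sums) to the net dpc.
    """

    communities: dict                 # {community id: [residues]}
    net: dict                         # {(a, b) a<=b: net dpc}
    threshold: float = 0.1

    def sign_class(self, a: int, b: int) -> str:
        v = self.net.get((min(a, b), max(a, b)), 0.0)
        if v >= self.threshold:
            return "more_often"
        if v <= -self.threshold:
            return "less_often"
        return "unchanged"

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for c, residues in self.communities.items():
            g.add_node(c, size=len(residues))
        for (a, b), v in self.net.items():
            if a == b:
                g.nodes[a]["intra_net_dpc"] = v
            elif v != 0.0:
                g.add_edge(a, b, net_dpc=v, sign=self.sign_class(a, b))
        return g


def compute_contact_probabilities(
    traj: Trajectory,
    cutoff: float = 4.5,
    min_sep: int = 3,
) -> ContactMap:
    """Contact probability per residue pair.

    A pair is in contact in a frame iff the minimum distance between
    their heavy atoms is below ``cutoff``; pairs closer in sequence than
    ``min_sep`` are excluded.
    """
    heavy = traj.topology.heavy
    if not heavy.any():
        raise ContactNetworkError("topology has no heavy atoms flagged")
    idx = np.flatnonzero(heavy)
    res = traj.topology.residue_indices[idx]
    counts: dict = {}
    for f in range(traj.n_frames):
        pos = traj.coordinates[f, idx, :]
        tree = cKDTree(pos)
        seen = set()
        for a, b in tree.query_pairs(r=cutoff):
            ri, rj = res[a], res[b]
            if ri == rj:
                continue
            i, j = (ri, rj) if ri < rj else (rj, ri)
            if j - i < min_sep:
                continue
            seen.add((i, j))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    return ContactMap(
        counts=counts,
        n_frames=traj.n_frames,
        n_residues=traj.n_residues,
        cutoff=cutoff,
        min_sep=min_sep,
        condition_label=traj.condition_label,
    )


def _check_compatible(map_a: ContactMap, map_b: ContactMap) -> None:
    if map_a.n_residues != map_b.n_residues:
        raise ContactNetworkError(
            f"residue universes differ: {map_a.n_residues} vs {map_b.n_residues}"
        )
    if map_a.min_sep != map_b.min_sep:
        raise ContactNetworkError("contact maps use different min_sep")


def _eligible_pairs(map_a: ContactMap, map_b: ContactMap):
    return sorted(set(map_a.counts) | set(map_b.counts))


def dynamic_contact_mask(
    map_a: ContactMap,
    map_b: ContactMap,
    low: float = 0.1,
    high: float = 0.9,
) -> frozenset:
    """Pairs whose pc lies in the closed interval [low, high] in at least
    one of the two conditions ("dynamic" contacts)."""
    _check_compatible(map_a, map_b)
    selected = set()
    for pair in _eligible_pairs(map_a, map_b):
        pa, pb = map_a.pc(*pair), map_b.pc(*pair)
        if low <= pa <= high or low <= pb <= high:
            selected.add(pair)
    return frozenset(selected)


def contact_difference(
    map_a: ContactMap,
    map_b: ContactMap,
    mask: frozenset | None = None,
    threshold: float = 0.1,
) -> ContactDifference:
    """dpc = pc_B - pc_A on masked pairs, classified at +-threshold.

    Condition A is the reference (wild-type-like) condition, so positive
    dpc means the contact forms more often in condition B.
    """
    _check_compatible(map_a, map_b)
    if mask is None:
        mask = frozenset(_eligible_pairs(map_a, map_b))
    dpc, classification = {}, {}
    for pair in sorted(mask):
        d = map_b.pc(*pair) - map_a.pc(*pair)
        dpc[pair] = d
        if d >= threshold:
            classification[pair] = "more_often"
        elif d <= -threshold:
            classification[pair] = "less_often"
        else:
            classification[pair] = "unchanged"
    return ContactDifference(
        dpc=dpc,
        classification=classification,
        mask=frozenset(mask),
        threshold=threshold,
        label_a=map_a.condition_label,
        label_b=map_b.condition_label,
    )


def build_consensus_network(
    map_a: ContactMap,
    map_b: ContactMap,
    threshold: float = 0.9,
) -> ConsensusNetwork:
    """Graph of contacts with pc >= threshold in *both* conditions."""
    _check_compatible(map_a, map_b)
    g = nx.Graph()
    g.add_nodes_from(range(map_a.n_residues))
    for pair in _eligible_pairs(map_a, map_b):
        if map_a.pc(*pair) >= threshold and map_b.pc(*pair) >= threshold:
            g.add_edge(*pair)
    return ConsensusNetwork(graph=g, threshold=threshold)


def _components_partition(g: nx.Graph) -> list:
    """Connected components as a partition, each sorted, ordered by
    lowest member."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def detect_communities(net: ConsensusNetwork) -> CommunityPartition:
    """Girvan-Newman community detection with modularity-maximum stopping.

    Edges are removed in order of decreasing edge betweenness (recomputed
    exactly after every removal; ties broken toward the lexicographically
    smallest edge).  Every partition along the dendrogram — starting from
    the connected components of the untouched network — is scored with
    Newman-Girvan modularity on the original network, and the best-scoring
    one is returned (ties: fewest communities).  Community ids are
    assigned in order of each community's lowest residue index.
    """
    g0 = net.graph
    if g0.number_of_nodes() == 0 or g0.number_of_edges() == 0:
        raise ContactNetworkError("consensus network has no edges to partition")
    work = g0.copy()
    candidates = [_components_partition(work)]
    while work.number_of_edges() > 0:
        n_before = nx.number_connected_components(work)
        betweenness = nx.edge_betweenness_centrality(work)
        best_edge = min(
            betweenness,
            key=lambda e: (-betweenness[e], min(e), max(e)),
        )
        work.remove_edge(*best_edge)
        if nx.number_connected_components(work) > n_before:
            candidates.append(_components_partition(work))
    scored = [
        (nx.algorithms.community.modularity(g0, p), -len(p), i, p)
        for i, p in enumerate(candidates)
    ]
    best = max(scored, key=lambda t: (t[0], t[1], -t[2]))
    modularity, _, _, partition = best
    membership = {}
    for cid, residues in enumerate(sorted(partition, key=lambda c: c[0])):
        for r in residues:
            membership[r] = cid
    return CommunityPartition(membership=membership, modularity=float(modularity))


def community_difference(
    partition: CommunityPartition,
    diff: ContactDifference,
) -> CommunityDiffGraph:
    """Net dpc between (and within) communities.

    For each unordered community pair, the net dpc is the sum of per-pair
    dpc over masked residue pairs with one member in each community;
    intra-community sums are reported under ``(c, c)``.  Residues in the
    difference map but missing from the partition are skipped with a
    warning.
    """
    membership = partition.membership
    communities = partition.communities
    net = {(a, b): 0.0 for a in communities for b in communities if a <= b}
    skipped = set()
    for (i, j), d in diff.dpc.items():
        if i not in membership or j not in membership:
            skipped.update(r for r in (i, j) if r not in membership)
            continue
        a, b = membership[i], membership[j]
        key = (a, b) if a <= b else (b, a)
        net[key] += d
    if skipped:
        warnings.warn(
            f"{len(skipped)} residues in the contact difference are not in "
            f"the community partition and were ignored: {sorted(skipped)[:10]}",
            stacklevel=2,
        )
    return CommunityDiffGraph(
        communities=communities,
        net=net,
        threshold=diff.threshold,
    )
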
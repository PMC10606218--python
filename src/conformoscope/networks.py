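"""Protein-structure networks, consensus networks and residue communities.

A structure is represented as a network of interacting residues: nodes are
residue numbers, and two residues at least 3 positions apart in sequence are
linked when their Calpha atoms fall within a contact cutoff (5 A default;
this package reads only Calpha traces, so the heavy-atom contact definition
of all-atom tools is replaced by a Calpha proxy). Contact counts are
normalised per amino-acid type,

    I_ij = 100 * n_ij / sqrt(N_i * N_j),

where N_x is the mean contact count of amino-acid type x over the input
pool (floored at one contact, so strengths stay within [0, 100]), and
edges with interaction strength below ``i_min`` (default 3.0) are pruned.

Consensus networks over a conformational ensemble retain edges present in a
minimum fraction of members; comparing the consensus of an outward-open
ensemble with that of an inward-open ensemble exposes the state-specific
contacts and the residue communities they form (the gating communities of
the carrier).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import SegmentTable, StructureModel
from .superpose import ResidueMap


@dataclasses.dataclass
class PSNGraph:
    """Residue-interaction network with its construction parameters."""

    graph: nx.Graph
    i_min: float
    contact_cutoff: float
    norm_factors: dict[str, float]

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def strength(self, i: int, j: int) -> float:
        return float(self.graph.edges[i, j]["weight"])


@dataclasses.dataclass(frozen=True)
class Community:
    id: str
    members: frozenset[int]
    segments_touched: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def contact_norm_factors(models: Sequence[StructureModel], contact_cutoff: float = 5.0,
                         min_separation: int = 3) -> dict[str, float]:
    """Mean contact count per amino-acid type over a pool of models."""
    counts: dict[str, list[int]] = defaultdict(list)
    for model in models:
        n_contacts = _contact_counts(model, contact_cutoff, min_separation)
        for letter, c in zip(model.letters, n_contacts):
            counts[letter].append(c)
    return {aa: float(np.mean(v)) for aa, v in counts.items()}


def _contact_counts(model: StructureModel, cutoff: float, min_separation: int) -> np.ndarray:
    d = squareform(pdist(model.coords))
    numbers = np.asarray(model.numbers)
    sep = np.abs(numbers[:, None] - numbers[None, :])
    contact = (d <= cutoff) & (sep >= min_separation)
    return contact.sum(axis=1)


def build_psn(
    model: StructureModel,
    contact_cutoff: float = 5.0,
    i_min: float = 3.0,
    norm_factors: Optional[dict[str, float]] = None,
    min_separation: int = 3,
) -> PSNGraph:
    """Residue-interaction network of one model.

    ``norm_factors`` (the per-amino-acid normalisation N_x) should be
    computed once over the whole ensemble with :func:`contact_norm_factors`
    when building networks for several members of a pool; if omitted it is
    computed from this model alone.
    """
    if len(model) < 10:
        raise ValueError("model too small for a structure network (<10 residues)")
    if norm_factors is None:
        norm_factors = contact_norm_factors([model], contact_cutoff, min_separation)
    d = squareform(pdist(model.coords))
    if not np.all(np.isfinite(d)):
        raise ValueError("degenerate coordinates")
    numbers = model.numbers
    g = nx.Graph()
    g.add_nodes_from(numbers)
    n = len(numbers)
    for i in range(n):
        n_i = max(norm_factors.get(model.letters[i], 0.0), 1.0)
        for j in range(i + 1, n):
            if abs(numbers[j] - numbers[i]) < min_separation or d[i, j] > contact_cutoff:
                continue
            n_j = max(norm_factors.get(model.letters[j], 0.0), 1.0)
            strength = 100.0 / np.sqrt(n_i * n_j)
            if strength >= i_min:
                g.add_edge(numbers[i], numbers[j], weight=float(strength))
    return PSNGraph(g, i_min=i_min, contact_cutoff=contact_cutoff, norm_factors=dict(norm_factors))


def consensus_network(
    graphs: Sequence[PSNGraph],
    occupancy: float = 0.5,
    maps: Optional[Sequence[ResidueMap]] = None,
    reference_numbers: Optional[Sequence[int]] = None,
) -> PSNGraph:
    """Edges present in at least ``occupancy`` of the graphs, mean strength.

    When the members are numbered differently, ``maps[k]`` must map graph
    ``k``'s residue numbers onto a designated reference numbering (pairs of
    positional indices into ``graphs[k]``'s sorted node list and
    ``reference_numbers``).
    """
    if len(graphs) < 2:
        raise ValueError("consensus needs at least 2 graphs")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    edge_occurrences: dict[tuple[int, int], list[float]] = defaultdict(list)
    common_nodes: Optional[set[int]] = None
    for k, psn in enumerate(graphs):
        if maps is not None:
            if reference_numbers is None:
                raise ValueError("reference_numbers required with maps")
            own = sorted(psn.nodes)
            translate = {own[i]: reference_numbers[j] for i, j in maps[k].pairs}
        else:
            translate = {n: n for n in psn.nodes}
        nodes_here = set(translate.values())
        common_nodes = nodes_here if common_nodes is None else common_nodes & nodes_here
        for i, j in psn.edges:
            if i in translate and j in translate:
                key = tuple(sorted((translate[i], translate[j])))
                edge_occurrences[key].append(psn.strength(i, j))
    if not common_nodes:
        raise ValueError("graphs share no residues after mapping")
    g = nx.Graph()
    g.add_nodes_from(sorted(common_nodes))
    threshold = occupancy * len(graphs)
    for (i, j), strengths in edge_occurrences.items():
        if len(strengths) + 1e-9 >= threshold:
            g.add_edge(i, j, weight=float(np.mean(strengths)))
    first = graphs[0]
    return PSNGraph(g, i_min=first.i_min, contact_cutoff=first.contact_cutoff,
                    norm_factors=dict(first.norm_factors))


def detect_communities(
    psn: PSNGraph,
    segments: Optional[SegmentTable] = None,
    min_size: int = 3,
    split_above: int = 30,
) -> list[Community]:
    """Communities of the pruned network.

    Connected components are taken first; components larger than
    ``split_above`` nodes are split by greedy modularity maximisation
    (deterministic). Components below ``min_size`` members are dropped.
    """
    g = psn.graph
    groups: list[set[int]] = []
    for comp in nx.connected_components(g):
        comp = set(comp)
        if len(comp) <= 1:
            continue
        if len(comp) > split_above:
            sub = g.subgraph(comp)
            groups.extend(set(c) for c in nx.community.greedy_modularity_communities(sub, weight="weight"))
        else:
            groups.append(comp)
    groups = [c for c in groups if len(c) >= min_size]
    groups.sort(key=lambda c: (-len(c), min(c)))
    communities = []
    for k, members in enumerate(groups, start=1):
        touched = frozenset(
            s for s in (segments.segment_of(r) for r in members) if s
        ) if segments is not None else frozenset()
        communities.append(Community(f"c{k}", frozenset(members), touched))
    return communities


@dataclasses.dataclass
class StateComparison:
    """Edge- and community-level differences between two state networks."""

    oo_only: set[tuple[int, int]]
    io_only: set[tuple[int, int]]
    shared: set[tuple[int, int]]
    oo_communities: list[Community]
    io_communities: list[Community]
    matched: list[tuple[Community, Community, float]]  # (oo, io, jaccard)

    def created_communities(self) -> list[Community]:
        paired = {id(c) for c, _, _ in self.matched}
        return [c for c in self.oo_communities if id(c) not in paired]

    def disrupted_communities(self) -> list[Community]:
        paired = {id(c) for _, c, _ in self.matched}
        return [c for c in self.io_communities if id(c) not in paired]


def _difference_graph(psn: PSNGraph, edges: set[tuple[int, int]]) -> PSNGraph:
    g = nx.Graph()
    for i, j in edges:
        g.add_edge(i, j, weight=psn.strength(i, j))
    return PSNGraph(g, psn.i_min, psn.contact_cutoff, psn.norm_factors)


def compare_state_networks(
    g_oo: PSNGraph,
    g_io: PSNGraph,
    segments: Optional[SegmentTable] = None,
    min_size: int = 2,
    match_jaccard: float = 0.3,
) -> StateComparison:
    """Classify edges as OO-only / IO-only / shared and match communities."""
    e_oo, e_io = g_oo.edges, g_io.edges
    oo_only, io_only, shared = e_oo - e_io, e_io - e_oo, e_oo & e_io
    com_oo = detect_communities(_difference_graph(g_oo, oo_only), segments, min_size=min_size)
    com_io = detect_communities(_difference_graph(g_io, io_only), segments, min_size=min_size)
    matched = []
    for a in com_oo:
        best, best_j = None, 0.0
        for b in com_io:
            inter = len(a.members & b.members)
            union = len(a.members | b.members)
            j = inter / union if union else 0.0
            if j > best_j:
                best, best_j = b, j
        if best is not None and best_j >= match_jaccard:
            matched.append((a, best, best_j))
    return StateComparison(oo_only, io_only, shared, com_oo, com_io, matched)


def write_edges_tsv(psn: PSNGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_i\tresidue_j\tinteraction_strength\n")
        for i, j in sorted(psn.edges):
            fh.write(f"{i}\t{j}\t{psn.strength(i, j):.3f}\n")


def write_graphml(psn: PSNGraph, path: str | Path) -> None:
    nx.write_graphml(psn.graph, str(path))


def write_communities_tsv(communities: Sequence[Community], path: str | Path,
                          segments: Optional[SegmentTable] = None) -> None:
    with open(path, "w") as fh:
        fh.write("community_id\tresidue\tsegment\n")
        for com in communities:
            for r in sorted(com.members):
                seg = segments.segment_of(r) if segments is not None else ""
                fh.write(f"{com.id}\t{r}\t{seg or ''}\n")
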
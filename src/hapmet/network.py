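"""Haplotype networks with unit-mutation edges and inferred intermediates.

An alignment is collapsed into haplotypes (identical sequences after
alignment-wide masking of ambiguous columns), the haplotypes are joined into
a minimum-spanning network (MSN) on Hamming distances with every co-minimal
edge retained, edges longer than one step are subdivided through inferred
(frequency-0) nodes, and the network is rooted at the most prevalent
haplotype with every edge directed away from the root.

The MSN stands in for statistical parsimony: on low-diversity intraspecific
data the two coincide, and the MSN is deterministic and well defined.  All
tie-breaks (haplotype numbering, root choice, cycle orientation) are
lexicographic so the whole construction is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import InputError, NetworkError
from .io import RateCategory, SequenceAlignment, TraitTable, categorize_rate

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "RootedNetwork",
    "masked_columns",
    "collapse_haplotypes",
    "build_network",
    "root_network",
    "network_distance",
    "export_network",
]


@dataclass(frozen=True)
class Haplotype:
    """A unique sequence variant and the individuals carrying it.

    ``sequence`` is in masked coordinates: alignment columns containing an
    ambiguity (N or -) in any record are removed alignment-wide before
    collapsing, so members are identical at every retained column.
    """

    haplotype_id: str
    sequence: str
    members: tuple[str, ...]

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """Unit-mutation haplotype graph (undirected).

    Nodes are haplotype ids plus inferred intermediates; every edge joins two
    sequences at Hamming distance exactly 1.  ``components`` lists the node
    sets of each connected component (singleton list when connected, which a
    finite connection limit may prevent).
    """

    graph: nx.Graph
    haplotypes: tuple[Haplotype, ...]

    @property
    def individual_to_haplotype(self) -> dict[str, str]:
        return {
            member: hap.haplotype_id
            for hap in self.haplotypes
            for member in hap.members
        }

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def observed_nodes(self) -> list[str]:
        return [h.haplotype_id for h in self.haplotypes]

    @property
    def inferred_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d.get("is_inferred", False)
        ]


@dataclass
class RootedNetwork:
    """A haplotype network rooted at the most prevalent haplotype.

    ``direction`` orients every undirected edge away from the root following
    breadth-first distance; the undirected edge set is unchanged.
    """

    network: HaplotypeNetwork
    root: str
    direction: dict[tuple[str, str], tuple[str, str]] = field(repr=False)

    def digraph(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.network.graph.nodes(data=True))
        dg.add_edges_from(self.direction.values())
        return dg

    def contracted_digraph(self) -> nx.DiGraph:
        """Directed graph on observed haplotypes only.

        Chains of inferred (memberless) nodes are contracted: a directed
        path u -> x1 -> ... -> xk -> v through inferred x's becomes the
        single edge (u, v).  Inferred nodes always have graph degree 2 (they
        arise only from edge subdivision), so these chains are unambiguous.
        """
        full = self.digraph()
        observed = set(self.network.observed_nodes)
        contracted = nx.DiGraph()
        contracted.add_nodes_from(observed)
        for u in observed:
            for succ in full.successors(u):
                node = succ
                while node not in observed:
                    nexts = list(full.successors(node))
                    if not nexts:  # dangling inferred chain: cannot happen
                        node = None
                        break
                    node = nexts[0]
                if node is not None:
                    contracted.add_edge(u, node)
        return contracted


def masked_columns(alignment: SequenceAlignment) -> list[int]:
    """Indices of alignment columns containing N or '-' in any record."""
    length = alignment.length
    masked = set()
    for _, seq in alignment.records:
        for col in range(length):
            if seq[col] in "N-":
                masked.add(col)
    return sorted(masked)


def _mask(seq: str, masked: set[int]) -> str:
    return "".join(b for i, b in enumerate(seq) if i not in masked)


def collapse_haplotypes(alignment: SequenceAlignment) -> list[Haplotype]:
    """Group individuals sharing a (masked) sequence into haplotypes.

    Ids are H1, H2, ... in descending frequency, ties broken
    lexicographically by sequence.
    """
    masked = set(masked_columns(alignment))
    if len(masked) == alignment.length:
        raise InputError("every alignment column is masked; nothing to compare")
    groups: dict[str, list[str]] = {}
    for rid, seq in alignment.records:
        groups.setdefault(_mask(seq, masked), []).append(rid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Haplotype(f"H{i + 1}", seq, tuple(sorted(members)))
        for i, (seq, members) in enumerate(ordered)
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(
    haplotypes: list[Haplotype], max_connection_steps: int | None = None
) -> HaplotypeNetwork:
    """Minimum-spanning network over Hamming distances, unit-edge subdivided.

    Distance levels are processed in ascending order; at each level every
    pair of haplotypes at that distance lying in different components (as
    they stood when the level opened) is joined, so all co-minimal
    alternatives are retained.  Edges of length L > 1 are subdivided into L
    unit steps through L-1 inferred nodes whose sequences apply the
    differing sites one per step in ascending column order (starting from
    the lower-numbered haplotype).  Pairs farther apart than
    ``max_connection_steps`` are never joined.
    """
    if not haplotypes:
        raise InputError("no haplotypes")
    n = len(haplotypes)
    ids = [h.haplotype_id for h in haplotypes]
    graph = nx.Graph()
    for hap in haplotypes:
        graph.add_node(
            hap.haplotype_id,
            sequence=hap.sequence,
            frequency=hap.frequency,
            members=hap.members,
            is_inferred=False,
        )
    # distance levels
    by_dist: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = _hamming(haplotypes[i].sequence, haplotypes[j].sequence)
            if d == 0:
                raise InputError(
                    f"haplotypes {ids[i]} and {ids[j]} have identical sequences"
                )
            if max_connection_steps is None or d <= max_connection_steps:
                by_dist.setdefault(d, []).append((i, j))

    comp = list(range(n))  # union-find over observed haplotypes

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    msn_edges: list[tuple[int, int, int]] = []
    for dist in sorted(by_dist):
        snapshot = [find(i) for i in range(n)]
        added = []
        for i, j in by_dist[dist]:
            if snapshot[i] != snapshot[j]:
                msn_edges.append((i, j, dist))
                added.append((i, j))
        for i, j in added:
            comp[find(i)] = find(j)

    for i, j, dist in msn_edges:
        _add_subdivided_edge(graph, haplotypes[i], haplotypes[j], dist)
    return HaplotypeNetwork(graph, tuple(haplotypes))


def _add_subdivided_edge(
    graph: nx.Graph, ha: Haplotype, hb: Haplotype, dist: int
) -> None:
    if dist == 1:
        graph.add_edge(ha.haplotype_id, hb.haplotype_id)
        return
    diff_cols = [
        c for c, (x, y) in enumerate(zip(ha.sequence, hb.sequence)) if x != y
    ]
    seq = list(ha.sequence)
    prev = ha.haplotype_id
    for step, col in enumerate(diff_cols[:-1], start=1):
        seq[col] = hb.sequence[col]
        node = f"{ha.haplotype_id}~{hb.haplotype_id}~{step}"
        graph.add_node(
            node,
            sequence="".join(seq),
            frequency=0,
            members=(),
            is_inferred=True,
        )
        graph.add_edge(prev, node)
        prev = node
    graph.add_edge(prev, hb.haplotype_id)


def root_network(network: HaplotypeNetwork) -> RootedNetwork:
    """Root at the most prevalent haplotype and orient edges away from it.

    Tie on maximal frequency goes to the lexicographically smallest
    haplotype id.  Each edge is directed from the endpoint nearer the root
    (breadth-first distance) to the farther one; equal-depth edges (only
    possible on retained co-minimal cycles) go from the smaller node id to
    the larger.
    """
    comps = network.components
    if len(comps) > 1:
        raise NetworkError(
            f"cannot root a disconnected network; components: "
            f"{[sorted(c) for c in comps]}"
        )
    max_freq = max(h.frequency for h in network.haplotypes)
    root = min(
        h.haplotype_id for h in network.haplotypes if h.frequency == max_freq
    )
    depth = nx.single_source_shortest_path_length(network.graph, root)
    direction = {}
    for u, v in network.graph.edges():
        key = (min(u, v), max(u, v))
        if depth[u] < depth[v]:
            direction[key] = (u, v)
        elif depth[v] < depth[u]:
            direction[key] = (v, u)
        else:
            direction[key] = (min(u, v), max(u, v))
    return RootedNetwork(network, root, direction)


def network_distance(
    network: HaplotypeNetwork, individual_i: str, individual_j: str
) -> int:
    """Shortest-path length (mutational steps) between two individuals'
    haplotype nodes; 0 when they share a haplotype."""
    mapping = network.individual_to_haplotype
    for ind in (individual_i, individual_j):
        if ind not in mapping:
            raise InputError(f"unknown individual id: {ind!r}")
    a, b = mapping[individual_i], mapping[individual_j]
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(network.graph, a, b)
    except nx.NetworkXNoPath:
        raise NetworkError(
            f"individuals {individual_i!r} and {individual_j!r} lie in "
            f"different network components; distance undefined"
        ) from None


def export_network(
    rooted: RootedNetwork, traits: TraitTable, path: str | Path
) -> None:
    """Write the rooted network as GraphML with per-node trait summaries.

    Node attributes: frequency, members (comma-joined), counts of members in
    each rate category, is_inferred, is_root.
    """
    rates = traits.rates()
    dg = rooted.digraph()
    out = nx.DiGraph()
    for node, data in dg.nodes(data=True):
        members = data.get("members", ())
        missing = [m for m in members if m not in rates]
        if missing:
            raise InputError(f"no trait for members {missing} of node {node}")
        cats = [categorize_rate(rates[m]) for m in members]
        out.add_node(
            node,
            frequency=int(data.get("frequency", 0)),
            members=",".join(members),
            n_low=sum(c is RateCategory.LOW for c in cats),
            n_medium=sum(c is RateCategory.MEDIUM for c in cats),
            n_high=sum(c is RateCategory.HIGH for c in cats),
            is_inferred=bool(data.get("is_inferred", False)),
            is_root=(node == rooted.root),
        )
    out.add_edges_from(dg.edges())
    nx.write_graphml(out, str(path))
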
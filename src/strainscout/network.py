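"""Feature-based molecular networking (FBMN).

Nodes are LC-MS features (with their MS/MS spectra); edges connect spectrally
similar features. The construction mirrors the classic networking recipe:

1. remove fragment ions within +/-17 Da of the precursor and drop spectra
   left empty;
2. score all pairs with the modified cosine;
3. keep an edge when the cosine score and matched-peak count reach the
   thresholds (inclusive >= 0.5 and >= 4 by default, configurable to
   strict >);
4. keep an edge only if each endpoint ranks in the other's top-k most
   similar nodes (k = 10);
5. while any connected component exceeds the family-size cap (100), remove
   its lowest-scoring edge and recompute components.

Connected components of size >= 2 are *molecular families*; degree-0 nodes
are singletons. All tie-breaks are by canonical feature-id order so a run is
bit-reproducible and independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .data_io import Spectrum
from .occurrence import PresenceMatrix
from .similarity import SimilarityParams, modified_cosine, precursor_window_filter

__all__ = [
    "NetworkParams",
    "Edge",
    "MolecularNetwork",
    "build_network",
    "topk_prune",
    "cap_families",
    "family_exclusivity",
    "network_summary",
]


@dataclass(frozen=True)
class NetworkParams:
    """Edge and family pruning thresholds.

    min_cosine / min_matched_peaks : edge admission thresholds (0.5, 4),
        inclusive by default (``cosine_inclusive`` / ``peaks_inclusive``).
    top_k : mutual-rank neighborhood size (10).
    max_family_size : component size cap (100).
    """

    min_cosine: float = 0.5
    min_matched_peaks: int = 4
    top_k: int = 10
    max_family_size: int = 100
    cosine_inclusive: bool = True
    peaks_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_cosine <= 1:
            raise ValueError("min_cosine must be in [0, 1]")
        if self.min_matched_peaks < 1 or self.top_k < 1:
            raise ValueError("min_matched_peaks and top_k must be >= 1")
        if self.max_family_size < 2:
            raise ValueError("max_family_size must be >= 2")

    def admits(self, score: float, n_matched: int) -> bool:
        ok_s = score >= self.min_cosine if self.cosine_inclusive else score > self.min_cosine
        ok_n = (
            n_matched >= self.min_matched_peaks
            if self.peaks_inclusive
            else n_matched > self.min_matched_peaks
        )
        return ok_s and ok_n


@dataclass(frozen=True)
class Edge:
    """A scored network edge in canonical order (node_a < node_b)."""

    node_a: int
    node_b: int
    score: float
    n_matched: int

    def __post_init__(self) -> None:
        if not self.node_a < self.node_b:
            raise ValueError("edge endpoints must satisfy node_a < node_b")

    @property
    def key(self) -> tuple[int, int]:
        return (self.node_a, self.node_b)


@dataclass
class MolecularNetwork:
    """Similarity graph over features with derived families and singletons."""

    graph: nx.Graph
    params: NetworkParams
    families: list[frozenset[int]] = field(default_factory=list)
    singletons: list[int] = field(default_factory=list)

    def refresh_components(self) -> None:
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: min(c),
        )
        self.families = [c for c in comps if len(c) >= 2]
        self.singletons = sorted(n for c in comps if len(c) == 1 for n in c)

    @property
    def edges(self) -> list[Edge]:
        return [
            Edge(min(a, b), max(a, b), d["score"], d["matched_peaks"])
            for a, b, d in self.graph.edges(data=True)
        ]

    def set_node_attributes(
        self,
        mz: Mapping[int, float] | None = None,
        rt: Mapping[int, float] | None = None,
        annotation_level: Mapping[int, object] | None = None,
        class_label: Mapping[int, str] | None = None,
        provenance: Mapping[int, Iterable[str]] | None = None,
    ) -> None:
        """Attach per-node metadata used by the GraphML export."""
        for name, mapping in (
            ("mz", mz),
            ("rt", rt),
            ("level", annotation_level),
            ("class", class_label),
            ("provenance", provenance),
        ):
            if mapping is None:
                continue
            for n in self.graph.nodes:
                if n in mapping:
                    val = mapping[n]
                    if name == "provenance":
                        val = sorted(val)
                    self.graph.nodes[n][name] = val


def _rank_edges(edges: list[Edge]) -> dict[tuple[int, int], dict[int, int]]:
    """For each node, rank incident edges by score desc (ties: neighbor id)."""
    incident: dict[int, list[Edge]] = {}
    for e in edges:
        incident.setdefault(e.node_a, []).append(e)
        incident.setdefault(e.node_b, []).append(e)
    ranks: dict[tuple[int, int], dict[int, int]] = {e.key: {} for e in edges}
    for node, es in incident.items():
        es_sorted = sorted(
            es, key=lambda e: (-e.score, e.node_b if e.node_a == node else e.node_a)
        )
        for r, e in enumerate(es_sorted):
            ranks[e.key][node] = r
    return ranks


def topk_prune(edges: list[Edge], top_k: int) -> list[Edge]:
    """Keep an edge only if each endpoint is in the other's top-k by score."""
    ranks = _rank_edges(edges)
    return [
        e
        for e in edges
        if ranks[e.key][e.node_a] < top_k and ranks[e.key][e.node_b] < top_k
    ]


def cap_families(network: MolecularNetwork, max_family_size: int | None = None) -> MolecularNetwork:
    """Shrink oversized components by removing their lowest-scoring edges.

    While any connected component exceeds the cap, the globally
    lowest-scoring edge inside any oversized component is removed (ties by
    canonical edge id) and components are recomputed. Removing edges only
    refines the partition, so the loop terminates; re-capping a capped
    network is a no-op.
    """
    cap = max_family_size if max_family_size is not None else network.params.max_family_size
    g = network.graph
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > cap]
        if not oversized:
            break
        candidates = [
            (d["score"], (min(a, b), max(a, b)))
            for comp in oversized
            for a, b, d in g.subgraph(comp).edges(data=True)
        ]
        _, (a, b) = min(candidates)
        g.remove_edge(a, b)
    network.refresh_components()
    return network


def build_network(
    spectra: Mapping[int, Spectrum],
    sim: SimilarityParams | None = None,
    net: NetworkParams | None = None,
) -> MolecularNetwork:
    """Build the molecular network from feature spectra.

    Spectra emptied by the precursor-window filter are excluded from the
    network. A network with zero edges (all singletons) is valid.
    """
    sim = sim or SimilarityParams()
    net = net or NetworkParams()
    filtered: dict[int, Spectrum] = {}
    for fid in sorted(spectra):
        s = precursor_window_filter(spectra[fid], sim.precursor_window)
        if s.n_peaks > 0:
            filtered[fid] = s
    ids = sorted(filtered)
    edges: list[Edge] = []
    for idx, a in enumerate(ids):
        for b in ids[idx + 1 :]:
            res = modified_cosine(filtered[a], filtered[b], sim)
            if net.admits(res.score, res.n_matched):
                edges.append(Edge(a, b, res.score, res.n_matched))
    edges = topk_prune(edges, net.top_k)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, score=e.score, matched_peaks=e.n_matched)
    network = MolecularNetwork(graph=g, params=net)
    return cap_families(network)


def family_exclusivity(
    network: MolecularNetwork, pm: PresenceMatrix
) -> dict[int, tuple[str | None, float]]:
    """Per family: the extract with most exclusive nodes and its fraction.

    A node is *exclusive* to an extract when it is present in that extract
    and in no other. Families with fraction 1.0 are strain-exclusive: every
    member is detected in one and the same extract only. Families without
    any exclusive node report (None, 0.0). Keys are family indices in the
    order of ``network.families``.
    """
    fid_index = {f: i for i, f in enumerate(pm.feature_ids)}
    rowsums = pm.matrix.sum(axis=1)
    exclusive_extract: dict[int, str] = {}
    for f, i in fid_index.items():
        if rowsums[i] == 1:
            j = int(pm.matrix[i].argmax())
            exclusive_extract[f] = pm.sample_ids[j]
    out: dict[int, tuple[str | None, float]] = {}
    for k, family in enumerate(network.families):
        missing = [n for n in family if n not in fid_index]
        if missing:
            raise KeyError(f"presence matrix does not cover nodes {sorted(missing)}")
        counts: dict[str, int] = {}
        for n in family:
            x = exclusive_extract.get(n)
            if x is not None:
                counts[x] = counts.get(x, 0) + 1
        if not counts:
            out[k] = (None, 0.0)
        else:
            best = max(sorted(counts), key=lambda x: counts[x])
            out[k] = (best, counts[best] / len(family))
    return out


def network_summary(network: MolecularNetwork) -> dict[str, float]:
    """Node/edge/family/singleton counts and the singleton fraction."""
    n_nodes = network.graph.number_of_nodes()
    n_singletons = len(network.singletons)
    return {
        "nodes": n_nodes,
        "edges": network.graph.number_of_edges(),
        "families": len(network.families),
        "singletons": n_singletons,
        "singleton_fraction": (n_singletons / n_nodes) if n_nodes else 0.0,
    }
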
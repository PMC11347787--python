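"""Target-set algebra, PPI subnetworks, and the SOC-pathway-target network.

The network-toxicology stage works entirely from exported files: per-database
drug-target lists, disease/SOC-associated gene lists, and a STRING-style
scored edge list.  Gene symbols are uppercased on ingestion; alias resolution
is deliberately left to the user.

Topology is computed on the unweighted interaction graph (scores only filter
edges): exact degree, unnormalized shortest-path betweenness, and harmonic
closeness scaled to [0, 1], which stays well-defined on disconnected graphs.

The tripartite SOC-pathway-target network links each SOC to its selected
pathways and each pathway to its member targets; a target's *pathway degree*
(number of adjacent pathways) ranks candidate key toxicity targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TargetSet", "InteractionNetwork", "NodeMetrics", "TripartiteNetwork",
    "TargetFileError", "read_target_lists", "write_target_list",
    "union_with_provenance", "intersect_targets", "multi_set_overlap",
    "build_subnetwork", "topology_metrics", "build_tripartite",
    "rank_targets_by_pathway_degree",
]


class TargetFileError(ValueError):
    """A gene-list or edge-list file is malformed."""


@dataclass(frozen=True)
class TargetSet:
    """A named set of gene symbols (uppercased, deduplicated)."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]) -> None:
        if not name:
            raise ValueError("target set name must be non-empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(g.strip().upper() for g in genes
                                                    if g.strip()))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_target_lists(paths: Sequence[str | Path]) -> list[TargetSet]:
    """Read gene-list files (one symbol per line, or ``symbol<TAB>score``).

    The set name is the file stem.  A first row whose second column is not
    numeric is treated as a header.  An empty file yields an empty set with a
    warning; a line with more than two columns is an error naming the line.
    """
    out = []
    for path in paths:
        path = Path(path)
        genes: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n").strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) > 2:
                    raise TargetFileError(
                        f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}")
                if len(parts) == 2 and lineno == 1 and not _is_number(parts[1]):
                    continue  # header row
                if not parts[0].strip():
                    raise TargetFileError(f"{path}:{lineno}: empty gene symbol")
                genes.append(parts[0])
        if not genes:
            warnings.warn(f"empty target list: {path}")
        out.append(TargetSet(path.stem, genes))
    return out


def write_target_list(ts: TargetSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(ts.genes):
            fh.write(g + "\n")


def union_with_provenance(sets: Sequence[TargetSet],
                          ) -> tuple[TargetSet, dict[str, tuple[str, ...]]]:
    """Union of the sets plus, per symbol, the names of the sets containing it."""
    provenance: dict[str, tuple[str, ...]] = {}
    for ts in sets:
        for g in ts.genes:
            provenance[g] = provenance.get(g, ()) + (ts.name,)
    union = TargetSet("union", provenance.keys())
    return union, provenance


def intersect_targets(a: TargetSet, b: TargetSet) -> TargetSet:
    return TargetSet(f"{a.name}∩{b.name}", a.genes & b.genes)


def multi_set_overlap(sets: Sequence[TargetSet]) -> dict[tuple[str, ...], int]:
    """Exclusive overlap signatures (upset semantics).

    Each gene in the union is counted under exactly one signature: the tuple
    of names (in input order) of the sets containing it.  Counts therefore sum
    to the union cardinality.
    """
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*(ts.genes for ts in sets)) if sets else set()
    for g in union:
        sig = tuple(ts.name for ts in sets if g in ts.genes)
        counts[sig] = counts.get(sig, 0) + 1
    return counts


@dataclass
class InteractionNetwork:
    """Undirected PPI graph; edges carry a score on the 0-1000 STRING scale."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, nodes: Iterable[str],
                   scored_edges: Iterable[tuple[str, str, float]]) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(n.strip().upper() for n in nodes)
        for u, v, score in scored_edges:
            u, v = u.strip().upper(), v.strip().upper()
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if not (0 <= score <= 1000):
                raise ValueError(f"score {score} for ({u}, {v}) outside [0, 1000]")
            if u not in g or v not in g:
                raise ValueError(f"edge ({u}, {v}) references a node outside the network")
            g.add_edge(u, v, score=float(score))
        return cls(g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges with canonically ordered endpoints, sorted for determinism."""
        out = [(min(u, v), max(u, v), d["score"]) for u, v, d in self.graph.edges(data=True)]
        return sorted(out)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_subnetwork(edges_path: str | Path, nodes: TargetSet,
                     min_score: float = 400.0) -> InteractionNetwork:
    """Induced subnetwork of a STRING-style edge-list export.

    Keeps edges whose endpoints are both in ``nodes`` and whose
    ``combined_score`` is at least ``min_score`` (default 400, medium
    confidence).  Requested nodes without a surviving edge remain as isolated
    degree-0 nodes.  Expected columns: ``protein1 protein2 combined_score``
    (tab-separated; header optional).
    """
    path = Path(edges_path)
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TargetFileError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            if lineno == 1 and not _is_number(parts[2]):
                continue  # header row
            if not _is_number(parts[2]):
                raise TargetFileError(f"{path}:{lineno}: non-numeric score {parts[2]!r}")
            u, v, score = parts[0].upper().strip(), parts[1].upper().strip(), float(parts[2])
            if u == v:
                continue  # self-interactions are dropped
            if u in nodes.genes and v in nodes.genes and score >= min_score:
                edges.append((u, v, score))
    return InteractionNetwork.from_edges(nodes.genes, edges)


@dataclass(frozen=True)
class NodeMetrics:
    symbol: str
    degree: int
    betweenness: float
    closeness: float  # harmonic, scaled to [0, 1]


def topology_metrics(net: InteractionNetwork) -> list[NodeMetrics]:
    """Exact topology of every node, ranked for key-node identification.

    Degree is the incident-edge count; betweenness is unnormalized
    shortest-path betweenness (each unordered pair counted once); closeness is
    harmonic centrality divided by n-1, well-defined per reachable component
    on disconnected graphs.  Ranking: degree desc, betweenness desc, symbol.
    """
    g = net.graph
    n = g.number_of_nodes()
    betweenness = nx.betweenness_centrality(g, normalized=False)
    harmonic = nx.harmonic_centrality(g)
    metrics = [NodeMetrics(symbol=v,
                           degree=g.degree(v),
                           betweenness=betweenness[v],
                           closeness=harmonic[v] / (n - 1) if n > 1 else 0.0)
               for v in g.nodes]
    metrics.sort(key=lambda m: (-m.degree, -m.betweenness, m.symbol))
    return metrics


@dataclass(frozen=True)
class TripartiteNetwork:
    """SOC -> pathway -> target network (edges only between adjacent layers)."""

    soc_nodes: frozenset[str]
    pathway_nodes: frozenset[str]
    target_nodes: frozenset[str]
    soc_pathway_edges: frozenset[tuple[str, str]]
    pathway_target_edges: frozenset[tuple[str, str]]


def build_tripartite(soc_to_pathways: Mapping[str, Iterable[str]],
                     pathway_to_targets: Mapping[str, Iterable[str]],
                     ) -> TripartiteNetwork:
    """Assemble the SOC-pathway-target network.

    A SOC-pathway edge exists iff the pathway is among that SOC's selected
    pathways; a pathway-target edge iff the target is a member of the pathway.
    A node appearing in two layers is an error (layers must be disjoint).
    """
    socs = frozenset(soc_to_pathways)
    pathways = frozenset(pathway_to_targets) | frozenset(
        p for ps in soc_to_pathways.values() for p in ps)
    targets = frozenset(t.strip().upper() for ts in pathway_to_targets.values() for t in ts)
    clashes = (socs & pathways) | (socs & targets) | (pathways & targets)
    if clashes:
        raise ValueError(f"node(s) present in two layers: {sorted(clashes)}")
    sp = frozenset((s, p) for s, ps in soc_to_pathways.items() for p in ps)
    pt = frozenset((p, t.strip().upper())
                   for p, ts in pathway_to_targets.items() for t in ts)
    return TripartiteNetwork(socs, pathways, targets, sp, pt)


def rank_targets_by_pathway_degree(tn: TripartiteNetwork) -> list[tuple[str, int]]:
    """Targets with their pathway degree, descending; ties broken lexicographically."""
    deg = {t: 0 for t in tn.target_nodes}
    for _, t in tn.pathway_target_edges:
        deg[t] += 1
    return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
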
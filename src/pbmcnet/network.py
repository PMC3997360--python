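"""Bottom-up network construction and module mining.

The co-expression graph has an edge between two genes iff ``|r| > tau``
(strict; default tau = 0.7).  Maximal cliques are enumerated with the
Bron-Kerbosch algorithm (pivoting variant) and agglomerated by a greedy
merge: two overlapping subnetworks are merged iff the union's edge density
is at least ``gamma`` AND the union's mean absolute pairwise correlation
(over *all* member pairs, from the full correlation matrix) is at least
``alpha_corr`` (defaults 0.8 / 0.8).  Requiring both makes the guarantee
"each module's induced submatrix has average |r| above 0.8" an enforced
contract rather than a consequence of density alone.

Connectivity diagnostics follow the hierarchical-modularity convention:
per-node degree ``k`` and clustering coefficient ``C(k) = 2*T/(k*(k-1))``
within the module-induced subgraph, and the least-squares slope of
``log C(k)`` on ``log k`` (negative slope = hierarchical signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .correlation import CorrelationResult

__all__ = [
    "CoexpressionGraph",
    "GeneModule",
    "build_graph",
    "maximal_cliques",
    "merge_modules",
    "node_connectivity",
    "hierarchy_signature",
    "identify_hubs",
]


@dataclass
class CoexpressionGraph:
    """Unweighted threshold graph with |r| edge weights kept for display."""

    graph: nx.Graph
    tau: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    def adjacency(self) -> dict[str, set[str]]:
        return {v: set(self.graph.neighbors(v)) for v in self.graph.nodes}


@dataclass
class GeneModule:
    """A mined subnetwork (gene community).

    ``density`` counts edges present among members over C(m, 2);
    ``mean_abs_corr`` averages |r| over all member pairs of the full
    correlation matrix (not only pairs joined by an edge).  ``degrees`` and
    ``clustering`` are computed on the module-induced subgraph.
    """

    members: tuple[str, ...]
    density: float
    mean_abs_corr: float
    degrees: dict[str, int] = field(default_factory=dict)
    clustering: dict[str, float] = field(default_factory=dict)
    hubs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.members = tuple(sorted(self.members))
        if len(self.members) < 2:
            raise ValueError("GeneModule: needs at least 2 members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def build_graph(c: CorrelationResult, tau: float = 0.7) -> CoexpressionGraph:
    """Threshold graph: edge iff ``|r| > tau`` (strict inequality)."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("build_graph: tau must be in [0, 1)")
    g = nx.Graph()
    genes = c.genes
    g.add_nodes_from(genes)
    rmat = c.r
    for a, b in combinations(genes, 2):
        w = abs(float(rmat.loc[a, b]))
        if w > tau:
            g.add_edge(a, b, weight=w)
    return CoexpressionGraph(g, tau)


def _bron_kerbosch_pivot(
    R: set[str], P: set[str], X: set[str],
    adj: dict[str, set[str]], out: list[frozenset[str]],
) -> None:
    if not P and not X:
        out.append(frozenset(R))
        return
    pivot = max(P | X, key=lambda u: len(P & adj[u]))
    for v in list(P - adj[pivot]):
        _bron_kerbosch_pivot(R | {v}, P & adj[v], X & adj[v], adj, out)
        P.remove(v)
        X.add(v)


def _canonical_sets(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    # size descending, then lexicographic on sorted member names
    return sorted(set(sets), key=lambda s: (-len(s), tuple(sorted(s))))


def maximal_cliques(g: CoexpressionGraph) -> list[frozenset[str]]:
    """All maximal cliques, each once, size-descending then lexicographic.

    Isolated nodes are returned as singleton cliques (they are maximal).
    """
    adj = g.adjacency()
    if not adj:
        return []
    out: list[frozenset[str]] = []
    _bron_kerbosch_pivot(set(), set(adj), set(), adj, out)
    return _canonical_sets(out)


def _density(members: frozenset[str], adj: dict[str, set[str]]) -> float:
    m = len(members)
    if m < 2:
        return 1.0
    edges = sum(1 for a, b in combinations(members, 2) if b in adj[a])
    return edges / (m * (m - 1) / 2)


def _mean_abs_corr(members: frozenset[str], c: CorrelationResult) -> float:
    idx = sorted(members)
    sub = c.r.loc[idx, idx].to_numpy(dtype=float)
    m = len(idx)
    if m < 2:
        return 1.0
    iu = np.triu_indices(m, k=1)
    return float(np.mean(np.abs(sub[iu])))


def merge_modules(
    cliques: Sequence[frozenset[str]],
    c: CorrelationResult,
    g: CoexpressionGraph,
    gamma: float = 0.8,
    alpha_corr: float = 0.8,
    min_size: int = 2,
) -> list[GeneModule]:
    """Greedy density-constrained agglomeration of maximal cliques.

    Candidate pairs with overlapping membership are processed in order of
    union size (descending, ties broken lexicographically on sorted member
    names); a pair is merged iff the union's density in ``g`` is >= gamma
    and its mean |r| is >= alpha_corr, iterating to a fixpoint.  Subnetworks
    fully contained in another are absorbed.  Returned modules all satisfy
    both floors; subnetworks of fewer than ``min_size`` genes, or raw
    cliques whose mean |r| falls below ``alpha_corr``, are dropped.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("merge_modules: gamma must be in (0, 1]")
    if not 0.0 <= alpha_corr <= 1.0:
        raise ValueError("merge_modules: alpha_corr must be in [0, 1]")
    adj = g.adjacency()
    node_set = set(adj)
    for cl in cliques:
        stray = set(cl) - node_set
        if stray:
            raise ValueError(f"merge_modules: clique node(s) absent from graph: {sorted(stray)}")

    subnets = _canonical_sets(frozenset(cl) for cl in cliques)

    merged = True
    while merged:
        merged = False
        candidates: list[tuple[int, tuple[str, ...], int, int]] = []
        for i, j in combinations(range(len(subnets)), 2):
            if subnets[i] & subnets[j]:
                union = subnets[i] | subnets[j]
                candidates.append((-len(union), tuple(sorted(union)), i, j))
        for _, _, i, j in sorted(candidates):
            union = subnets[i] | subnets[j]
            if _density(union, adj) >= gamma and _mean_abs_corr(union, c) >= alpha_corr:
                rest = [s for k, s in enumerate(subnets) if k not in (i, j)]
                subnets = _canonical_sets(rest + [union])
                merged = True
                break

    # absorb fully contained subnetworks (canonical order = supersets first)
    kept: list[frozenset[str]] = []
    for s in subnets:
        if not any(s < other for other in subnets if other is not s):
            kept.append(s)
    kept = _canonical_sets(kept)

    modules: list[GeneModule] = []
    for s in kept:
        if len(s) < min_size:
            continue
        dens = _density(s, adj)
        mac = _mean_abs_corr(s, c)
        if dens < gamma or mac < alpha_corr:
            continue
        mod = GeneModule(members=tuple(sorted(s)), density=dens, mean_abs_corr=mac)
        conn = node_connectivity(g, s)
        mod.degrees = {v: k for v, (k, _) in conn.items()}
        mod.clustering = {v: ck for v, (_, ck) in conn.items()}
        modules.append(mod)
    return modules


def node_connectivity(
    g: CoexpressionGraph, members: Iterable[str]
) -> dict[str, tuple[int, float]]:
    """Per-node ``(k, C(k))`` within the member-induced subgraph.

    ``C(k) = 2*triangles(v) / (k*(k-1))`` for ``k >= 2`` and 0 otherwise.
    """
    members = set(members)
    stray = members - set(g.graph.nodes)
    if stray:
        raise ValueError(f"node_connectivity: nodes absent from graph: {sorted(stray)}")
    adj = {v: set(g.graph.neighbors(v)) & members for v in members}
    out: dict[str, tuple[int, float]] = {}
    for v in members:
        nbrs = adj[v]
        k = len(nbrs)
        if k < 2:
            out[v] = (k, 0.0)
            continue
        tri = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = (k, 2.0 * tri / (k * (k - 1)))
    return out


def hierarchy_signature(points: Iterable[tuple[int, float]]) -> float | None:
    """Least-squares slope of ``log C(k)`` on ``log k``.

    Points with ``C = 0`` (log undefined) are excluded.  Returns ``None``
    when fewer than two distinct k values remain — the signature is then
    undefined.  A negative slope is the hierarchical-modularity signature.
    """
    pts = [(k, ck) for k, ck in points if k >= 2 and ck > 0.0]
    ks = sorted({k for k, _ in pts})
    if len(ks) < 2:
        return None
    x = np.log(np.array([k for k, _ in pts], dtype=float))
    y = np.log(np.array([ck for _, ck in pts], dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def identify_hubs(
    g: CoexpressionGraph, modules: Sequence[GeneModule]
) -> dict[int, tuple[str, ...]]:
    """Hub genes per module (keyed by module position).

    A hub is adjacent to every other member of its module *and* to at least
    one node belonging to a different module.
    """
    if not modules:
        raise ValueError("identify_hubs: no modules supplied")
    membership = [m.member_set for m in modules]
    out: dict[int, tuple[str, ...]] = {}
    for i, mod in enumerate(modules):
        others: set[str] = set()
        for j, other in enumerate(membership):
            if j != i:
                others |= other - membership[i]
        hubs = []
        for v in mod.members:
            nbrs = set(g.graph.neighbors(v))
            if (mod.member_set - {v}) <= nbrs and nbrs & others:
                hubs.append(v)
        out[i] = tuple(sorted(hubs))
        mod.hubs = out[i]
    return out
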
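"""Minimal-connected-neighborhood seed expansion and enrichment statistics.

The central object is the min/max expansion: given a seed gene set, an
interaction-evidence network and a co-variation network, find the subgraph
of the evidence network that (lexicographically) first covers as many seeds
as possible in one connected component, then uses as few nodes as possible,
then as few edges, with gene-name order as the final tie-break.  This is a
Steiner-tree-style problem; a Kruskal-style component-joining heuristic is
used, replaced by a provably optimal exhaustive search whenever the
admissible instance is small enough.

Admissible non-seed nodes are
  * covariation-supported genes (a qualifying tau/p edge to at least one
    seed),
  * their gene-family mates (same fixed-length symbol prefix or explicit
    family map) when family inclusion is on — family mates never count
    toward coverage, and
  * connectors lying within ``max_path_len`` evidence hops of a seed.
When no covariation support exists and family inclusion is off, only the
seeds themselves are admissible and the result degrades to the largest
seed-only evidence component.

Also provided: top-k evidence-neighborhood recovery around a single gene,
a Poisson-density PPI edge-enrichment statistic, and hypergeometric term
over-representation.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from scipy import stats

from .covariation import CovariationNetwork
from .diffexp import bh_adjust
from .iofmt import AnnotationMap, EvidenceNetwork, GeneSet, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionParams",
    "ExpandedNeighborhood",
    "expand_neighborhood_minmax",
    "brute_force_expansion",
    "evidence_k_neighborhood",
    "ppi_enrichment",
    "term_enrichment",
    "verify_neighborhood",
]


@dataclass
class ExpansionParams:
    r_min: float = 0.6
    p_max: float = 1e-3
    family_inclusion: bool = True
    family_prefix_len: int = 3
    family_map: Mapping[str, str] | None = None
    max_path_len: int = 3
    exact_solver_node_limit: int = 14

    def __post_init__(self) -> None:
        if self.max_path_len < 1:
            raise ValueError("max_path_len must be >= 1")

    def family_of(self, gene: str) -> str:
        g = normalize_symbol(gene)
        if self.family_map:
            norm = {normalize_symbol(k): v for k, v in self.family_map.items()}
            if g in norm:
                return norm[g]
        return g[: self.family_prefix_len]


@dataclass
class ExpandedNeighborhood:
    """A connected evidence subgraph covering seeds, with node provenance.

    ``nodes`` maps each node to its provenance tag: ``seed``,
    ``covariation-supported``, ``family-included`` or ``connector``.
    """

    nodes: dict[str, str]
    edges: list[tuple[str, str]]
    seeds_covered: int
    uncovered_seeds: list[str]
    connected: bool

    @property
    def total_nodes(self) -> int:
        return len(self.nodes)

    def node_set(self) -> set[str]:
        return set(self.nodes)


# ---------------------------------------------------------------------------
# admissibility
# ---------------------------------------------------------------------------


def _admissible_instance(
    seeds: GeneSet,
    evidence: EvidenceNetwork,
    cov: CovariationNetwork | None,
    params: ExpansionParams,
):
    """Admissible node set, provenance tags, and the restricted adjacency."""
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    if evidence.n_edges == 0:
        raise ValueError("evidence network is empty")
    seed_set = set(seeds.genes)
    ev_nodes = set(evidence.nodes())
    if not seed_set & ev_nodes:
        raise ValueError(f"no seed of {seeds.name!r} is present in the evidence network")

    supported: set[str] = set()
    if cov is not None:
        supported = cov.supported_genes(seed_set, params.r_min, params.p_max) & ev_nodes

    provenance: dict[str, str] = {s: "seed" for s in seed_set}
    for g in supported:
        provenance[g] = "covariation-supported"

    if not supported and not params.family_inclusion:
        # degenerate instance: seeds only
        admissible = seed_set & ev_nodes
        adj = _restricted_adjacency(evidence, admissible)
        return admissible, provenance, adj

    family: set[str] = set()
    if params.family_inclusion:
        anchor_families = {params.family_of(g) for g in seed_set | supported}
        for g in ev_nodes:
            if g in seed_set or g in supported:
                continue
            if params.family_of(g) in anchor_families:
                family.add(g)
                provenance[g] = "family-included"

    # connectors: within max_path_len evidence hops of any seed
    full_adj: dict[str, list[str]] = {}
    for a, b, _s in evidence.edges():
        full_adj.setdefault(a, []).append(b)
        full_adj.setdefault(b, []).append(a)
    connectors: set[str] = set()
    frontier = list(seed_set & ev_nodes)
    dist = {s: 0 for s in frontier}
    for _ in range(params.max_path_len):
        nxt = []
        for u in frontier:
            for v in full_adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    for g in dist:
        if g not in seed_set and g not in supported and g not in family:
            connectors.add(g)
            provenance[g] = "connector"

    admissible = (seed_set & ev_nodes) | supported | family | connectors
    adj = _restricted_adjacency(evidence, admissible)
    return admissible, provenance, adj


def _restricted_adjacency(evidence: EvidenceNetwork, nodes: set[str]):
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b, _s in evidence.edges():
        if a in nodes and b in nodes:
            adj[a].append(b)
            adj[b].append(a)
    for n in adj:
        adj[n].sort()
    return adj


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

BRUTE_FORCE_LIMIT = 18


def _best_connected_subset(adj: dict[str, list[str]], seed_set: set[str]):
    """Optimal node subset by (max coverage, min size, lexicographic order).

    Exhaustive over all subsets of the admissible nodes; connectivity of the
    induced subgraph is required.  Returns the chosen node list (sorted).
    """
    nodes = sorted(adj)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    masks = [0] * n
    for g, nbrs in adj.items():
        for h in nbrs:
            masks[idx[g]] |= 1 << idx[h]
    seed_mask = 0
    for s in seed_set:
        if s in idx:
            seed_mask |= 1 << idx[s]

    def connected(subset: int) -> bool:
        start = subset & -subset
        seen = start
        frontier = start
        while frontier:
            reach = 0
            f = frontier
            while f:
                bit = f & -f
                f ^= bit
                reach |= masks[bit.bit_length() - 1]
            frontier = reach & subset & ~seen
            seen |= frontier
        return seen == subset

    best_key: tuple[int, int] | None = None
    best_subsets: list[int] = []
    for subset in range(1, 1 << n):
        cov = bin(subset & seed_mask).count("1")
        if cov == 0:
            continue
        size = bin(subset).count("1")
        key = (-cov, size)
        if best_key is not None and key > best_key:
            continue
        if not connected(subset):
            continue
        if best_key is None or key < best_key:
            best_key, best_subsets = key, [subset]
        else:
            best_subsets.append(subset)
    if best_key is None:
        return []
    # final tie-break: lexicographically smallest sorted node-name tuple
    def names(subset: int) -> tuple[str, ...]:
        return tuple(nodes[i] for i in range(n) if subset >> i & 1)

    return list(min(names(s) for s in best_subsets))


def _spanning_tree(adj: dict[str, list[str]], nodes: list[str]) -> list[tuple[str, str]]:
    """Deterministic (lexicographic Kruskal) spanning tree of the induced subgraph."""
    node_set = set(nodes)
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    edges = sorted(
        {(min(a, b), max(a, b)) for a in nodes for b in adj.get(a, []) if b in node_set}
    )
    tree = []
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.append((a, b))
    return tree


def _finalize(
    chosen: list[str],
    adj: dict[str, list[str]],
    seed_set: set[str],
    provenance: dict[str, str],
    all_seeds: Sequence[str],
) -> ExpandedNeighborhood:
    chosen_set = set(chosen)
    # prune non-seed leaves whose removal changes neither coverage nor
    # connectivity (on the spanning tree this is every non-seed leaf)
    tree = _spanning_tree(adj, sorted(chosen_set))
    degree: dict[str, int] = {v: 0 for v in chosen_set}
    for a, b in tree:
        degree[a] += 1
        degree[b] += 1
    changed = True
    while changed:
        changed = False
        for v in sorted(chosen_set):
            if v not in seed_set and degree.get(v, 0) <= 1 and len(chosen_set) > 1:
                chosen_set.discard(v)
                for a, b in list(tree):
                    if v in (a, b):
                        tree.remove((a, b))
                        other = b if a == v else a
                        degree[other] -= 1
                degree.pop(v, None)
                changed = True
    nodes = {v: provenance[v] for v in sorted(chosen_set)}
    covered = chosen_set & seed_set
    uncovered = sorted(set(all_seeds) - covered)
    return ExpandedNeighborhood(
        nodes=nodes,
        edges=sorted(tree),
        seeds_covered=len(covered),
        uncovered_seeds=uncovered,
        connected=True,
    )


def brute_force_expansion(
    seeds: GeneSet,
    evidence: EvidenceNetwork,
    cov: CovariationNetwork | None,
    params: ExpansionParams | None = None,
) -> ExpandedNeighborhood:
    """Provably optimal expansion by exhaustive search (test oracle)."""
    params = params or ExpansionParams()
    admissible, provenance, adj = _admissible_instance(seeds, evidence, cov, params)
    if len(adj) > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"instance has {len(adj)} admissible nodes; brute force is capped at {BRUTE_FORCE_LIMIT}"
        )
    seed_set = set(seeds.genes)
    chosen = _best_connected_subset(adj, seed_set)
    if not chosen:
        raise ValueError("no seed is present in the admissible evidence subgraph")
    result = _finalize(chosen, adj, seed_set, provenance, seeds.genes)
    assert verify_neighborhood(result, seeds, evidence, cov, params)
    return result


# ---------------------------------------------------------------------------
# Kruskal-style Steiner heuristic
# ---------------------------------------------------------------------------


def _cheapest_join(
    adj: dict[str, list[str]],
    comp_a: set[str],
    comp_b: set[str],
    in_result: set[str],
):
    """Cheapest path from comp_a to comp_b: cost = (# new nodes, # edges).

    Dijkstra with 0/1 node weights (nodes already in the result are free);
    returns (cost, n_edges, path) or None if unreachable.
    """
    heap: list[tuple[int, int, str]] = []
    best: dict[str, tuple[int, int]] = {}
    parent: dict[str, str | None] = {}
    for s in sorted(comp_a):
        heap.append((0, 0, s))
        best[s] = (0, 0)
        parent[s] = None
    heapq.heapify(heap)
    while heap:
        cost, edges, u = heapq.heappop(heap)
        if (cost, edges) > best.get(u, (math.inf, math.inf)):
            continue
        if u in comp_b:
            path = [u]
            while parent[u] is not None:
                u = parent[u]
                path.append(u)
            return cost, edges, path[::-1]
        for v in adj[u]:
            step = 0 if (v in in_result or v in comp_b) else 1
            cand = (cost + step, edges + 1)
            if cand < best.get(v, (math.inf, math.inf)):
                best[v] = cand
                parent[v] = u
                heapq.heappush(heap, (cand[0], cand[1], v))
    return None


def expand_neighborhood_minmax(
    seeds: GeneSet,
    evidence: EvidenceNetwork,
    cov: CovariationNetwork | None,
    params: ExpansionParams | None = None,
) -> ExpandedNeighborhood:
    """Min/max expansion of a seed set to a minimal connected neighborhood.

    Lexicographic objective: maximize seeds in one connected component of
    the returned subgraph, then minimize node count, then edge count, then
    node-name order.  The Kruskal-style heuristic repeatedly joins the two
    seed components reachable by the cheapest admissible path; instances
    with at most ``exact_solver_node_limit`` admissible nodes are solved
    exactly instead.  Seeds unreachable under the constraints are reported
    uncovered, never allowed to force a disconnected result.
    """
    params = params or ExpansionParams()
    admissible, provenance, adj = _admissible_instance(seeds, evidence, cov, params)
    seed_set = set(seeds.genes)

    if len(adj) <= params.exact_solver_node_limit:
        chosen = _best_connected_subset(adj, seed_set)
        if not chosen:
            raise ValueError("no seed is present in the admissible evidence subgraph")
        result = _finalize(chosen, adj, seed_set, provenance, seeds.genes)
        assert verify_neighborhood(result, seeds, evidence, cov, params)
        return result

    comps: list[set[str]] = [{s} for s in sorted(seed_set & set(adj))]
    if not comps:
        raise ValueError("no seed is present in the admissible evidence subgraph")
    extra_nodes: set[str] = set()
    chosen_edges: set[tuple[str, str]] = set()
    while len(comps) > 1:
        in_result = set().union(*comps) | extra_nodes
        best = None
        for i, j in itertools.combinations(range(len(comps)), 2):
            join = _cheapest_join(adj, comps[i], comps[j], in_result)
            if join is None:
                continue
            cost, edges, path = join
            key = (cost, edges, tuple(sorted(path)))
            if best is None or key < best[0]:
                best = (key, i, j, path)
        if best is None:
            break
        _key, i, j, path = best
        merged = comps[i] | comps[j] | set(path)
        extra_nodes |= set(path) - seed_set
        for a, b in zip(path, path[1:]):
            chosen_edges.add((min(a, b), max(a, b)))
        rest = [c for k, c in enumerate(comps) if k not in (i, j)]
        # a zero-cost path may run through another component's nodes;
        # absorb any component it touches
        comps = []
        for c in rest:
            if c & merged:
                merged |= c
            else:
                comps.append(c)
        comps.append(merged)

    # choose the best remaining component: most seeds, then fewest nodes,
    # then lexicographic
    def comp_key(c: set[str]):
        return (-len(c & seed_set), len(c), tuple(sorted(c)))

    chosen_comp = min(comps, key=comp_key)
    sub_adj = {
        v: [u for u in adj[v] if u in chosen_comp and (min(u, v), max(u, v)) in chosen_edges]
        for v in chosen_comp
    }
    if len(chosen_comp) == 1:
        sub_adj = {v: [] for v in chosen_comp}
    result = _finalize(sorted(chosen_comp), sub_adj, seed_set, provenance, seeds.genes)
    assert verify_neighborhood(result, seeds, evidence, cov, params)
    return result


def verify_neighborhood(
    result: ExpandedNeighborhood,
    seeds: GeneSet,
    evidence: EvidenceNetwork,
    cov: CovariationNetwork | None,
    params: ExpansionParams,
) -> bool:
    """Independent check of connectivity and every node's provenance tag."""
    nodes = result.node_set()
    if not nodes:
        return False
    # connectivity over the reported edges
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in result.edges:
        if a not in nodes or b not in nodes or not evidence.has_edge(a, b):
            return False
        adj[a].add(b)
        adj[b].add(a)
    start = next(iter(sorted(nodes)))
    seen = {start}
    stack = [start]
    while stack:
        for v in adj[stack.pop()]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if seen != nodes:
        return False

    seed_set = set(seeds.genes)
    supported = (
        cov.supported_genes(seed_set, params.r_min, params.p_max) if cov is not None else set()
    )
    anchor_families = {params.family_of(g) for g in seed_set | supported}
    for v, tag in result.nodes.items():
        if tag == "seed":
            if v not in seed_set:
                return False
        elif tag == "covariation-supported":
            if v not in supported:
                return False
        elif tag == "family-included":
            if params.family_of(v) not in anchor_families or not params.family_inclusion:
                return False
        elif tag != "connector":
            return False
    if result.seeds_covered != len(nodes & seed_set):
        return False
    return True


# ---------------------------------------------------------------------------
# neighborhood recovery, PPI enrichment, term over-representation
# ---------------------------------------------------------------------------


def evidence_k_neighborhood(seed: str, evidence: EvidenceNetwork, k: int) -> GeneSet:
    """The seed plus its k highest-scoring evidence neighbors (ties by name)."""
    s = normalize_symbol(seed)
    if s not in set(evidence.nodes()):
        raise KeyError(f"seed {s!r} is absent from the evidence network")
    nbrs = sorted(evidence.neighbors(s), key=lambda t: (-t[1], t[0]))
    return GeneSet(name=f"{s}_k{k}", genes=[s] + [g for g, _ in nbrs[:k]])


class PPIEnrichment(NamedTuple):
    observed_edges: int
    expected_edges: float
    p_value: float


def ppi_enrichment(genes: GeneSet, evidence: EvidenceNetwork) -> PPIEnrichment:
    """Upper-tail Poisson test of edge count within a gene set.

    expected = (number of gene pairs) x (global edge density of the
    background network); p = P(Poisson(expected) >= observed).  This is a
    density null computable from the local edge file alone, not a
    degree-corrected null.
    """
    if len(genes) < 2:
        raise ValueError("ppi_enrichment needs at least 2 genes")
    background = set(evidence.nodes())
    outside = [g for g in genes if g not in background]
    if outside:
        logger.warning("%d gene(s) absent from background network (degree 0): %s",
                       len(outside), outside)
    members = set(genes.genes)
    observed = sum(1 for a, b, _ in evidence.edges() if a in members and b in members)
    n_pairs = len(genes) * (len(genes) - 1) / 2
    expected = n_pairs * evidence.density()
    if expected == 0:
        p = 1.0 if observed == 0 else 0.0
    else:
        p = float(stats.poisson.sf(observed - 1, expected))
    return PPIEnrichment(observed, expected, p)


class TermEnrichmentRow(NamedTuple):
    term_id: str
    term_name: str
    k: int
    K: int
    p_value: float
    q_value: float


def term_enrichment(
    genes: GeneSet,
    annotation: AnnotationMap,
    background: GeneSet,
) -> list[TermEnrichmentRow]:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Per term with K members in the background: p = P(X >= k) for the
    overlap k of n query genes drawn from the N-gene background; q by BH
    across tested terms.  Terms with K = 0 are skipped.
    """
    bg = set(background.genes)
    query = set(genes.genes)
    if len(bg) < len(query):
        raise ValueError("background is smaller than the query gene set")
    if not query <= bg:
        raise ValueError(f"query genes outside background: {sorted(query - bg)}")
    N, n = len(bg), len(query)
    rows = []
    for tid, (tname, term_genes) in sorted(annotation.items()):
        K = len(set(term_genes) & bg)
        if K == 0:
            continue
        k = len(set(term_genes) & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((tid, tname, k, K, min(p, 1.0)))
    qs = bh_adjust([r[4] for r in rows])
    out = [TermEnrichmentRow(tid, tname, k, K, p, q)
           for (tid, tname, k, K, p), q in zip(rows, qs)]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out
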
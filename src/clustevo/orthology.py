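"""Orthogroup construction.

Cross-species orthogroups are an input (precomputed Jaccard-style
assignments). Genes absent from them are *species-specific*; those are
grouped here by filtering all-vs-all protein similarity hits and running
Markov clustering (MCL) per species, then merged with the precomputed
orthogroups into one registry that partitions the gene set.

MCL alternates expansion (matrix power, flow spreading) and inflation
(elementwise power, flow sharpening) of a column-stochastic matrix until
convergence; clusters are read off the attractors of the limit matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import Gene, Orthogroup, OrthogroupRegistry


@dataclass(frozen=True)
class MclParams:
    """Markov-clustering parameters.

    inflation > 1 controls granularity (2.0 is the conventional default
    and the value used throughout this pipeline); expansion is the matrix
    power (2 = one step of random-walk spreading). Entries below
    prune_threshold are zeroed each iteration to keep the matrix sparse in
    effect; iteration stops when the max absolute entry change drops below
    convergence_tol.
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-6
    max_iter: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self):
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if not (isinstance(self.expansion, int) and self.expansion >= 2):
            raise ValueError("expansion must be an integer >= 2")


def filter_hits(hits, min_cov=0.60, max_evalue=1e-5, min_identity=60.0):
    """Build an unweighted similarity graph from BLAST hits.

    An edge (a, b) exists iff at least one hit in either direction has
    query AND subject coverage >= min_cov (inclusive), e-value < max_evalue
    (strict) and percent identity > min_identity (strict). When several
    HSPs exist for a directed pair only the best-bitscore one is
    evaluated — no HSP tiling.
    """
    best: dict[tuple, object] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    graph = nx.Graph()
    for h in best.values():
        graph.add_node(h.query_id)
        graph.add_node(h.subject_id)
        if (
            h.query_cov >= min_cov
            and h.subject_cov >= min_cov
            and h.evalue < max_evalue
            and h.pct_identity > min_identity
        ):
            graph.add_edge(h.query_id, h.subject_id, weight=1.0)
    return graph


def _mcl_component(adj: np.ndarray, params: MclParams):
    """Run MCL on one dense adjacency block; return (converged, limit M)."""
    a = adj.astype(float).copy()
    n = a.shape[0]
    # Self-loops: max incident weight per node, floored at 1.
    loops = np.maximum(a.max(axis=0), 1.0) if n > 1 else np.ones(1)
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)
    converged = False
    for _ in range(params.max_iter):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = expanded ** params.inflation
        inflated[inflated < params.prune_threshold] = 0.0
        colsum = inflated.sum(axis=0)
        dead = colsum == 0.0
        if dead.any():  # pruning emptied a column; restore pre-inflation flow
            inflated[:, dead] = expanded[:, dead]
            colsum = inflated.sum(axis=0)
        inflated /= colsum
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < params.convergence_tol:
            converged = True
            break
    return converged, m


def _read_clusters(m: np.ndarray, params: MclParams):
    """Interpret the MCL limit matrix as a partition of node indices.

    Attractors are nodes with residual self-flow; each attractor's cluster
    is the set of nodes flowing into it. Overlapping attractor clusters are
    merged into attractor systems; a non-attractor node reached by several
    systems is assigned to the system containing the lowest-sorted node
    (deterministic tie-break), and unreached nodes become singletons.
    """
    n = m.shape[0]
    thr = params.prune_threshold
    attractors = [i for i in range(n) if m[i, i] > thr]
    supports = {i: set(np.nonzero(m[i] > thr)[0]) | {i} for i in attractors}
    # Union-find over attractors whose supports overlap.
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if i < j and supports[i] & supports[j] & set(attractors):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    systems: dict[int, set] = {}
    for i in attractors:
        systems.setdefault(find(i), set()).update(supports[i])
    # Assign each node to exactly one system (lowest-sorted member wins).
    roots = sorted(systems, key=lambda r: min(systems[r]))
    assigned: dict[int, int] = {}
    for r in roots:
        for node in systems[r]:
            if node not in assigned:
                assigned[node] = r
    clusters: dict[int, set] = {}
    for node in range(n):
        if node in assigned:
            clusters.setdefault(assigned[node], set()).add(node)
        else:
            clusters[node] = {node}  # unreached: singleton
    return [frozenset(c) for c in clusters.values()]


def mcl_cluster(graph: nx.Graph, params: MclParams | None = None):
    """Deterministic Markov clustering of an undirected weighted graph.

    Returns a sorted list of frozensets of node ids forming a partition of
    the graph's nodes. Connected components are clustered independently
    (MCL flow never crosses components). Non-convergence within
    ``max_iter`` emits a warning and uses the current matrix.
    """
    params = params or MclParams()
    result = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            result.append(frozenset(nodes))
            continue
        idx = {node: i for i, node in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.subgraph(comp).edges(data=True):
            w = data.get("weight", 1.0)
            if w <= 0:
                raise ValueError("edge weights must be positive")
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
        converged, m = _mcl_component(adj, params)
        if not converged:
            warnings.warn(
                f"MCL did not converge within {params.max_iter} iterations "
                f"on a component of {len(nodes)} nodes; using current "
                "partition"
            )
        for cl in _read_clusters(m, params):
            result.append(frozenset(nodes[i] for i in cl))
    return sorted(result, key=lambda c: min(c))


def species_specific_partition(graph, genes: dict, base_covered,
                               params: MclParams | None = None):
    """Cluster genes absent from the base orthogroups, one MCL per species.

    Only within-species edges among leftover genes are used (cross-species
    edges among leftovers are ignored); genes with no passing hit are left
    out, to become singleton orthogroups during assembly.
    """
    leftovers = [g for g in genes.values() if g.gene_id not in base_covered]
    by_species: dict[str, list] = {}
    for g in leftovers:
        by_species.setdefault(g.species, []).append(g.gene_id)
    partition = []
    for sp in sorted(by_species):
        members = set(by_species[sp])
        sub = nx.Graph()
        nodes_in_graph = members & set(graph.nodes)
        sub.add_nodes_from(sorted(nodes_in_graph))
        for u, v, data in graph.edges(data=True):
            if u in members and v in members:
                sub.add_edge(u, v, **data)
        for cl in mcl_cluster(sub, params):
            if len(cl) > 1:
                partition.append(cl)
    return sorted(partition, key=lambda c: min(c))


def assemble_orthogroups(base, leftover_partition, all_genes: dict
                         ) -> OrthogroupRegistry:
    """Merge base orthogroups, MCL clusters, and singletons into a registry.

    The result is a partition of ``all_genes``: each leftover cluster
    becomes a species-specific orthogroup with a generated id, and genes in
    neither become singleton orthogroups. Overlap between the base
    orthogroups and the leftover partition is a hard error.
    """
    base = list(base)
    covered = set()
    for og in base:
        covered.update(og.genes())
    stray = covered - set(all_genes)
    if stray:
        raise ValueError(
            f"base orthogroups reference unknown gene(s): {sorted(stray)[:5]}"
        )
    merged = list(base)
    counter = 0
    for cluster in sorted(leftover_partition, key=lambda c: min(c)):
        overlap = set(cluster) & covered
        if overlap:
            raise ValueError(
                f"leftover cluster contains base-assigned gene(s): "
                f"{sorted(overlap)[:5]}"
            )
        counter += 1
        members: dict[str, set] = {}
        for gid in cluster:
            members.setdefault(all_genes[gid].species, set()).add(gid)
        merged.append(
            Orthogroup(
                og_id=f"SSOG{counter:06d}",
                members={sp: frozenset(gs) for sp, gs in members.items()},
            )
        )
        covered.update(cluster)
    for gid in sorted(set(all_genes) - covered):
        counter += 1
        merged.append(
            Orthogroup(
                og_id=f"SSOG{counter:06d}",
                members={all_genes[gid].species: frozenset({gid})},
            )
        )
    registry = OrthogroupRegistry(merged)
    assert registry.covered_genes() == frozenset(all_genes)
    return registry


def build_orthogroups(hits, base, genes: dict,
                      params: MclParams | None = None,
                      min_cov=0.60, max_evalue=1e-5, min_identity=60.0
                      ) -> OrthogroupRegistry:
    """End-to-end: filter hits, MCL the species-specific genes, assemble."""
    covered = set()
    for og in base:
        covered.update(og.genes())
    graph = filter_hits(hits, min_cov=min_cov, max_evalue=max_evalue,
                        min_identity=min_identity)
    partition = species_specific_partition(graph, genes, covered, params)
    return assemble_orthogroups(base, partition, genes)
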
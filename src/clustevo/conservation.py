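"""Pairwise SM gene-cluster homology and species-specificity accounting.

Two clusters from different species are homologous when more than half of
the genes in the larger cluster are orthologous to genes of the smaller
cluster AND more than half of the smaller cluster's genes are orthologous
to genes of the larger one (strict > on both fractions). "Orthologous"
includes inparalogs: a gene counts as matched if its orthogroup contains
any gene of the other cluster.

Species-specificity is read off the connected components of the homology
graph, so many-to-one relationships (two clusters in one species
homologous to one in another) are honored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .types import GeneCluster, OrthogroupRegistry


@dataclass(frozen=True)
class ClusterPairScore:
    cluster_a: str
    cluster_b: str
    shared_orthogroups: int
    frac_large: float
    frac_small: float
    homologous: bool


@dataclass(frozen=True)
class SpeciesClusterStats:
    species: str
    n_clusters: int
    n_species_specific: int
    fraction_specific: float


@dataclass(frozen=True)
class ClusterConservationSummary:
    per_species: tuple  # of SpeciesClusterStats
    subset_counts: dict  # frozenset of species -> number of components
    components: tuple  # of frozensets of cluster ids


def _matched_fraction(cluster: GeneCluster, other_genes: set,
                      ogs: OrthogroupRegistry) -> float:
    matched = 0
    for gid in cluster.gene_ids:
        og = ogs.of_gene(gid)
        if og is not None and not other_genes.isdisjoint(og.genes()):
            matched += 1
    return matched / len(cluster.gene_ids)


def score_cluster_pair(a: GeneCluster, b: GeneCluster,
                       ogs: OrthogroupRegistry) -> ClusterPairScore:
    """Score one cross-species cluster pair. Symmetric in (a, b).

    When the clusters tie in size both are treated as "larger":
    ``frac_large`` is the max and ``frac_small`` the min of the two
    per-side fractions, keeping the score symmetric.
    """
    if a.species == b.species:
        raise ValueError(
            f"clusters {a.cluster_id!r} and {b.cluster_id!r} share species "
            f"{a.species!r}"
        )
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty cluster")
    genes_a, genes_b = set(a.gene_ids), set(b.gene_ids)
    frac_a = _matched_fraction(a, genes_b, ogs)
    frac_b = _matched_fraction(b, genes_a, ogs)
    if len(a) > len(b):
        frac_large, frac_small = frac_a, frac_b
    elif len(b) > len(a):
        frac_large, frac_small = frac_b, frac_a
    else:
        frac_large, frac_small = max(frac_a, frac_b), min(frac_a, frac_b)
    shared = {
        ogs.of_gene(g).og_id
        for g in a.gene_ids
        if ogs.of_gene(g) is not None
        and not genes_b.isdisjoint(ogs.of_gene(g).genes())
    }
    return ClusterPairScore(
        cluster_a=a.cluster_id,
        cluster_b=b.cluster_id,
        shared_orthogroups=len(shared),
        frac_large=frac_large,
        frac_small=frac_small,
        homologous=frac_large > 0.5 and frac_small > 0.5,
    )


def homology_components(clusters: dict, ogs: OrthogroupRegistry
                        ) -> ClusterConservationSummary:
    """Connected components of the cross-species cluster homology graph.

    A cluster is species-specific iff its component contains no cluster
    from another species. ``subset_counts`` reports, per exact species
    subset, how many components span it; the counts sum to the number of
    components.
    """
    graph = nx.Graph()
    ids = sorted(clusters)
    graph.add_nodes_from(ids)
    for i, cid_a in enumerate(ids):
        for cid_b in ids[i + 1:]:
            a, b = clusters[cid_a], clusters[cid_b]
            if a.species == b.species:
                continue
            if score_cluster_pair(a, b, ogs).homologous:
                graph.add_edge(cid_a, cid_b)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    subset_counts = Counter(
        frozenset(clusters[cid].species for cid in comp)
        for comp in components
    )
    specific = {
        cid
        for comp in components
        if len({clusters[c].species for c in comp}) == 1
        for cid in comp
    }
    per_species = []
    for sp in sorted({c.species for c in clusters.values()}):
        sp_ids = [cid for cid in ids if clusters[cid].species == sp]
        n_spec = sum(1 for cid in sp_ids if cid in specific)
        per_species.append(
            SpeciesClusterStats(
                species=sp,
                n_clusters=len(sp_ids),
                n_species_specific=n_spec,
                fraction_specific=n_spec / len(sp_ids) if sp_ids else float("nan"),
            )
        )
    return ClusterConservationSummary(
        per_species=tuple(per_species),
        subset_counts=dict(subset_counts),
        components=tuple(components),
    )


def cluster_link_profile(focal: GeneCluster, all_clusters: dict,
                         ogs: OrthogroupRegistry):
    """Orthology links from one cluster into every other cluster.

    For each other cluster (any species, including the focal species) the
    link count is the number of focal genes whose orthogroup contains at
    least one gene of that cluster; same-species links are flagged as
    inparalog links and zero-count pairs are omitted. The focal cluster
    itself is excluded.
    """
    links = []
    for cid in sorted(all_clusters):
        other = all_clusters[cid]
        if other.cluster_id == focal.cluster_id:
            continue
        other_genes = set(other.gene_ids)
        count = 0
        for gid in focal.gene_ids:
            og = ogs.of_gene(gid)
            if og is not None and not other_genes.isdisjoint(og.genes()):
                count += 1
        if count:
            links.append(
                {
                    "focal_cluster": focal.cluster_id,
                    "other_cluster": other.cluster_id,
                    "other_species": other.species,
                    "shared_gene_count": count,
                    "inparalog": other.species == focal.species,
                }
            )
    return links


def homology_link_rows(clusters: dict, ogs: OrthogroupRegistry):
    """Cluster-cluster link rows (for TSV export) over all species pairs."""
    rows = []
    ids = sorted(clusters)
    for i, cid_a in enumerate(ids):
        for cid_b in ids[i + 1:]:
            a, b = clusters[cid_a], clusters[cid_b]
            if a.species == b.species:
                continue
            score = score_cluster_pair(a, b, ogs)
            if score.shared_orthogroups:
                rows.append(
                    {
                        "cluster_a": score.cluster_a,
                        "cluster_b": score.cluster_b,
                        "shared_orthogroups": score.shared_orthogroups,
                        "frac_large": round(score.frac_large, 6),
                        "frac_small": round(score.frac_small, 6),
                        "homologous": score.homologous,
                    }
                )
    return rows
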
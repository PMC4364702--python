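"""Core domain types shared across the pipeline.

The unit of all conservation logic is the *orthogroup*: a cross-species set
of genes presumed descended from a single gene in the species' common
ancestor, possibly including within-species duplicates (inparalogs).
Secondary-metabolite (SM) gene clusters are ordered sets of physically
clustered genes in one species, anchored by a backbone synthase gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Functional category tokens accepted in gene tables.
CATEGORIES = frozenset(
    {"primary_metabolism", "sm_backbone", "sm_clustered", "development"}
)


@dataclass(frozen=True)
class Gene:
    """A species-tagged gene with functional-category flags.

    Invariants (enforced by :func:`validate`):

    * ``cluster_id`` is set if and only if ``sm_clustered`` is among the
      categories;
    * ``sm_backbone`` implies ``sm_clustered`` (backbone genes are
      clustered genes).
    """

    gene_id: str
    species: str
    categories: frozenset = frozenset()
    cluster_id: str | None = None
    go_terms: frozenset = frozenset()

    def validate(self) -> None:
        unknown = self.categories - CATEGORIES
        if unknown:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown category token(s) "
                f"{sorted(unknown)}"
            )
        clustered = "sm_clustered" in self.categories
        if (self.cluster_id is not None) != clustered:
            raise ValueError(
                f"gene {self.gene_id!r}: cluster_id "
                f"{'set without' if self.cluster_id else 'missing despite'} "
                "sm_clustered category"
            )
        if "sm_backbone" in self.categories and not clustered:
            raise ValueError(
                f"gene {self.gene_id!r}: sm_backbone requires sm_clustered"
            )


@dataclass(frozen=True)
class GeneCluster:
    """An SM gene cluster: ordered gene ids in one species.

    ``backbone_ids`` is the subset encoding the core synthase(s)
    (NRPS/PKS/hybrid/prenyltransferase).
    """

    cluster_id: str
    species: str
    gene_ids: tuple
    backbone_ids: frozenset = frozenset()

    def __post_init__(self):
        if not set(self.backbone_ids) <= set(self.gene_ids):
            raise ValueError(
                f"cluster {self.cluster_id!r}: backbone ids outside cluster"
            )

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Orthogroup:
    """A cross-species gene family: mapping species -> frozenset of gene ids."""

    og_id: str
    members: dict

    def genes(self):
        for sp in sorted(self.members):
            yield from sorted(self.members[sp])

    def species(self) -> frozenset:
        return frozenset(sp for sp, gs in self.members.items() if gs)

    def size(self) -> int:
        return sum(len(g) for g in self.members.values())


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein similarity hit (best HSP of a directed pair)."""

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float
    query_cov: float
    subject_cov: float


class OrthogroupRegistry:
    """Orthogroups keyed by id with a gene -> orthogroup reverse index.

    Construction fails if any gene is listed in two orthogroups, so the
    registry is a partition of the genes it covers by construction.
    """

    def __init__(self, orthogroups):
        self._by_id: dict[str, Orthogroup] = {}
        self._by_gene: dict[str, Orthogroup] = {}
        for og in orthogroups:
            if og.og_id in self._by_id:
                raise ValueError(f"duplicate orthogroup id {og.og_id!r}")
            if og.size() == 0:
                raise ValueError(f"orthogroup {og.og_id!r} is empty")
            self._by_id[og.og_id] = og
            for g in og.genes():
                if g in self._by_gene:
                    raise ValueError(
                        f"gene {g!r} listed in orthogroups "
                        f"{self._by_gene[g].og_id!r} and {og.og_id!r}"
                    )
                self._by_gene[g] = og

    def __len__(self):
        return len(self._by_id)

    def __iter__(self):
        return iter(sorted(self._by_id.values(), key=lambda og: og.og_id))

    def __contains__(self, og_id):
        return og_id in self._by_id

    def get(self, og_id: str) -> Orthogroup:
        return self._by_id[og_id]

    def of_gene(self, gene_id: str) -> Orthogroup | None:
        """Orthogroup containing ``gene_id``, or None if unplaced."""
        return self._by_gene.get(gene_id)

    def covered_genes(self) -> frozenset:
        return frozenset(self._by_gene)

    def partition(self) -> set:
        """The partition as a set of frozensets of gene ids."""
        return {frozenset(og.genes()) for og in self._by_id.values()}


def clusters_from_genes(genes: dict) -> dict:
    """Assemble :class:`GeneCluster` records from a gene registry.

    Gene order within a cluster follows registry (input file) order.
    Raises if genes of one cluster id span several species.
    """
    order: dict[str, list] = {}
    species: dict[str, str] = {}
    backbone: dict[str, set] = {}
    for g in genes.values():
        if g.cluster_id is None:
            continue
        order.setdefault(g.cluster_id, []).append(g.gene_id)
        backbone.setdefault(g.cluster_id, set())
        if "sm_backbone" in g.categories:
            backbone[g.cluster_id].add(g.gene_id)
        prev = species.setdefault(g.cluster_id, g.species)
        if prev != g.species:
            raise ValueError(
                f"cluster {g.cluster_id!r} spans species {prev!r} and "
                f"{g.species!r}"
            )
    return {
        cid: GeneCluster(
            cluster_id=cid,
            species=species[cid],
            gene_ids=tuple(order[cid]),
            backbone_ids=frozenset(backbone[cid]),
        )
        for cid in sorted(order)
    }
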
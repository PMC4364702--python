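"""Seeded synthetic multi-species worlds with planted ground truth.

A world emulates the comparative setup the pipeline analyzes: several
fungal species with heavy species-specific secondary-metabolite (SM)
content, cross-species gene families (orthogroups) with occasional
inparalogs, SM gene clusters of 2-25 genes with tunable pairwise
conservation, GO annotations (including the developmental-process term
GO:0032502), and two-replicate negative-binomial RNA-seq counts with
planted knockout log2 fold-change effects copied across conserved
orthologs with a configurable probability.

Everything is a deterministic function of the seed; the ground-truth
ledger records the planted orthogroup partition, the planted homologous
cluster pairs and their coverage fractions, per-gene knockout targets with
their true effects, and per-category species-specific orthogroup counts,
so recovery tests can compare pipeline output against construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .types import Gene, Orthogroup, clusters_from_genes

DEV_TERM = "GO:0032502"  # developmental process
SM_TERM = "GO:0019748"  # secondary metabolic process

_DEFAULT_SPECIES = ("Afum", "Anid", "Anig", "Aory")


def _default_family_sharing(species):
    """Default subset weights: heavy species-specific content, a conserved
    core spanning all species, thin pairwise sharing."""
    species = tuple(species)
    sharing = {species: 0.45}
    pairs = [
        (a, b) for i, a in enumerate(species) for b in species[i + 1:]
    ]
    for p in pairs:
        sharing[p] = 0.12 / len(pairs)
    remaining = 1.0 - sum(sharing.values())
    for sp in species:
        sharing[(sp,)] = remaining / len(species)
    return sharing


def _default_de_targets():
    # Fractions of each compartment's genes affected per knockout,
    # emulating a broad regulator (veA-like) and a narrow one (mtfA-like).
    return {
        "veA": {
            "sm_under": 0.35, "sm_over": 0.12,
            "dev_under": 0.20, "dev_over": 0.08,
            "other_under": 0.13, "other_over": 0.11,
        },
        "mtfA": {
            "sm_under": 0.20, "sm_over": 0.06,
            "dev_under": 0.04, "dev_over": 0.06,
            "other_under": 0.04, "other_over": 0.03,
        },
    }


@dataclass
class WorldConfig:
    seed: int = 0
    species: tuple = _DEFAULT_SPECIES
    genes_per_species: int = 2000
    family_sharing: dict | None = None  # subset tuple -> probability
    n_clusters_per_species: object = 20  # int or {species: int}
    cluster_size_range: tuple = (2, 25)  # uniform over inclusive range
    planted_conserved_pairs: tuple = ()  # (sp_a, sp_b, count, f)
    planted_pair_size: int = 10  # genes per planted cluster (f * size integer)
    cluster_shared_gene_prob: float = 0.10
    inparalog_prob: float = 0.08
    category_fractions: dict = field(
        default_factory=lambda: {"primary_metabolism": 0.30,
                                 "development": 0.05}
    )
    de_targets: dict = field(default_factory=_default_de_targets)
    expressed_species: tuple | None = None  # default: first two species
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    nb_mean_log: float = float(np.log(500.0))
    nb_mean_sigma: float = 1.0
    nb_dispersion: float = 0.2
    depth_sigma: float = 0.1
    regulation_copy_prob: float = 0.6
    hit_dropout: float = 0.0  # noise: prob of dropping a within-group hit
    n_filler_terms: int = 10

    def __post_init__(self):
        self.species = tuple(self.species)
        if self.family_sharing is None:
            self.family_sharing = _default_family_sharing(self.species)
        if self.expressed_species is None:
            self.expressed_species = self.species[:2]
        self.expressed_species = tuple(self.expressed_species)
        for prob in (self.cluster_shared_gene_prob, self.inparalog_prob,
                     self.regulation_copy_prob, self.hit_dropout):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cluster_size_range[0] < 2:
            raise ValueError("cluster sizes must be >= 2")

    def n_clusters(self, sp: str) -> int:
        if isinstance(self.n_clusters_per_species, dict):
            return self.n_clusters_per_species[sp]
        return int(self.n_clusters_per_species)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    genes: dict  # gene_id -> Gene
    clusters: dict  # cluster_id -> GeneCluster
    base_orthogroups: list  # cross-species Orthogroups (the "given" table)
    true_partition: list  # every family, incl. species-specific, as frozensets
    hits: list  # SimilarityHit rows (raw tuples for writing)
    counts: dict  # (species, regulator) -> (DataFrame, conditions Series)
    annotations: dict  # gene_id -> frozenset of GO terms (fine or slim)
    slim_map: dict
    truth: dict


class _Builder:
    def __init__(self, config: WorldConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.counters = {sp: 0 for sp in config.species}
        self.genes: dict[str, dict] = {}  # gene_id -> attribute dict
        self.families: list[dict] = []  # {id?, members: {sp: [gene_ids]}}

    def new_gene(self, sp: str) -> str:
        self.counters[sp] += 1
        gid = f"{sp}_g{self.counters[sp]:05d}"
        self.genes[gid] = {
            "species": sp, "categories": set(), "cluster_id": None,
        }
        return gid

    def new_family(self, members: dict) -> dict:
        fam = {"members": members}
        self.families.append(fam)
        return fam

    def quota_met(self) -> bool:
        return all(
            self.counters[sp] >= self.cfg.genes_per_species
            for sp in self.cfg.species
        )


def _check_feasible(cfg: WorldConfig):
    planted_per_species: dict[str, int] = {sp: 0 for sp in cfg.species}
    for sp_a, sp_b, count, f in cfg.planted_conserved_pairs:
        for sp in (sp_a, sp_b):
            if sp not in planted_per_species:
                raise ValueError(f"planted pair references unknown species {sp!r}")
            planted_per_species[sp] += count
        k = f * cfg.planted_pair_size
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"coverage fraction {f} is not a multiple of "
                f"1/{cfg.planted_pair_size}"
            )
        if not 0.0 <= f <= 1.0:
            raise ValueError("coverage fraction must lie in [0, 1]")
    for sp in cfg.species:
        if planted_per_species[sp] > cfg.n_clusters(sp):
            raise ValueError(
                f"{sp}: planted conserved pairs ({planted_per_species[sp]}) "
                f"exceed cluster count ({cfg.n_clusters(sp)})"
            )
        sm_budget = (
            planted_per_species[sp] * cfg.planted_pair_size
            + (cfg.n_clusters(sp) - planted_per_species[sp])
            * cfg.cluster_size_range[1]
        )
        if sm_budget > cfg.genes_per_species:
            raise ValueError(
                f"{sp}: worst-case SM gene demand ({sm_budget}) exceeds "
                f"genes_per_species ({cfg.genes_per_species})"
            )
    return planted_per_species


def _build_clusters(b: _Builder):
    """Planted conserved pairs first, then species-specific clusters."""
    cfg = b.cfg
    cluster_counter = {sp: 0 for sp in cfg.species}
    planted_pairs = []

    def next_cluster(sp):
        cluster_counter[sp] += 1
        return f"{sp}_c{cluster_counter[sp]:02d}"

    for sp_a, sp_b, count, f in cfg.planted_conserved_pairs:
        m = cfg.planted_pair_size
        k = int(round(f * m))
        for _ in range(count):
            cid_a, cid_b = next_cluster(sp_a), next_cluster(sp_b)
            genes_a, genes_b = [], []
            for i in range(m):
                ga, gb = b.new_gene(sp_a), b.new_gene(sp_b)
                genes_a.append(ga)
                genes_b.append(gb)
                if i < k:  # shared orthogroup across the pair
                    b.new_family({sp_a: [ga], sp_b: [gb]})
                else:  # private singleton families on both sides
                    b.new_family({sp_a: [ga]})
                    b.new_family({sp_b: [gb]})
            for cid, sp, glist in ((cid_a, sp_a, genes_a),
                                   (cid_b, sp_b, genes_b)):
                for j, gid in enumerate(glist):
                    b.genes[gid]["categories"].add("sm_clustered")
                    if j == 0:
                        b.genes[gid]["categories"].add("sm_backbone")
                    b.genes[gid]["cluster_id"] = cid
            planted_pairs.append(
                {"cluster_a": cid_a, "cluster_b": cid_b, "f": f,
                 "expected_homologous": f > 0.5}
            )

    for sp in cfg.species:
        lo, hi = cfg.cluster_size_range
        while cluster_counter[sp] < cfg.n_clusters(sp):
            cid = next_cluster(sp)
            size = int(b.rng.integers(lo, hi + 1))
            for j in range(size):
                gid = b.new_gene(sp)
                b.genes[gid]["categories"].add("sm_clustered")
                if j == 0:
                    b.genes[gid]["categories"].add("sm_backbone")
                b.genes[gid]["cluster_id"] = cid
                if b.rng.random() < cfg.cluster_shared_gene_prob:
                    # Ortholog recruited from outside SM clusters elsewhere:
                    # a cross-species family whose foreign members stay
                    # background genes.
                    others = [s for s in cfg.species if s != sp]
                    n_other = int(b.rng.integers(1, len(others) + 1))
                    chosen = list(
                        b.rng.choice(others, size=n_other, replace=False)
                    )
                    members = {sp: [gid]}
                    for osp in chosen:
                        members[osp] = [b.new_gene(osp)]
                    b.new_family(members)
                else:
                    b.new_family({sp: [gid]})
    return planted_pairs


def _fill_background(b: _Builder):
    cfg = b.cfg
    subsets = sorted(cfg.family_sharing)
    weights = np.array([cfg.family_sharing[s] for s in subsets], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("family_sharing weights must be non-negative")
    weights = weights / weights.sum()
    guard = 0
    while not b.quota_met():
        guard += 1
        if guard > 100 * cfg.genes_per_species * len(cfg.species):
            raise RuntimeError("background fill did not terminate")
        subset = subsets[int(b.rng.choice(len(subsets), p=weights))]
        if all(b.counters[sp] >= cfg.genes_per_species for sp in subset):
            continue
        members = {}
        for sp in subset:
            n_copies = 1 + (b.rng.random() < cfg.inparalog_prob)
            members[sp] = [b.new_gene(sp) for _ in range(n_copies)]
        b.new_family(members)


def _assign_categories(b: _Builder):
    cfg = b.cfg
    p_pm = cfg.category_fractions.get("primary_metabolism", 0.0)
    p_dev = cfg.category_fractions.get("development", 0.0)
    n_species = len(cfg.species)
    for fam in b.families:
        gene_ids = [g for gs in fam["members"].values() for g in gs]
        is_sm = any(b.genes[g]["cluster_id"] is not None for g in gene_ids)
        if not is_sm and b.rng.random() < p_pm:
            for g in gene_ids:
                b.genes[g]["categories"].add("primary_metabolism")
        # Development is drawn preferentially from fully conserved families,
        # emulating the high conservation of developmental genes.
        span = len(fam["members"])
        p = p_dev * (1.6 if span == n_species else 0.25)
        if b.rng.random() < min(p, 1.0):
            for g in gene_ids:
                b.genes[g]["categories"].add("development")


def similarity_from_partition(families, gene_species, rng,
                              hit_dropout: float = 0.0):
    """Emit BLAST-like rows recovering within-species inparalog groups.

    For every within-species group of >= 2 genes of a species-specific
    family, all pairwise hits passing the filter thresholds are emitted
    (dropped independently with probability ``hit_dropout``); decoy hits
    failing exactly one threshold (identity == 60, e-value == 1e-5, or
    coverage < 0.6) connect random genes of different groups so that
    filtering plus clustering must actively reject them.

    Returns rows as 14-tuples in extended outfmt-6 column order.
    """
    rows = []
    lengths: dict[str, int] = {}
    multi_groups = []
    singles = []
    for fam in families:
        if len(fam["members"]) != 1:
            continue  # cross-species families are in the base table
        (sp, gene_ids), = fam["members"].items()
        length = int(rng.integers(200, 601))
        for g in gene_ids:
            lengths[g] = length
        if len(gene_ids) >= 2:
            multi_groups.append((sp, sorted(gene_ids)))
        else:
            singles.append((sp, gene_ids[0]))

    def row(q, s, pident, evalue, cov):
        ql, sl = lengths[q], lengths[s]
        alen = max(1, int(np.floor(cov * min(ql, sl))))
        bit = round(float(rng.uniform(100, 500)), 1)
        return (q, s, round(pident, 1), alen, 0, 0, 1, alen, 1, alen,
                evalue, bit, ql, sl)

    for sp, group in multi_groups:
        for i, qg in enumerate(group):
            for sg in group[i + 1:]:
                if hit_dropout and rng.random() < hit_dropout:
                    continue
                pident = float(rng.uniform(70, 95))
                evalue = float(10.0 ** -rng.uniform(10, 50))
                rows.append(row(qg, sg, pident, evalue, 0.85))

    # Sub-threshold decoys between distinct species-specific groups (a
    # decoy inside a group would shadow its passing hit under the
    # best-bitscore-HSP rule).
    group_of: dict[str, int] = {}
    by_sp: dict[str, list] = {}
    for gi, (sp, grp) in enumerate(multi_groups):
        for g in grp:
            group_of[g] = gi
            by_sp.setdefault(sp, []).append(g)
    for gi, (sp, g) in enumerate(singles, start=len(multi_groups)):
        group_of[g] = gi
        by_sp.setdefault(sp, []).append(g)
    decoy_kinds = ("identity", "evalue", "coverage")
    n_decoys = max(len(multi_groups), len(singles) // 4)
    for i in range(n_decoys):
        sp = sorted(by_sp)[int(rng.integers(0, len(by_sp)))]
        if len(by_sp[sp]) < 2:
            continue
        q, s = rng.choice(by_sp[sp], size=2, replace=False)
        if group_of[q] == group_of[s]:
            continue
        kind = decoy_kinds[i % 3]
        if kind == "identity":
            rows.append(row(q, s, 60.0, 1e-30, 0.85))  # == 60: strict >
        elif kind == "evalue":
            rows.append(row(q, s, 80.0, 1e-5, 0.85))  # == 1e-5: strict <
        else:
            rows.append(row(q, s, 80.0, 1e-30, 0.5))  # cov < 0.6
    return rows, lengths


def _nb_counts(rng, mean, dispersion, size):
    # NB with Var = m + dispersion * m^2: shape n = 1/dispersion.
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _select_targets(b: _Builder, regulator: str, species: str,
                    fractions: dict, prior_targets: dict | None):
    """Per-gene (direction, lfc) targets for one knockout in one species.

    ``prior_targets`` maps gene_id -> direction for the previously
    processed expressed species; a gene with a targeted conserved ortholog
    there is itself targeted (same direction) with probability q, and only
    genes without such orthologs fall back to the independent per-category
    fractions.
    """
    cfg = b.cfg
    rng = b.rng
    gene_to_family = {}
    for fam in b.families:
        for gs in fam["members"].values():
            for g in gs:
                gene_to_family[g] = fam
    targets: dict[str, tuple] = {}

    def draw_lfc(direction):
        mag = abs(rng.normal(cfg.lfc_mean, cfg.lfc_sd))
        mag = max(mag, 0.5)
        return mag if direction == "over" else -mag

    for gid in sorted(g for g, a in b.genes.items()
                      if a["species"] == species):
        attrs = b.genes[gid]
        prior_dirs = []
        if prior_targets is not None:
            fam = gene_to_family[gid]
            for sp, gs in fam["members"].items():
                if sp == species:
                    continue
                prior_dirs.extend(
                    prior_targets[g] for g in gs if g in prior_targets
                )
        if prior_dirs:
            if rng.random() < cfg.regulation_copy_prob:
                direction = prior_dirs[0]
                targets[gid] = (direction, draw_lfc(direction))
            continue
        if attrs["cluster_id"] is not None:
            p_under, p_over = fractions["sm_under"], fractions["sm_over"]
        elif "development" in attrs["categories"]:
            p_under, p_over = fractions["dev_under"], fractions["dev_over"]
        else:
            p_under, p_over = fractions["other_under"], fractions["other_over"]
        u = rng.random()
        if u < p_under:
            targets[gid] = ("under", draw_lfc("under"))
        elif u < p_under + p_over:
            targets[gid] = ("over", draw_lfc("over"))
    return targets


def _simulate_counts(b: _Builder, species: str, base_mean: dict,
                     targets: dict):
    cfg = b.cfg
    rng = b.rng
    gene_ids = sorted(g for g, a in b.genes.items()
                      if a["species"] == species)
    samples = ["WT_1", "WT_2", "MUT_1", "MUT_2"]
    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=len(samples)))
    mu = np.array([base_mean[g] for g in gene_ids])
    fold = np.array(
        [2.0 ** targets[g][1] if g in targets else 1.0 for g in gene_ids]
    )
    mat = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        m = mu * depth[j] * (fold if sample.startswith("MUT") else 1.0)
        mat[:, j] = _nb_counts(rng, m, cfg.nb_dispersion,
                               size=len(gene_ids))
    counts = pd.DataFrame(mat, index=gene_ids, columns=samples)
    conditions = pd.Series(
        ["WT", "WT", "mutant", "mutant"], index=samples
    )
    return counts, conditions


def _annotations(b: _Builder):
    cfg = b.cfg
    rng = b.rng
    fillers = [f"GO:SLIM{i:02d}" for i in range(1, cfg.n_filler_terms + 1)]
    fine_of = {t: f"GO:F{i:04d}" for i, t in enumerate(fillers, 1)}
    slim_map = {t: t for t in fillers + [DEV_TERM, SM_TERM]}
    slim_map.update({fine_of[t]: t for t in fillers})
    ann: dict[str, set] = {}
    for gid in sorted(b.genes):
        attrs = b.genes[gid]
        terms = set()
        if "development" in attrs["categories"]:
            terms.add(DEV_TERM)
        if attrs["cluster_id"] is not None:
            terms.add(SM_TERM)
        n_extra = int(rng.integers(1, 3))
        for t in rng.choice(fillers, size=n_extra, replace=False):
            # Half the time emit the fine-grained synonym to exercise the
            # term -> slim collapse.
            terms.add(fine_of[t] if rng.random() < 0.5 else t)
        ann[gid] = frozenset(terms)
    return ann, slim_map


def _strict_specific_counts(b: _Builder):
    counts: dict = {}
    for sp in b.cfg.species:
        for cat in ("primary_metabolism", "sm_backbone", "sm_clustered"):
            n = n_spec = 0
            for fam in b.families:
                has_cat = any(
                    cat in b.genes[g]["categories"]
                    for g in fam["members"].get(sp, ())
                )
                if not has_cat:
                    continue
                n += 1
                n_spec += len(fam["members"]) == 1
            counts[f"{sp}:{cat}"] = {"n_orthogroups": n, "n_specific": n_spec}
    return counts


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world (deterministic per seed)."""
    _check_feasible(config)
    b = _Builder(config)
    planted_pairs = _build_clusters(b)
    _fill_background(b)
    _assign_categories(b)

    genes = {}
    for gid in b.genes:  # preserve creation order (cluster order matters)
        a = b.genes[gid]
        gene = Gene(
            gene_id=gid,
            species=a["species"],
            categories=frozenset(a["categories"]),
            cluster_id=a["cluster_id"],
        )
        gene.validate()
        genes[gid] = gene
    clusters = clusters_from_genes(genes)

    base = []
    og_counter = 0
    for fam in b.families:
        if len(fam["members"]) > 1:
            og_counter += 1
            base.append(
                Orthogroup(
                    og_id=f"OG{og_counter:05d}",
                    members={sp: frozenset(gs)
                             for sp, gs in fam["members"].items()},
                )
            )
    true_partition = [
        frozenset(g for gs in fam["members"].values() for g in gs)
        for fam in b.families
    ]

    gene_species = {g: a["species"] for g, a in b.genes.items()}
    hit_rows, _lengths = similarity_from_partition(
        b.families, gene_species, b.rng, hit_dropout=config.hit_dropout
    )

    # Baseline expression: family-level means so orthologs are correlated.
    base_mean: dict[str, float] = {}
    for fam in b.families:
        fam_mu = float(
            np.exp(b.rng.normal(config.nb_mean_log, config.nb_mean_sigma))
        )
        for gs in fam["members"].values():
            for g in gs:
                base_mean[g] = fam_mu * float(np.exp(b.rng.normal(0, 0.2)))

    counts = {}
    truth_targets: dict = {}
    for regulator in sorted(config.de_targets):
        fractions = config.de_targets[regulator]
        prior: dict | None = None
        for sp in config.expressed_species:
            targets = _select_targets(b, regulator, sp, fractions, prior)
            counts[(sp, regulator)] = _simulate_counts(
                b, sp, base_mean, targets
            )
            truth_targets[f"{sp}:{regulator}"] = {
                g: {"direction": d, "log2fc": round(l, 6)}
                for g, (d, l) in sorted(targets.items())
            }
            prior = {g: d for g, (d, _) in targets.items()}

    annotations, slim_map = _annotations(b)

    truth = {
        "seed": config.seed,
        "species": list(config.species),
        "true_partition": sorted(sorted(fs) for fs in true_partition),
        "planted_pairs": planted_pairs,
        "targets": truth_targets,
        "strict_specific_counts": _strict_specific_counts(b),
        "regulation_copy_prob": config.regulation_copy_prob,
    }
    return SyntheticWorld(
        config=config,
        genes=genes,
        clusters=clusters,
        base_orthogroups=base,
        true_partition=true_partition,
        hits=hit_rows,
        counts=counts,
        annotations=annotations,
        slim_map=slim_map,
        truth=truth,
    )


def write_world(world: SyntheticWorld, outdir) -> Path:
    """Write every pipeline input file plus the ground-truth ledger."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_gene_table(world.genes, out / "genes.tsv")
    cio.write_orthogroups(world.base_orthogroups, out / "orthogroups.tsv")
    with open(out / "hits.tsv", "w") as fh:
        for r in world.hits:
            fh.write("\t".join(
                f"{x:.6g}" if isinstance(x, float) else str(x) for x in r
            ) + "\n")
    for (sp, regulator), (counts, conditions) in sorted(world.counts.items()):
        cio.write_counts(counts, out / f"counts_{sp}_{regulator}.tsv")
        pd.DataFrame(
            {"sample": conditions.index, "condition": conditions.values}
        ).to_csv(out / f"design_{sp}_{regulator}.tsv", sep="\t", index=False)
    rows = [
        {"gene_id": g, "term": t}
        for g in sorted(world.annotations)
        for t in sorted(world.annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(
        out / "go_annotations.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(world.slim_map.items()), columns=["term", "slim_term"]
    ).to_csv(out / "slim_map.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(world.truth, fh, indent=1, sort_keys=True)
    return out
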
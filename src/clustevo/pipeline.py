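"""End-to-end orchestration: run the full analysis on a world directory
(or an in-memory synthetic world) and collect one JSON-able report.

Stages: orthogroup assembly (filter + MCL + merge), SM cluster homology
and species-specificity accounting, orthogroup specificity statistics with
Fisher tests, per-knockout differential expression and Table-1-style
summaries, cross-species concordance, and GO-slim enrichment of the
under-/over-expressed sets.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import conservation, diffexpr, enrichment, io, orthology
from . import specificity as spec
from .orthology import MclParams
from .synthetic import DEV_TERM, SyntheticWorld
from .types import clusters_from_genes


def load_world_dir(path):
    """Load every pipeline input from a directory written by write_world."""
    path = Path(path)
    genes = io.read_gene_table(path / "genes.tsv")
    base = io.read_orthogroups(path / "orthogroups.tsv")
    hits = io.read_similarity_hits(path / "hits.tsv")
    counts = {}
    for f in sorted(path.glob("counts_*.tsv")):
        sp, regulator = f.stem.split("_")[1:3]
        design = io.read_design(path / f"design_{sp}_{regulator}.tsv")
        mat = io.read_counts(f)
        io.check_expression_genes(mat.index, genes)
        counts[(sp, regulator)] = (mat, design)
    annotations = io.read_go_annotations(
        path / "go_annotations.tsv", known_genes=genes
    )
    slim_map = io.read_slim_map(path / "slim_map.tsv")
    return {
        "genes": genes,
        "base": base,
        "hits": hits,
        "counts": counts,
        "annotations": annotations,
        "slim_map": slim_map,
    }


def world_inputs(world: SyntheticWorld):
    from .types import SimilarityHit

    hits = []
    for r in world.hits:
        if r[0] == r[1]:
            continue
        hits.append(
            SimilarityHit(
                query_id=r[0], subject_id=r[1], pct_identity=float(r[2]),
                evalue=float(r[10]), bitscore=float(r[11]),
                query_cov=float(r[3]) / float(r[12]),
                subject_cov=float(r[3]) / float(r[13]),
            )
        )
    return {
        "genes": world.genes,
        "base": world.base_orthogroups,
        "hits": hits,
        "counts": world.counts,
        "annotations": world.annotations,
        "slim_map": world.slim_map,
    }


def run_pipeline(inputs: dict, mcl_params: MclParams | None = None) -> dict:
    """Run every stage; return a nested result dict plus live objects."""
    genes = inputs["genes"]
    ogs = orthology.build_orthogroups(
        inputs["hits"], inputs["base"], genes, params=mcl_params
    )
    clusters = clusters_from_genes(genes)
    cluster_summary = conservation.homology_components(clusters, ogs)
    spec_rows = spec.specificity_table(genes, ogs)
    fisher_rows = spec.fisher_specificity_tests(genes, ogs)
    species = sorted({g.species for g in genes.values()})
    escape = {
        sp: spec.sm_unclustered_elsewhere_fraction(genes, ogs, sp)
        for sp in species
    }

    de_tables = {}
    de_summaries = {}
    for (sp, regulator), (counts, conditions) in sorted(
        inputs["counts"].items()
    ):
        table = diffexpr.de_table(counts, conditions)
        de_tables[(sp, regulator)] = table
        sm_genes = {
            g.gene_id for g in genes.values()
            if g.species == sp and g.cluster_id is not None
        }
        dev_genes = {
            g for g, terms in inputs["annotations"].items()
            if DEV_TERM in terms and g in genes and genes[g].species == sp
        }
        de_summaries[(sp, regulator)] = diffexpr.summarize(
            table,
            {"all": set(table.index), "sm_cluster": sm_genes,
             "development": dev_genes},
        )

    concordance_results = {}
    regs = sorted({reg for (_, reg) in de_tables})
    for regulator in regs:
        expressed = sorted(sp for (sp, r) in de_tables if r == regulator)
        if len(expressed) < 2:
            continue
        sp_a, sp_b = expressed[:2]
        rec_a, rec_b = de_tables[(sp_a, regulator)], de_tables[(sp_b, regulator)]
        sm_a = {g.gene_id for g in genes.values()
                if g.species == sp_a and g.cluster_id is not None}
        flags = conc.flags_table(rec_a, sp_b, ogs, rec_b, gene_set=sm_a)
        concordance_results[(regulator, sp_a, sp_b)] = {
            cls: conc.concordance_summary(flags, cls)
            for cls in ("under", "over")
        }

    enrich_results = {}
    for (sp, regulator), table in de_tables.items():
        background = {
            g for g in table.index
            if g in inputs["annotations"] and g in genes
        }
        for cls in ("under", "over"):
            study = set(table.index[table["de_class"] == cls]) & background
            if not study:
                continue
            enrich_results[(sp, regulator, cls)] = enrichment.enrich(
                study, background, inputs["annotations"],
                slim_map=inputs["slim_map"],
            )

    return {
        "orthogroups": ogs,
        "clusters": clusters,
        "cluster_summary": cluster_summary,
        "specificity": spec_rows,
        "fisher": fisher_rows,
        "sm_unclustered_elsewhere": escape,
        "de_tables": de_tables,
        "de_summaries": de_summaries,
        "concordance": concordance_results,
        "enrichment": enrich_results,
    }
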
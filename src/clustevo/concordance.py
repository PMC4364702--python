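"""Cross-species concordance of differential expression.

DE classes are mapped between two species through orthogroups. For each
classified gene three nested existential flags are computed relative to a
named partner species: does any orthogroup member in the partner species
exist (has_ortholog), is any of them differentially expressed
(has_de_ortholog), and does any share the gene's own direction
(has_same_direction_ortholog)?

Summary percentages follow the denominators of the printed arithmetic:
"had an ortholog" is a percentage of the DE-class gene set; "had a DE
ortholog" and "similarly expressed" are percentages of the
ortholog-bearing subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexpr import round1
from .types import OrthogroupRegistry


@dataclass(frozen=True)
class ConcordanceFlags:
    gene_id: str
    de_class: str
    has_ortholog: bool
    has_de_ortholog: bool
    has_same_direction_ortholog: bool


@dataclass(frozen=True)
class ConcordanceSummary:
    n_in_class: int
    n_with_ortholog: int
    n_with_de_ortholog: int
    n_with_same_direction: int
    pct_with_ortholog: float  # of n_in_class; nan when undefined
    pct_with_de_ortholog: float  # of n_with_ortholog
    pct_with_same_direction: float  # of n_with_ortholog


def _partner_classes(gene_id, partner_species, ogs, partner_records):
    og = ogs.of_gene(gene_id)
    if og is None:
        raise KeyError(f"gene {gene_id!r} absent from orthogroup registry")
    partners = sorted(og.members.get(partner_species, ()))
    classes = []
    for p in partners:
        if p in partner_records.index:
            classes.append(partner_records.loc[p, "de_class"])
        else:
            classes.append("not_de")  # present but untested/unmeasured
    return classes


def gene_flags(gene_id: str, de_class: str, partner_species: str,
               ogs: OrthogroupRegistry, partner_records: pd.DataFrame
               ) -> ConcordanceFlags:
    """Existential ortholog flags for one classified gene."""
    classes = _partner_classes(gene_id, partner_species, ogs, partner_records)
    has_ortholog = bool(classes)
    has_de = any(c in ("over", "under") for c in classes)
    same_dir = de_class in ("over", "under") and any(
        c == de_class for c in classes
    )
    return ConcordanceFlags(
        gene_id=gene_id,
        de_class=de_class,
        has_ortholog=has_ortholog,
        has_de_ortholog=has_de,
        has_same_direction_ortholog=same_dir,
    )


def flags_table(records: pd.DataFrame, partner_species: str,
                ogs: OrthogroupRegistry, partner_records: pd.DataFrame,
                gene_set=None) -> pd.DataFrame:
    """Flags for every (optionally set-restricted) gene of one species."""
    ids = records.index if gene_set is None else records.index.intersection(
        list(gene_set)
    )
    rows = []
    for gid in ids:
        f = gene_flags(gid, records.loc[gid, "de_class"], partner_species,
                       ogs, partner_records)
        rows.append(
            {
                "gene_id": f.gene_id,
                "de_class": f.de_class,
                "has_ortholog": f.has_ortholog,
                "has_de_ortholog": f.has_de_ortholog,
                "has_same_direction_ortholog": f.has_same_direction_ortholog,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "de_class", "has_ortholog", "has_de_ortholog",
                 "has_same_direction_ortholog"],
    ).set_index("gene_id")


def concordance_summary(flags: pd.DataFrame, de_class_filter: str
                        ) -> ConcordanceSummary:
    """Counts and one-decimal percentages for one DE class."""
    sub = flags[flags["de_class"] == de_class_filter]
    n = len(sub)
    n_orth = int(sub["has_ortholog"].sum())
    n_de = int(sub["has_de_ortholog"].sum())
    n_same = int(sub["has_same_direction_ortholog"].sum())
    return ConcordanceSummary(
        n_in_class=n,
        n_with_ortholog=n_orth,
        n_with_de_ortholog=n_de,
        n_with_same_direction=n_same,
        pct_with_ortholog=round1(100.0 * n_orth / n) if n else float("nan"),
        pct_with_de_ortholog=round1(100.0 * n_de / n_orth)
        if n_orth else float("nan"),
        pct_with_same_direction=round1(100.0 * n_same / n_orth)
        if n_orth else float("nan"),
    )


def _link_category(class_a: str, class_b: str) -> str:
    if class_a == class_b:
        return {
            "over": "both_over",
            "under": "both_under",
            "not_de": "both_not",
        }[class_a]
    return "conflicting" if "over" in (class_a, class_b) or "under" in (
        class_a, class_b
    ) else "both_not"


def link_table(species_a: str, species_b: str, gene_set_a, gene_set_b,
               ogs: OrthogroupRegistry, records_a: pd.DataFrame,
               records_b: pd.DataFrame) -> list:
    """Gene-gene links: one row per cross-species pair sharing an orthogroup.

    Both genes must lie in the given sets and in the classified records.
    Categories: both_under / both_over / both_not when classes agree,
    conflicting when they differ and at least one is DE.
    """
    set_a = set(gene_set_a) & set(records_a.index)
    set_b = set(gene_set_b) & set(records_b.index)
    rows = []
    for og in ogs:
        a_members = sorted(set(og.members.get(species_a, ())) & set_a)
        b_members = sorted(set(og.members.get(species_b, ())) & set_b)
        for ga in a_members:
            for gb in b_members:
                ca = records_a.loc[ga, "de_class"]
                cb = records_b.loc[gb, "de_class"]
                rows.append(
                    {
                        "gene_a": ga,
                        "gene_b": gb,
                        "og_id": og.og_id,
                        "class_a": ca,
                        "class_b": cb,
                        "category": _link_category(ca, cb),
                    }
                )
    rows.sort(key=lambda r: (r["gene_a"], r["gene_b"]))
    return rows


def collapse_links_by_orthogroup(links: list) -> dict:
    """Per-orthogroup link-category counts (one vote per orthogroup).

    An orthogroup's category is both_X when every pair agrees on both_X,
    otherwise conflicting if any pair conflicts, else mixed_not_de.
    """
    by_og: dict[str, set] = {}
    for row in links:
        by_og.setdefault(row["og_id"], set()).add(row["category"])
    counts: dict[str, int] = {}
    for cats in by_og.values():
        if len(cats) == 1:
            label = next(iter(cats))
        elif "conflicting" in cats:
            label = "conflicting"
        else:
            label = "mixed_not_de"
        counts[label] = counts.get(label, 0) + 1
    return counts
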
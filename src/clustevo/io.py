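"""Readers and writers for every external table the pipeline touches.

All files are plain TSV. Identifiers are case-sensitive; species labels are
free strings. Written tables are sorted lexicographically by their first
two key columns so that re-running on the same input is byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .types import Gene, Orthogroup, OrthogroupRegistry, SimilarityHit

GENE_TABLE_COLUMNS = ["gene_id", "species", "categories", "cluster_id"]

#: Standard 12 BLAST outfmt-6 fields plus query/subject sequence lengths.
BLAST14_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "slen",
]


def read_gene_table(path) -> dict:
    """Read a gene table into an ordered ``{gene_id: Gene}`` registry.

    Expected header: gene_id, species, categories (semicolon-joined,
    possibly empty), cluster_id (possibly empty). Duplicate gene ids and
    unknown category tokens are hard errors; the category/cluster cross
    invariants of :class:`Gene` are enforced per row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing column(s) {missing}")
    genes: dict[str, Gene] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in genes:
            raise ValueError(f"{path}: duplicate gene_id {row.gene_id!r}")
        cats = frozenset(t for t in row.categories.split(";") if t)
        gene = Gene(
            gene_id=row.gene_id,
            species=row.species,
            categories=cats,
            cluster_id=row.cluster_id or None,
        )
        gene.validate()
        genes[row.gene_id] = gene
    return genes


def write_gene_table(genes: dict, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "species": g.species,
            "categories": ";".join(sorted(g.categories)),
            "cluster_id": g.cluster_id or "",
        }
        for g in genes.values()
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_orthogroups(path) -> list:
    """Read (og_id, species, gene_id) rows into a list of Orthogroups.

    A gene listed under two orthogroup ids is a hard error. The partition
    check against the full gene registry is deferred to
    :func:`clustevo.orthology.assemble_orthogroups`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("og_id", "species", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: orthogroup table missing {col!r}")
    members: dict[str, dict] = {}
    seen: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in seen and seen[row.gene_id] != row.og_id:
            raise ValueError(
                f"{path}: gene {row.gene_id!r} in orthogroups "
                f"{seen[row.gene_id]!r} and {row.og_id!r}"
            )
        seen[row.gene_id] = row.og_id
        members.setdefault(row.og_id, {}).setdefault(row.species, set()).add(
            row.gene_id
        )
    return [
        Orthogroup(og_id=og_id, members={sp: frozenset(gs) for sp, gs in m.items()})
        for og_id, m in sorted(members.items())
    ]


def write_orthogroups(orthogroups, path) -> None:
    rows = []
    for og in orthogroups:
        for sp in sorted(og.members):
            for g in sorted(og.members[sp]):
                rows.append({"og_id": og.og_id, "species": sp, "gene_id": g})
    rows.sort(key=lambda r: (r["og_id"], r["species"], r["gene_id"]))
    pd.DataFrame(rows, columns=["og_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_similarity_hits(path, lengths=None) -> list:
    """Read BLAST-tabular similarity hits.

    Accepts 14 columns (outfmt 6 extended with qlen and slen) or, with a
    companion ``lengths`` TSV (gene_id, length), the standard 12 columns.
    Per-side coverage is the aligned-span length divided by the sequence
    length. Self-hits are discarded; an alignment longer than either
    sequence is a hard error (malformed input).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 14:
        df.columns = BLAST14_COLUMNS
    elif df.shape[1] == 12:
        if lengths is None:
            raise ValueError(
                f"{path}: 12-column BLAST input requires a lengths table "
                "(qlen/slen columns absent)"
            )
        lens = pd.read_csv(lengths, sep="\t", dtype={0: str})
        lens.columns = ["gene_id", "length"][: lens.shape[1]]
        lmap = dict(zip(lens["gene_id"], lens["length"]))
        df.columns = BLAST14_COLUMNS[:12]
        try:
            df["qlen"] = [lmap[q] for q in df["qseqid"]]
            df["slen"] = [lmap[s] for s in df["sseqid"]]
        except KeyError as exc:
            raise ValueError(f"{path}: no length for gene {exc.args[0]!r}")
    else:
        raise ValueError(
            f"{path}: expected 12 or 14 tab-separated columns, "
            f"got {df.shape[1]}"
        )
    hits = []
    for row in df.itertuples(index=False):
        if row.qseqid == row.sseqid:
            continue
        if row.length > row.qlen or row.length > row.slen:
            raise ValueError(
                f"{path}: alignment length {row.length} exceeds sequence "
                f"length for pair ({row.qseqid}, {row.sseqid})"
            )
        hits.append(
            SimilarityHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                pct_identity=float(row.pident),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                query_cov=float(row.length) / float(row.qlen),
                subject_cov=float(row.length) / float(row.slen),
            )
        )
    return hits


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids in count matrix")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    """Read a (sample, condition) design table into a sample->condition map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"{path}: design table missing {col!r}")
    return pd.Series(df["condition"].values, index=df["sample"].values)


def read_go_annotations(path, known_genes=None) -> dict:
    """Read a 2-column (gene_id, term) GAF-lite TSV into gene -> term set.

    Rows for genes missing from ``known_genes`` (when given) raise a
    warning rather than an error and are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs 2 columns")
    gene_col, term_col = df.columns[:2]
    ann: dict[str, set] = {}
    unknown = set()
    for g, t in zip(df[gene_col], df[term_col]):
        if known_genes is not None and g not in known_genes:
            unknown.add(g)
        ann.setdefault(g, set()).add(t)
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} annotated gene(s) absent from gene "
            "table (kept)"
        )
    return {g: frozenset(ts) for g, ts in ann.items()}


def read_slim_map(path) -> dict:
    """Read a 2-column (term, slim_term) mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: slim map needs 2 columns")
    a, b = df.columns[:2]
    return dict(zip(df[a], df[b]))


def write_link_table(links, path) -> None:
    """Write typed link records (cluster-cluster or gene-gene) as TSV.

    ``links`` is a list of dicts sharing a key order; rows are sorted by
    their first two columns, making output deterministic.
    """
    if links:
        columns = list(links[0].keys())
        df = pd.DataFrame(links, columns=columns)
        df = df.sort_values(columns[:2], kind="mergesort").reset_index(drop=True)
    else:
        columns = ["a", "b"]
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def check_expression_genes(records_index, genes: dict) -> None:
    """Warn (not fail) on expression rows for genes absent from the registry."""
    unknown = [g for g in records_index if g not in genes]
    if unknown:
        warnings.warn(
            f"{len(unknown)} expression row(s) for genes absent from the "
            f"gene table (first: {unknown[0]!r})"
        )


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
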
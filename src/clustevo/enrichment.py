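"""GO-slim term enrichment of DE gene sets.

One-sided (over-representation) hypergeometric test per slim term with
Benjamini-Hochberg correction across all tested terms of the run; a term
is significant when its adjusted p-value is below 0.05. Annotations are
first collapsed through an optional term -> slim mapping (identity when
absent); no ontology-graph propagation beyond that mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .specificity import bh_adjust

ENRICH_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hits: int  # k
    study_size: int  # n
    background_hits: int  # K
    background_size: int  # N
    p_value: float  # P[X >= k], X ~ Hypergeom(N, K, n)
    p_adjusted: float
    significant: bool


def map_to_slim(annotations: dict, slim_map: dict | None) -> dict:
    """Replace each gene's terms by their slim images, deduplicated.

    Terms absent from the mapping are dropped (they have no slim image);
    with no mapping the annotations pass through unchanged.
    """
    if slim_map is None:
        return {g: frozenset(ts) for g, ts in annotations.items()}
    out = {}
    for g, terms in annotations.items():
        mapped = frozenset(slim_map[t] for t in terms if t in slim_map)
        if mapped:
            out[g] = mapped
    return out


def enrich(study_set, background_set, annotations: dict,
           slim_map: dict | None = None, alpha: float = ENRICH_ALPHA
           ) -> list:
    """Hypergeometric over-representation of each slim term in the study set.

    The study set must be a subset of the background; both must be
    non-empty. One result per term with at least one background
    annotation, in deterministic (sorted-term) order.
    """
    study = set(study_set)
    background = set(background_set)
    if not study or not background:
        raise ValueError("study and background sets must be non-empty")
    if not study <= background:
        raise ValueError("study set is not a subset of the background")
    ann = map_to_slim(annotations, slim_map)
    term_background: dict[str, set] = {}
    for g in background:
        for t in ann.get(g, ()):
            term_background.setdefault(t, set()).add(g)
    n_bg = len(background)
    n_study = len(study)
    terms = sorted(term_background)
    results = []
    for t in terms:
        bg_hits = term_background[t]
        k = len(bg_hits & study)
        big_k = len(bg_hits)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_study))
        results.append((t, k, big_k, min(p, 1.0)))
    adjusted = bh_adjust([r[3] for r in results])
    return [
        EnrichmentResult(
            term_id=t,
            study_hits=k,
            study_size=n_study,
            background_hits=big_k,
            background_size=n_bg,
            p_value=p,
            p_adjusted=padj,
            significant=padj < alpha,
        )
        for (t, k, big_k, p), padj in zip(results, adjusted)
    ]
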
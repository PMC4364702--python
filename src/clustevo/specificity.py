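"""Orthogroup species-specificity and the SM-vs-primary-metabolism tests.

Two specificity modes are distinguished:

* **strict** — an orthogroup is species-specific for a focal species when
  it has members in no other species (a single gene or only inparalogs);
* **functional** — species-specific when no other-species member carries
  the focal functional-category annotation, i.e. the function rather than
  the gene is species-specific.

Strict specificity implies functional specificity, so per-category strict
counts never exceed functional counts.

The Fisher exact test and Benjamini-Hochberg correction are authored here
(two-sided by hypergeometric enumeration, mirroring R's fisher.test
convention of summing all tables as or less probable than the observed
one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .types import OrthogroupRegistry

#: Functional categories participating in specificity accounting.
SPECIFICITY_CATEGORIES = ("primary_metabolism", "sm_backbone", "sm_clustered")

#: Relative slack when comparing point probabilities to the observed one,
#: mirroring conventional two-sided Fisher behavior under floating point.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class SpecificityResult:
    species: str
    category: str
    mode: str  # strict | functional
    n_orthogroups: int
    n_specific: int
    fraction: float  # nan when n_orthogroups == 0


@dataclass(frozen=True)
class FisherResult:
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None


def _genes_of(og, species, category, genes):
    return [
        g for g in og.members.get(species, ())
        if category in genes[g].categories
    ]


def is_species_specific(og, species: str, category: str, mode: str,
                        genes: dict) -> bool:
    """Is this orthogroup species-specific for (species, category)?

    Precondition: the orthogroup contains at least one gene of that species
    annotated to that category.
    """
    if mode not in ("strict", "functional"):
        raise ValueError(f"unknown mode {mode!r}")
    if not _genes_of(og, species, category, genes):
        raise ValueError(
            f"orthogroup {og.og_id!r} has no {category!r} gene in "
            f"{species!r}"
        )
    others = [sp for sp in og.members if sp != species and og.members[sp]]
    if mode == "strict":
        return not others
    return not any(
        category in genes[g].categories
        for sp in others
        for g in og.members[sp]
    )


def specificity_table(genes: dict, ogs: OrthogroupRegistry,
                      modes=("strict", "functional")):
    """One SpecificityResult per (species, category, mode).

    A category with zero orthogroups for a species yields n=0 and a NaN
    fraction (flagged undefined rather than dropped).
    """
    species = sorted({g.species for g in genes.values()})
    results = []
    for sp in species:
        for cat in SPECIFICITY_CATEGORIES:
            cat_ogs = [
                og for og in ogs if _genes_of(og, sp, cat, genes)
            ]
            for mode in modes:
                n_spec = sum(
                    is_species_specific(og, sp, cat, mode, genes)
                    for og in cat_ogs
                )
                results.append(
                    SpecificityResult(
                        species=sp,
                        category=cat,
                        mode=mode,
                        n_orthogroups=len(cat_ogs),
                        n_specific=n_spec,
                        fraction=(n_spec / len(cat_ogs)) if cat_ogs
                        else float("nan"),
                    )
                )
    return results


def sm_unclustered_elsewhere_fraction(genes: dict, ogs: OrthogroupRegistry,
                                      species: str) -> tuple:
    """Fraction of a species' SM-cluster orthogroups with no ortholog in
    any other species' SM cluster.

    Counts orthogroups containing >= 1 sm_clustered gene of ``species``
    whose other-species members (if any) are all outside SM clusters.
    Returns (n_orthogroups, n_unclustered_elsewhere, fraction).
    """
    n = n_escape = 0
    for og in ogs:
        if not _genes_of(og, species, "sm_clustered", genes):
            continue
        n += 1
        foreign_clustered = any(
            "sm_clustered" in genes[g].categories
            for sp in og.members
            if sp != species
            for g in og.members[sp]
        )
        if not foreign_clustered:
            n_escape += 1
    return n, n_escape, (n_escape / n) if n else float("nan")


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided) and Benjamini-Hochberg, from scratch.
# ---------------------------------------------------------------------------

def _log_hyper_pmf(k, r1, c1, n):
    """log P[X = k] for the 2x2 hypergeometric with row sum r1, col sum c1."""
    c2 = n - c1
    return (
        gammaln(c1 + 1) - gammaln(k + 1) - gammaln(c1 - k + 1)
        + gammaln(c2 + 1) - gammaln(r1 - k + 1) - gammaln(c2 - (r1 - k) + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the 2x2 table ((a, b), (c, d)).

    The p-value sums the hypergeometric probabilities of every table with
    the same margins whose point probability is <= the observed one
    (within relative tolerance 1e-7). Any zero margin gives p = 1 by
    convention. Odds ratio is the sample ratio ad/bc with the usual
    infinity/zero conventions.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if min(r1, n - r1, c1, n - c1) == 0:
        return FisherResult(table=((a, b), (c, d)), odds_ratio=odds,
                            p_value=1.0)
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = _log_hyper_pmf(ks, r1, c1, n)
    probs = np.exp(logp)
    p_obs = probs[a - kmin]
    p = float(probs[probs <= p_obs * (1 + _REL_TOL)].sum())
    return FisherResult(table=((a, b), (c, d)), odds_ratio=odds,
                        p_value=min(p, 1.0))


def bh_adjust(p_values) -> list:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj(i) = min over j >= i (by sorted rank) of p(j) * m / j, clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def fisher_specificity_tests(genes: dict, ogs: OrthogroupRegistry):
    """SM-vs-primary-metabolism Fisher tests, one per (species, SM category).

    The 2x2 table is (specific, non-specific) x (SM-category orthogroups,
    primary-metabolism orthogroups) in strict mode. Orthogroups annotated
    to both the SM category and primary metabolism (for the species) are
    counted in the SM column only, avoiding double counting. BH is applied
    jointly across all tests of the run.
    """
    species = sorted({g.species for g in genes.values()})
    rows = []
    for sp in species:
        for cat in ("sm_backbone", "sm_clustered"):
            sm_spec = sm_non = pm_spec = pm_non = 0
            for og in ogs:
                in_cat = bool(_genes_of(og, sp, cat, genes))
                in_pm = bool(_genes_of(og, sp, "primary_metabolism", genes))
                if not (in_cat or in_pm):
                    continue
                if in_cat:
                    strict = is_species_specific(og, sp, cat, "strict", genes)
                    sm_spec += strict
                    sm_non += not strict
                else:
                    strict = is_species_specific(
                        og, sp, "primary_metabolism", "strict", genes
                    )
                    pm_spec += strict
                    pm_non += not strict
            res = fisher_two_sided(sm_spec, sm_non, pm_spec, pm_non)
            rows.append((sp, cat, res))
    adj = bh_adjust([r.p_value for _, _, r in rows])
    return [
        (sp, cat, FisherResult(table=r.table, odds_ratio=r.odds_ratio,
                               p_value=r.p_value, p_adjusted=padj))
        for (sp, cat, r), padj in zip(rows, adj)
    ]
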
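"""Species-specificity modes, Fisher exact test, and BH correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from clustevo import (
    Orthogroup,
    OrthogroupRegistry,
    bh_adjust,
    fisher_two_sided,
    is_species_specific,
    specificity_table,
)
from clustevo.specificity import sm_unclustered_elsewhere_fraction
from clustevo.types import Gene


def _gene(gid, sp, cats=(), cluster=None):
    return Gene(gene_id=gid, species=sp, categories=frozenset(cats),
                cluster_id=cluster)


class TestModes:
    def test_singleton_is_specific_in_both_modes(self):
        genes = {"a1": _gene("a1", "Afum", ["sm_clustered"], "c1")}
        og = Orthogroup("og1", {"Afum": frozenset({"a1"})})
        assert is_species_specific(og, "Afum", "sm_clustered", "strict", genes)
        assert is_species_specific(og, "Afum", "sm_clustered", "functional",
                                   genes)

    def test_foreign_member_with_other_annotation(self):
        genes = {
            "a1": _gene("a1", "Afum", ["sm_clustered"], "c1"),
            "b1": _gene("b1", "Anid", ["primary_metabolism"]),
        }
        og = Orthogroup("og1", {"Afum": frozenset({"a1"}),
                                "Anid": frozenset({"b1"})})
        assert not is_species_specific(og, "Afum", "sm_clustered", "strict",
                                       genes)
        assert is_species_specific(og, "Afum", "sm_clustered", "functional",
                                   genes)

    def test_shared_annotation_specific_in_neither(self):
        genes = {
            "a1": _gene("a1", "Afum", ["sm_clustered"], "c1"),
            "b1": _gene("b1", "Anid", ["sm_clustered"], "c2"),
        }
        og = Orthogroup("og1", {"Afum": frozenset({"a1"}),
                                "Anid": frozenset({"b1"})})
        assert not is_species_specific(og, "Afum", "sm_clustered", "strict",
                                       genes)
        assert not is_species_specific(og, "Afum", "sm_clustered",
                                       "functional", genes)

    def test_precondition_enforced(self):
        genes = {"a1": _gene("a1", "Afum")}
        og = Orthogroup("og1", {"Afum": frozenset({"a1"})})
        with pytest.raises(ValueError):
            is_species_specific(og, "Afum", "sm_clustered", "strict", genes)


class TestSpecificityTable:
    def test_functional_fraction_at_least_strict(self, small_world,
                                                 small_world_result):
        rows = small_world_result["specificity"]
        by_key = {(r.species, r.category, r.mode): r for r in rows}
        for (sp, cat, mode), r in by_key.items():
            if mode != "strict" or r.n_orthogroups == 0:
                continue
            func = by_key[(sp, cat, "functional")]
            assert r.n_specific <= func.n_specific
            assert r.n_orthogroups == func.n_orthogroups

    def test_strict_counts_match_planted_truth(self, small_world,
                                               small_world_result):
        truth = small_world.truth["strict_specific_counts"]
        rows = small_world_result["specificity"]
        for r in rows:
            if r.mode != "strict":
                continue
            expected = truth[f"{r.species}:{r.category}"]
            assert r.n_orthogroups == expected["n_orthogroups"]
            assert r.n_specific == expected["n_specific"]

    def test_all_shared_world_has_zero_fractions(self):
        genes = {
            "a1": _gene("a1", "A", ["sm_clustered", "sm_backbone"], "c1"),
            "b1": _gene("b1", "B", ["sm_clustered", "sm_backbone"], "c2"),
        }
        ogs = OrthogroupRegistry([
            Orthogroup("og1", {"A": frozenset({"a1"}),
                               "B": frozenset({"b1"})})
        ])
        for r in specificity_table(genes, ogs):
            if r.n_orthogroups:
                assert r.fraction == 0.0

    def test_empty_category_flagged_undefined(self):
        genes = {"a1": _gene("a1", "A")}
        ogs = OrthogroupRegistry([Orthogroup("og1",
                                             {"A": frozenset({"a1"})})])
        for r in specificity_table(genes, ogs):
            assert r.n_orthogroups == 0 and math.isnan(r.fraction)

    def test_sm_unclustered_elsewhere(self):
        genes = {
            "a1": _gene("a1", "A", ["sm_clustered"], "c1"),
            "a2": _gene("a2", "A", ["sm_clustered"], "c1"),
            "b1": _gene("b1", "B", ["primary_metabolism"]),
            "b2": _gene("b2", "B", ["sm_clustered"], "c2"),
        }
        ogs = OrthogroupRegistry([
            Orthogroup("og1", {"A": frozenset({"a1"}),
                               "B": frozenset({"b1"})}),  # escapes
            Orthogroup("og2", {"A": frozenset({"a2"}),
                               "B": frozenset({"b2"})}),  # clustered in B
        ])
        n, esc, frac = sm_unclustered_elsewhere_fraction(genes, ogs, "A")
        assert (n, esc) == (2, 1) and frac == 0.5


def _enumeration_oracle(a, b, c, d):
    """Exact-integer two-sided Fisher p: sum point weights <= observed
    (1e-7 relative slack, mirroring the declared tie convention)."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    weights = {
        k: math.comb(c1, k) * math.comb(n - c1, r1 - k)
        for k in range(kmin, kmax + 1)
    }
    w_obs = weights[a]
    total = math.comb(n, r1)
    return sum(w for w in weights.values()
               if w <= w_obs * (1 + 1e-7)) / total


class TestFisher:
    def test_extreme_table_closed_form(self):
        # Table (0, n; n, 0): the two extreme tables tie in probability
        # and only they are included, so p = 2 / C(2n, n).
        n = 4
        res = fisher_two_sided(0, n, n, 0)
        assert res.p_value == pytest.approx(2 / math.comb(2 * n, n),
                                            rel=1e-9)
        # Asymmetric margins: the opposite extreme is far more probable
        # than the observed one, so p is the observed table's mass alone.
        res = fisher_two_sided(0, 4, 6, 0)
        assert res.p_value == pytest.approx(1 / math.comb(10, 4), rel=1e-9)

    def test_enumerated_example(self):
        assert fisher_two_sided(3, 1, 1, 3).p_value == pytest.approx(
            0.4857142857, rel=1e-6
        )

    def test_symmetric_table_p_one(self):
        assert fisher_two_sided(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert fisher_two_sided(0, 0, 3, 4).p_value == 1.0

    def test_odds_ratio_conventions(self):
        assert fisher_two_sided(2, 1, 1, 2).odds_ratio == pytest.approx(4.0)
        assert math.isinf(fisher_two_sided(2, 0, 1, 2).odds_ratio)

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_two_sided(1.5, 2, 3, 4)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_enumeration_and_scipy(self, table):
        a, b, c, d = table
        mine = fisher_two_sided(a, b, c, d).p_value
        assert mine == pytest.approx(_enumeration_oracle(a, b, c, d),
                                     abs=1e-9)
        ref = ss.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_type_one_error_on_null_worlds(self):
        """Equal specific fractions in two categories: Fisher stays
        non-significant in the vast majority of seeded replicates."""
        rng = np.random.default_rng(0)
        n_reps, n_sig = 200, 0
        for _ in range(n_reps):
            sm = rng.binomial(40, 0.3)
            pm = rng.binomial(120, 0.3)
            p = fisher_two_sided(sm, 40 - sm, pm, 120 - pm).p_value
            n_sig += p < 0.05
        assert n_sig / n_reps <= 0.10


class TestBh:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=40))
    def test_matches_statsmodels_and_dominates_input(self, ps):
        from statsmodels.stats.multitest import multipletests

        mine = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        assert all(m >= p - 1e-12 for m, p in zip(mine, ps))


def test_fisher_specificity_tests_adjusted(small_world, small_world_result):
    rows = small_world_result["fisher"]
    assert rows
    for _sp, _cat, res in rows:
        assert res.p_adjusted >= res.p_value - 1e-12
        (a, b), (c, d) = res.table
        assert min(a, b, c, d) >= 0
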
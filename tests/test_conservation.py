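"""SM gene-cluster homology scoring and species-specificity accounting."""

import pytest

from clustevo import (
    GeneCluster,
    Orthogroup,
    OrthogroupRegistry,
    cluster_link_profile,
    homology_components,
    score_cluster_pair,
)


def _cluster(cid, sp, genes):
    return GeneCluster(cluster_id=cid, species=sp, gene_ids=tuple(genes))


def _registry(pairs):
    """pairs: list of lists of (species, gene) tuples, one per orthogroup."""
    ogs = []
    for i, members in enumerate(pairs):
        by_sp = {}
        for sp, g in members:
            by_sp.setdefault(sp, set()).add(g)
        ogs.append(Orthogroup(f"og{i}", {s: frozenset(g)
                                         for s, g in by_sp.items()}))
    return OrthogroupRegistry(ogs)


class TestScorePair:
    def test_identical_two_gene_clusters_fully_homologous(self):
        ogs = _registry([[("A", "a1"), ("B", "b1")],
                         [("A", "a2"), ("B", "b2")]])
        score = score_cluster_pair(
            _cluster("ca", "A", ["a1", "a2"]),
            _cluster("cb", "B", ["b1", "b2"]), ogs,
        )
        assert (score.frac_large, score.frac_small) == (1.0, 1.0)
        assert score.homologous

    def test_disjoint_orthogroups_not_homologous(self):
        ogs = _registry([[("A", "a1")], [("A", "a2")],
                         [("B", "b1")], [("B", "b2")]])
        score = score_cluster_pair(
            _cluster("ca", "A", ["a1", "a2"]),
            _cluster("cb", "B", ["b1", "b2"]), ogs,
        )
        assert (score.frac_large, score.frac_small) == (0.0, 0.0)
        assert not score.homologous

    def test_half_coverage_boundary_is_not_homologous(self):
        # |a| = 4, |b| = 2; two of a's genes matched, covering all of b:
        # frac_large = 0.5 is not > 0.5.
        ogs = _registry([
            [("A", "a1"), ("B", "b1")],
            [("A", "a2"), ("B", "b2")],
            [("A", "a3")], [("A", "a4")],
        ])
        score = score_cluster_pair(
            _cluster("ca", "A", ["a1", "a2", "a3", "a4"]),
            _cluster("cb", "B", ["b1", "b2"]), ogs,
        )
        assert score.frac_large == 0.5
        assert score.frac_small == 1.0
        assert not score.homologous

    def test_symmetric(self):
        ogs = _registry([
            [("A", "a1"), ("B", "b1")],
            [("A", "a2")], [("B", "b2")], [("B", "b3")],
        ])
        a = _cluster("ca", "A", ["a1", "a2"])
        b = _cluster("cb", "B", ["b1", "b2", "b3"])
        s1, s2 = score_cluster_pair(a, b, ogs), score_cluster_pair(b, a, ogs)
        assert (s1.frac_large, s1.frac_small, s1.homologous,
                s1.shared_orthogroups) == (
            s2.frac_large, s2.frac_small, s2.homologous,
            s2.shared_orthogroups)

    def test_same_species_rejected(self):
        ogs = _registry([[("A", "a1")], [("A", "a2")]])
        with pytest.raises(ValueError):
            score_cluster_pair(_cluster("c1", "A", ["a1"]),
                               _cluster("c2", "A", ["a2"]), ogs)

    def test_inparalogs_count_as_matched(self):
        # a1's orthogroup holds two B inparalogs, one inside cluster cb.
        ogs = _registry([[("A", "a1"), ("B", "b1"), ("B", "bx")]])
        score = score_cluster_pair(_cluster("ca", "A", ["a1"]),
                                   _cluster("cb", "B", ["b1"]), ogs)
        assert score.homologous


class TestComponents:
    def test_no_pairs_all_specific(self):
        ogs = _registry([[("A", "a1")], [("B", "b1")], [("C", "c1")]])
        clusters = {
            "ca": _cluster("ca", "A", ["a1"]),
            "cb": _cluster("cb", "B", ["b1"]),
            "cc": _cluster("cc", "C", ["c1"]),
        }
        summary = homology_components(clusters, ogs)
        assert all(s.fraction_specific == 1.0 for s in summary.per_species)
        assert sum(summary.subset_counts.values()) == len(summary.components)

    def test_component_spans_three_species_transitively(self):
        # ca~cb and cb~cc are homologous pairs but ca~cc is not (only
        # half of ca matches cc); the component still spans all three
        # species by transitivity.
        ogs = _registry([
            [("A", "a1"), ("B", "b1")],
            [("A", "a2"), ("B", "b2"), ("C", "c1")],
            [("B", "b3"), ("C", "c2")],
        ])
        clusters = {
            "ca": _cluster("ca", "A", ["a1", "a2"]),
            "cb": _cluster("cb", "B", ["b1", "b2", "b3"]),
            "cc": _cluster("cc", "C", ["c1", "c2"]),
        }
        from clustevo import score_cluster_pair

        assert not score_cluster_pair(clusters["ca"], clusters["cc"],
                                      ogs).homologous
        summary = homology_components(clusters, ogs)
        assert summary.subset_counts == {frozenset({"A", "B", "C"}): 1}

    def test_many_to_one_homology(self):
        # Two single-gene A clusters tied to one two-gene B cluster via a
        # shared inparalog-bearing orthogroup form one component.
        ogs = _registry([
            [("A", "a1"), ("A", "a2"), ("B", "b1"), ("B", "b2")],
        ])
        clusters = {
            "ca1": _cluster("ca1", "A", ["a1"]),
            "ca2": _cluster("ca2", "A", ["a2"]),
            "cb": _cluster("cb", "B", ["b1", "b2"]),
        }
        summary = homology_components(clusters, ogs)
        assert summary.components == (frozenset({"ca1", "ca2", "cb"}),)
        b = [s for s in summary.per_species if s.species == "B"][0]
        assert b.n_species_specific == 0

    def test_planted_world_fraction(self, small_world, small_world_result):
        """Planted pairs with f > 0.5 and only those form cross-species
        components; per-species fractions follow by arithmetic."""
        summary = small_world_result["cluster_summary"]
        expected_cross = {
            p["cluster_a"] for p in small_world.truth["planted_pairs"]
            if p["expected_homologous"]
        } | {
            p["cluster_b"] for p in small_world.truth["planted_pairs"]
            if p["expected_homologous"]
        }
        cross = {
            cid
            for comp in summary.components
            if len({small_world.clusters[c].species for c in comp}) > 1
            for cid in comp
        }
        assert cross == expected_cross
        afum = [s for s in summary.per_species if s.species == "Afum"][0]
        n_cross_afum = sum(
            1 for c in expected_cross
            if small_world.clusters[c].species == "Afum"
        )
        assert afum.fraction_specific == pytest.approx(
            (afum.n_clusters - n_cross_afum) / afum.n_clusters
        )

    def test_duplicated_cluster_always_homologous(self, small_world,
                                                  small_world_result):
        """A planted f=1.0 copy of a cluster scores 1.0/1.0."""
        ogs = small_world_result["orthogroups"]
        pair = [p for p in small_world.truth["planted_pairs"]
                if p["f"] == 1.0][0]
        score = score_cluster_pair(
            small_world.clusters[pair["cluster_a"]],
            small_world.clusters[pair["cluster_b"]], ogs,
        )
        assert (score.frac_large, score.frac_small) == (1.0, 1.0)


class TestLinkProfile:
    def test_counts_and_inparalog_flags(self):
        ogs = _registry([
            [("A", "a1"), ("B", "b1")],
            [("A", "a2"), ("A", "a3")],  # inparalog pair within A
            [("B", "b2")],
        ])
        clusters = {
            "ca": _cluster("ca", "A", ["a1", "a2"]),
            "ca2": _cluster("ca2", "A", ["a3"]),
            "cb": _cluster("cb", "B", ["b1", "b2"]),
        }
        links = cluster_link_profile(clusters["ca"], clusters, ogs)
        by_target = {l["other_cluster"]: l for l in links}
        assert by_target["cb"]["shared_gene_count"] == 1
        assert not by_target["cb"]["inparalog"]
        assert by_target["ca2"]["inparalog"]

    def test_focal_excluded_and_zero_links_omitted(self):
        ogs = _registry([[("A", "a1")], [("B", "b1")]])
        clusters = {
            "ca": _cluster("ca", "A", ["a1"]),
            "cb": _cluster("cb", "B", ["b1"]),
        }
        assert cluster_link_profile(clusters["ca"], clusters, ogs) == []

    def test_planted_focal_profile_counts(self, small_world,
                                          small_world_result):
        """Brute-force recount of one planted focal cluster's links."""
        ogs = small_world_result["orthogroups"]
        pair = small_world.truth["planted_pairs"][1]  # the f=0.6 pair
        focal = small_world.clusters[pair["cluster_a"]]
        links = cluster_link_profile(focal, small_world.clusters, ogs)
        partner = [l for l in links
                   if l["other_cluster"] == pair["cluster_b"]]
        assert partner[0]["shared_gene_count"] == round(0.6 * len(focal))
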
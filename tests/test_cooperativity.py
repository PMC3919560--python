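"""Genomic clustering, target-count profiles and cooperativity statistics."""

import numpy as np
import pandas as pd
import pytest

import mirmodules as mm
from mirmodules.association import InvalidInputError
from mirmodules.cooperativity import GenomicLocus, MiRNAGrouping


def _locus(name, chrom, start, end, host=None):
    return GenomicLocus(mirna_id=name, chromosome=chrom, start=start, end=end,
                        host_gene=host)


class TestGenomicClusters:
    def test_mirnas_within_window_cluster_together(self):
        loci = [_locus("a", "chr1", 1000, 1100), _locus("b", "chr1", 6000, 6100)]
        clusters = mm.build_genomic_clusters(loci, window=10_000)
        assert len(clusters) == 1
        assert clusters[0].members == {"a", "b"}
        assert clusters[0].kind == "genomic_cluster"
        assert clusters[0].name == "a cluster"

    def test_mirnas_beyond_window_do_not_cluster(self):
        loci = [_locus("a", "chr1", 1000, 1100), _locus("b", "chr1", 16200, 16300)]
        assert mm.build_genomic_clusters(loci, window=10_000) == []

    def test_shared_host_gene_links_regardless_of_distance(self):
        loci = [_locus("a", "chr1", 1000, 1100, host="HOST1"),
                _locus("b", "chr1", 900_000, 900_100, host="HOST1")]
        clusters = mm.build_genomic_clusters(loci)
        assert len(clusters) == 1 and clusters[0].members == {"a", "b"}

    def test_chain_closure_by_single_linkage(self):
        # a-8kb-b-8kb-c: a and c are 16 kb apart yet share a cluster via b
        loci = [_locus("a", "chr2", 0, 100), _locus("b", "chr2", 8100, 8200),
                _locus("c", "chr2", 16200, 16300)]
        clusters = mm.build_genomic_clusters(loci, window=10_000)
        assert len(clusters) == 1 and clusters[0].members == {"a", "b", "c"}

    def test_matches_networkx_transitive_closure_on_random_loci(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        loci = []
        for i in range(50):
            start = int(rng.integers(0, 200_000))
            loci.append(
                _locus(f"m{i:02d}", f"chr{rng.integers(1, 4)}", start,
                       start + int(rng.integers(50, 150)),
                       host=f"H{rng.integers(0, 10)}" if rng.random() < 0.3 else None)
            )
        clusters = mm.build_genomic_clusters(loci, window=10_000)

        g = nx.Graph()
        g.add_nodes_from(l.mirna_id for l in loci)
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if (a.chromosome == b.chromosome and gap <= 10_000) or (
                    a.host_gene is not None and a.host_gene == b.host_gene
                ):
                    g.add_edge(a.mirna_id, b.mirna_id)
        expected = {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}
        assert {frozenset(c.members) for c in clusters} == expected

    def test_malformed_interval_is_an_error(self):
        with pytest.raises(InvalidInputError, match="malformed interval"):
            _locus("a", "chr1", 100, 100)

    def test_duplicate_ids_are_an_error(self):
        loci = [_locus("a", "chr1", 0, 10), _locus("a", "chr1", 20, 30)]
        with pytest.raises(InvalidInputError, match="duplicate"):
            mm.build_genomic_clusters(loci)


def _toy_matrices():
    corr = pd.DataFrame(
        [[-0.2, +0.3, -0.4, 0.1],
         [-0.7, -0.1, -0.2, 0.2],
         [+0.1, -0.5, -0.9, 0.3]],
        index=["m1", "m2", "m3"], columns=["g1", "g2", "g3", "g4"],
    )
    targets = pd.DataFrame(
        [[True, False, True, False],
         [True, False, False, False],
         [True, True, True, False]],
        index=corr.index, columns=corr.columns,
    )
    return corr, targets


class TestTargetCountProfile:
    def test_max_inverse_aggregation_takes_most_negative(self):
        corr, targets = _toy_matrices()
        group = MiRNAGrouping("fam", "family", frozenset(["m1", "m2", "m3"]))
        profile = mm.target_count_profile(corr, targets, group)
        # g1 targeted by all three: min(-0.2, -0.7, +0.1) = -0.7
        assert profile.loc["g1", "k"] == 3
        assert profile.loc["g1", "correlation"] == pytest.approx(-0.7)
        # g2 targeted only by m3
        assert profile.loc["g2", "k"] == 1
        assert profile.loc["g2", "correlation"] == pytest.approx(-0.5)
        # g4 untargeted -> excluded
        assert "g4" not in profile.index

    def test_singleton_keeps_positive_correlation(self):
        corr = pd.DataFrame([[0.3]], index=["m1"], columns=["g1"])
        targets = pd.DataFrame([[True]], index=["m1"], columns=["g1"])
        group = MiRNAGrouping("solo", "family", frozenset(["m1"]))
        profile = mm.target_count_profile(corr, targets, group)
        assert profile.loc["g1", "k"] == 1
        assert profile.loc["g1", "correlation"] == pytest.approx(0.3)

    def test_matches_exhaustive_per_cell_scan(self):
        rng = np.random.default_rng(6)
        corr = pd.DataFrame(rng.uniform(-1, 1, (3, 4)),
                            index=["m1", "m2", "m3"],
                            columns=["g1", "g2", "g3", "g4"])
        targets = pd.DataFrame(rng.random((3, 4)) < 0.6,
                               index=corr.index, columns=corr.columns)
        group = MiRNAGrouping("fam", "family", frozenset(corr.index))
        profile = mm.target_count_profile(corr, targets, group)
        for g in corr.columns:
            hits = [m for m in corr.index if targets.loc[m, g]]
            if not hits:
                assert g not in profile.index
            else:
                assert profile.loc[g, "k"] == len(hits)
                assert profile.loc[g, "correlation"] == pytest.approx(
                    min(corr.loc[m, g] for m in hits)
                )

    def test_member_order_does_not_matter(self):
        corr, targets = _toy_matrices()
        g1 = MiRNAGrouping("a", "family", frozenset(["m1", "m2", "m3"]))
        g2 = MiRNAGrouping("b", "family", frozenset(["m3", "m1", "m2"]))
        pd.testing.assert_frame_equal(
            mm.target_count_profile(corr, targets, g1),
            mm.target_count_profile(corr, targets, g2),
        )

    def test_group_with_no_targets_yields_empty_profile(self):
        corr, targets = _toy_matrices()
        targets.loc[:, :] = False
        group = MiRNAGrouping("fam", "family", frozenset(["m1", "m2"]))
        assert mm.target_count_profile(corr, targets, group).empty


class TestCooperativityTrend:
    def test_perfectly_monotone_profile_gives_rho_minus_one(self):
        profile = pd.DataFrame({"k": [1, 2, 3], "correlation": [-0.1, -0.2, -0.3]},
                               index=["g1", "g2", "g3"])
        levels, medians, rho = mm.cooperativity_trend(profile)
        assert levels == [1, 2, 3]
        assert medians == pytest.approx([-0.1, -0.2, -0.3])
        assert rho == pytest.approx(-1.0)

    def test_constant_correlations_are_undefined(self):
        profile = pd.DataFrame({"k": [1, 2, 3], "correlation": [-0.2, -0.2, -0.2]},
                               index=["g1", "g2", "g3"])
        _, _, rho = mm.cooperativity_trend(profile)
        assert np.isnan(rho)

    def test_fewer_than_three_levels_is_undefined(self):
        profile = pd.DataFrame({"k": [1, 2], "correlation": [-0.1, -0.3]},
                               index=["g1", "g2"])
        _, _, rho = mm.cooperativity_trend(profile)
        assert np.isnan(rho)

    def test_empty_profile_is_an_error(self):
        with pytest.raises(InvalidInputError):
            mm.cooperativity_trend(pd.DataFrame(columns=["k", "correlation"]))


class TestCooperativityPvalue:
    def test_beating_every_null_gives_one_over_nperm_plus_one(self):
        # a strongly additive planted group beats all 100 random groupings
        ds = mm.generate_dataset(
            n_mirnas=100, n_mrnas=800, n_samples=40,
            coop_specs=(mm.CoopGroupSpec(),), background_target_rate=0.1,
            rng_seed=0,
        )
        corr = mm.compute_correlations(ds.mirna_expr, ds.mrna_expr)
        res = mm.cooperativity_pvalue(corr, ds.targets, ds.mirna_groupings[0],
                                      n_perm=100, rng=1)
        assert res.rho < -0.8
        assert res.p_value == pytest.approx(1 / 101)

    def test_zero_permutations_is_an_error(self):
        corr, targets = _toy_matrices()
        group = MiRNAGrouping("fam", "family", frozenset(["m1", "m2"]))
        with pytest.raises(InvalidInputError, match="n_perm"):
            mm.cooperativity_pvalue(corr, targets, group, n_perm=0)

    def test_undefined_rho_yields_undefined_p(self):
        corr, targets = _toy_matrices()  # only 2 populated levels for this pair
        group = MiRNAGrouping("fam", "family", frozenset(["m1", "m2"]))
        res = mm.cooperativity_pvalue(corr, targets, group, n_perm=10, rng=0)
        assert np.isnan(res.rho) and np.isnan(res.p_value)

    def test_analyze_groupings_reports_table_columns(self):
        ds = mm.generate_dataset(
            n_mirnas=60, n_mrnas=400, n_samples=30,
            coop_specs=(mm.CoopGroupSpec(n_members=5, n_targets=200),),
            background_target_rate=0.1, rng_seed=5,
        )
        from mirmodules.cooperativity import analyze_groupings

        corr = mm.compute_correlations(ds.mirna_expr, ds.mrna_expr)
        table = analyze_groupings(corr, ds.targets, ds.mirna_groupings,
                                  n_perm=20, rng=2)
        assert list(table.columns) == ["name", "kind", "n", "rho", "p"]
        assert (table["n"] >= 2).all()


class TestAdditiveModelRecovery:
    def test_median_trend_slope_matches_planted_effect(self):
        slopes = []
        for seed in range(3):
            ds = mm.generate_dataset(
                n_mirnas=100, n_mrnas=800, n_samples=40,
                coop_specs=(mm.CoopGroupSpec(effect=0.1, noise_sd=0.05,
                                             n_targets=500),),
                background_target_rate=0.1, rng_seed=seed,
            )
            corr = mm.compute_correlations(ds.mirna_expr, ds.mrna_expr)
            profile = mm.target_count_profile(corr, ds.targets, ds.mirna_groupings[0])
            levels, medians, _ = mm.cooperativity_trend(profile)
            slopes.append(np.polyfit(levels, medians, 1)[0])
        assert np.mean(slopes) == pytest.approx(-0.1, rel=0.2)
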
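"""Overlap metric, classical MDS and bubble-plot layout."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import mirmodules as mm
from mirmodules.association import InvalidInputError
from mirmodules.bicluster import Module, Submatrix
from mirmodules.enrichment import AnnotationSet


def _module(mirnas, direct, indirect=(), module_id="m", score=-0.5, edges=None):
    return Module(
        mirnas=tuple(mirnas), direct_mrnas=tuple(direct),
        indirect_mrnas=tuple(indirect), score=score,
        seed=Submatrix(tuple(mirnas), tuple(direct)),
        module_id=module_id, edges=edges or {},
    )


def _random_modules(rng, n=25):
    mods = []
    for i in range(n):
        mirnas = rng.choice(30, size=rng.integers(2, 8), replace=False)
        mrnas = rng.choice(80, size=rng.integers(5, 25), replace=False)
        mods.append(_module([f"mir{m}" for m in mirnas],
                            [f"g{g}" for g in mrnas], module_id=f"module_{i:03d}"))
    return mods


class TestOverlap:
    def test_identity(self):
        assert mm.overlap({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert mm.overlap({"a"}, {"b", "c"}) == 0.0

    def test_max_denominator_example(self):
        assert mm.overlap({"a", "b", "c", "d"}, {"a", "b"}) == 0.5

    def test_union_denominator_option_is_jaccard(self):
        assert mm.overlap({"a", "b", "c"}, {"b", "c", "d"}, "union") == pytest.approx(0.5)

    def test_empty_set_is_an_error(self):
        with pytest.raises(InvalidInputError):
            mm.overlap(set(), {"a"})

    def test_complement_is_a_metric_on_random_triples(self):
        rng = np.random.default_rng(3)
        sets = [
            set(rng.choice(50, size=rng.integers(3, 20), replace=False).tolist())
            for _ in range(25)
        ]
        for a, b, c in combinations(range(25), 3):
            dab = 1 - mm.overlap(sets[a], sets[b])
            dbc = 1 - mm.overlap(sets[b], sets[c])
            dac = 1 - mm.overlap(sets[a], sets[c])
            assert dab + dbc >= dac - 1e-12
            assert dab + dac >= dbc - 1e-12
            assert dbc + dac >= dab - 1e-12


class TestSimilarityMatrices:
    def test_identical_mirna_sets_give_unit_offdiagonal(self):
        m1 = _module(["a", "b"], ["g1"], module_id="m1")
        m2 = _module(["a", "b"], ["g2"], module_id="m2")
        sim_mir, sim_mrna = mm.similarity_matrices([m1, m2])
        assert sim_mir.loc["m1", "m2"] == 1.0
        assert sim_mrna.loc["m1", "m2"] == 0.0

    def test_invariants_on_random_modules(self):
        mods = _random_modules(np.random.default_rng(4))
        for sim in mm.similarity_matrices(mods):
            vals = sim.to_numpy()
            assert np.allclose(vals, vals.T)
            assert np.allclose(np.diag(vals), 1.0)
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_fewer_than_two_modules_is_an_error(self):
        with pytest.raises(InvalidInputError):
            mm.similarity_matrices([_module(["a"], ["g"])])


class TestClassicalMDS:
    def test_collinear_three_point_configuration(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        sim = pd.DataFrame(1 - d, index=list("ABC"), columns=list("ABC"))
        x = mm.classical_mds(sim, dims=1)["dim1"]
        gaps = sorted(
            [abs(x["A"] - x["B"]), abs(x["B"] - x["C"]), abs(x["A"] - x["C"])]
        )
        assert gaps == pytest.approx([1.0, 1.0, 2.0], abs=1e-8)

    def test_identical_modules_share_coordinates(self):
        sim = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        coords = mm.classical_mds(sim, dims=1)["dim1"]
        assert np.allclose(coords, 0.0)

    def test_reconstructs_one_dimensional_embeddings(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 15)
        d = np.abs(p[:, None] - p[None, :])
        sim = pd.DataFrame(1 - d)
        c = mm.classical_mds(sim, dims=1)["dim1"].to_numpy()
        assert np.abs(np.abs(c[:, None] - c[None, :]) - d).max() < 1e-8

    def test_reflection_stable_sign_convention(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 10)
        d = np.abs(p[:, None] - p[None, :])
        ids = [f"m{i}" for i in range(10)]
        sim = pd.DataFrame(1 - d, index=ids, columns=ids)
        c1 = mm.classical_mds(sim, dims=1)["dim1"]
        rev = ids[::-1]
        c2 = mm.classical_mds(sim.loc[rev, rev], dims=1)["dim1"]
        assert np.allclose(c1[ids], c2[ids], atol=1e-8)
        assert c1.loc[c1.abs().idxmax()] > 0


class TestLayout:
    def _annotated(self, rng, n=6):
        mods = _random_modules(rng, n)
        universe = frozenset(g for m in mods for g in m.mrnas)
        annot = AnnotationSet(
            {f"term{j}": frozenset(mods[j].mrnas) for j in range(n)}, universe
        )
        mm.label_modules(mods, annot)
        return mods

    def test_shared_mirnas_colocate_on_x_only(self):
        m1 = _module(["a", "b", "c"], ["g1", "g2"], module_id="m1")
        m2 = _module(["a", "b", "c"], ["g3", "g4"], module_id="m2")
        m3 = _module(["x", "y", "z"], ["g1", "g2"], module_id="m3")
        m4 = _module(["p", "q", "r"], ["g5", "g6"], module_id="m4")
        for mod in (m1, m2, m3, m4):
            mm.label_modules([mod], None)
        layouts = {l.module_id: l for l in mm.layout_modules([m1, m2, m3, m4])}
        assert layouts["m1"].x == pytest.approx(layouts["m2"].x, abs=1e-9)
        assert abs(layouts["m1"].y - layouts["m2"].y) > 1e-3

    def test_radius_is_linear_in_enriched_fraction(self):
        rng = np.random.default_rng(5)
        mods = self._annotated(rng)
        layouts = mm.layout_modules(mods, r_min=0.0, r_max=2.0)
        for mod, lay in zip(mods, layouts):
            assert lay.radius == pytest.approx(2.0 * mod.annotation.fraction)

    def test_z_order_is_a_permutation_sorting_big_behind_small(self):
        rng = np.random.default_rng(6)
        mods = self._annotated(rng, 8)
        layouts = mm.layout_modules(mods)
        ranks = sorted(l.z_rank for l in layouts)
        assert ranks == list(range(8))
        by_rank = sorted(layouts, key=lambda l: l.z_rank)
        sizes = [next(m.size for m in mods if m.module_id == l.module_id)
                 for l in by_rank]
        assert sizes == sorted(sizes, reverse=True)

    def test_color_pairs_unique_up_to_palette_capacity(self):
        rng = np.random.default_rng(7)
        mods = _random_modules(rng, 40)
        universe = frozenset(g for m in mods for g in m.mrnas)
        annot = AnnotationSet(
            {f"t{j}": frozenset(m.mrnas) for j, m in enumerate(mods)}, universe
        )
        mm.label_modules(mods, annot)
        layouts = mm.layout_modules(mods, palette_size=10)
        pairs = {(l.perimeter_color, l.area_color) for l in layouts}
        assert len(pairs) <= 100
        terms = {l.term for l in layouts}
        codes = {l.term: (l.perimeter_color, l.area_color) for l in layouts}
        assert len({codes[t] for t in terms}) == len(terms)  # unique per term

    def test_figure_export_writes_svg(self, tmp_path):
        rng = np.random.default_rng(8)
        mods = self._annotated(rng)
        layouts = mm.layout_modules(mods)
        from mirmodules.modulemap import plot_layout

        out = tmp_path / "map.svg"
        plot_layout(layouts, str(out))
        assert out.exists() and out.stat().st_size > 0


class TestModuleGraphExport:
    def _toy(self):
        edges = {
            ("m1", "g1"): -0.9, ("m1", "g2"): -0.4, ("m2", "g1"): -0.6,
            ("m2", "g3"): 0.7, ("m1", "g3"): 0.3, ("m2", "g2"): -0.5,
        }
        return _module(["m1", "m2"], ["g1", "g2"], ["g3"], edges=edges)

    def test_zero_thresholds_keep_all_edges(self):
        from mirmodules.modulemap import module_graph

        g = module_graph(self._toy(), 0.0, 0.0)
        assert g.number_of_edges() == 6

    def test_magnitude_threshold_filters_by_hand_enumeration(self):
        from mirmodules.modulemap import module_graph

        g = module_graph(self._toy(), 0.5, 0.5)
        kept = {tuple(sorted(e)) for e in g.edges}
        assert kept == {("g1", "m1"), ("g1", "m2"), ("g2", "m2"), ("g3", "m2")}

    def test_unit_negative_threshold_keeps_only_perfect_edges(self):
        from mirmodules.modulemap import module_graph

        mod = self._toy()
        mod.edges[("m1", "g1")] = -1.0
        g = module_graph(mod, 1.0, 1.0)
        assert {tuple(sorted(e)) for e in g.edges} == {("g1", "m1")}

    def test_excluding_every_edge_warns_and_returns_empty_graph(self):
        from mirmodules.modulemap import module_graph

        with pytest.warns(UserWarning, match="exclude"):
            g = module_graph(self._toy(), 1.0, 1.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5  # nodes are kept

    def test_graphml_roundtrip(self, tmp_path):
        import networkx as nx

        path = tmp_path / "mod.graphml"
        g = mm.export_module_graph(self._toy(), str(path), 0.0, 0.0)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.number_of_edges()

    def test_out_of_range_threshold_is_an_error(self):
        from mirmodules.modulemap import module_graph

        with pytest.raises(InvalidInputError):
            module_graph(self._toy(), -0.1, 0.0)
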
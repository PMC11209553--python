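"""KNN construction, distance rescaling, the weighted merge, and embedding."""

import numpy as np
import pandas as pd
import pytest

import screproject as srp
from screproject.errors import (
    DegenerateScaleError,
    MissingReductionError,
    ParameterError,
)
from screproject.neighbors import PARENT_TAG

from _oracles import brute_knn, brute_merge, brute_scale_factor, random_merge_instance
from conftest import make_pi


def graphs_equal(a, b, provenance=True):
    same = np.array_equal(a.indices, b.indices) and np.array_equal(a.distances, b.distances)
    if provenance and hasattr(a, "provenance") and hasattr(b, "provenance"):
        same = same and np.array_equal(a.provenance, b.provenance)
    return same


class TestBuildKnn:
    def test_collinear_hand_geometry(self):
        pi = make_pi(np.array([0.0, 1.0, 2.0, 4.0]), ["k"] * 4)
        g = srp.build_knn(pi, "pca", K=2)
        assert list(g.indices[0]) == [1, 2]
        assert list(g.distances[0]) == [1.0, 2.0]
        g.validate()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        pi = make_pi(X, ["k"] * 100)
        g = srp.build_knn(pi, "pca", K=5)
        oi, od = brute_knn(X, 5)
        assert np.array_equal(g.indices, oi)
        np.testing.assert_allclose(g.distances, od, rtol=1e-12)

    def test_rows_sorted_ascending(self):
        rng = np.random.default_rng(6)
        pi = make_pi(rng.normal(size=(40, 3)), ["k"] * 40)
        g = srp.build_knn(pi, "pca", K=7)
        assert (np.diff(g.distances, axis=1) >= 0).all()

    def test_parameter_and_lookup_errors(self, tiny_pi):
        with pytest.raises(ParameterError):
            srp.build_knn(tiny_pi, "pca", K=8)
        with pytest.raises(MissingReductionError):
            srp.build_knn(tiny_pi, "nope", K=2)


class TestRescale:
    def test_forced_ratio(self, toy12):
        """Child distances all d, qualifying parent distances all 2d → s=2."""
        parent, child = toy12
        link = parent.children["Xsub"]
        pg = srp.build_knn(parent, "pca", K=3)
        cg = srp.build_knn(child, "pca", K=2)
        # overwrite with constant distances to force the ratio exactly
        pg.distances[:] = 2.0
        cg.distances[:] = 1.0
        scaled = srp.rescale_child_distances(pg, cg, link)
        assert scaled.scale_factor == pytest.approx(2.0)
        assert (scaled.distances == 2.0).all()
        assert np.array_equal(scaled.indices, cg.indices)

    def test_invariant_to_uniform_child_scaling(self, toy12):
        parent, child = toy12
        link = parent.children["Xsub"]
        pg = srp.build_knn(parent, "pca", K=3)
        cg = srp.build_knn(child, "pca", K=2)
        s1 = srp.rescale_child_distances(pg, cg, link).distances
        cg2 = srp.NeighborGraph(
            cell_ids=cg.cell_ids, K=cg.K, indices=cg.indices, distances=cg.distances * 7.5
        )
        s2 = srp.rescale_child_distances(pg, cg2, link).distances
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_planted_scale_recovered(self):
        """60-cell toy with the child coordinate space shrunk 3.5× → the
        recovered scale factor is within 10% of 3.5."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(30, 4))
        B = rng.normal(loc=50.0, size=(30, 4))
        pi = make_pi(np.vstack([A, B]), ["a"] * 30 + ["b"] * 30)
        child = make_pi(A / 3.5, ["x"] * 15 + ["y"] * 15, prefix="c")
        srp.attach_subcluster(pi, "sub", [f"c{i}" for i in range(30)], child)
        pg = srp.build_knn(pi, "pca", K=5)
        cg = srp.build_knn(child, "pca", K=5)
        scaled = srp.rescale_child_distances(pg, cg, pi.children["sub"])
        assert scaled.scale_factor == pytest.approx(3.5, rel=0.10)
        oracle_s = brute_scale_factor(pg, cg, child.cell_ids)
        assert scaled.scale_factor == pytest.approx(oracle_s, rel=1e-12)

    def test_degenerate_child_distances(self, toy12):
        parent, child = toy12
        link = parent.children["Xsub"]
        pg = srp.build_knn(parent, "pca", K=3)
        cg = srp.build_knn(child, "pca", K=2)
        cg.distances[:] = 0.0
        with pytest.raises(DegenerateScaleError):
            srp.rescale_child_distances(pg, cg, link)


def merge_toy12(toy12, w, K=3):
    parent, child = toy12
    link = parent.children["Xsub"]
    pg = srp.build_knn(parent, "pca", K=K)
    cg = srp.build_knn(child, "pca", K=K)
    scaled = srp.rescale_child_distances(pg, cg, link)
    cfg = srp.ReprojectionConfig(K=K, w=w)
    merged = srp.merge_neighbors(pg, {"Xsub": (scaled, link)}, cfg, parent.cells["cluster"])
    return pg, {"Xsub": (scaled, link)}, cfg, merged, parent


class TestMerge:
    def test_w0_rows_equal_child_graph(self, toy12):
        """w=0 means K1=0: merged rows of subclustered cells are exactly the
        rescaled child rows (maximal separation)."""
        pg, scaled, cfg, merged, parent = merge_toy12(toy12, w=0.0)
        graph, link = scaled["Xsub"]
        child_pos = {str(c): i for i, c in enumerate(graph.cell_ids)}
        for i, cid in enumerate(merged.cell_ids):
            if str(cid) not in child_pos:
                continue
            row = child_pos[str(cid)]
            got_ids = [merged.cell_ids[j] for j in merged.indices[i] if j >= 0]
            want_ids = [graph.cell_ids[j] for j in graph.indices[row] if j >= 0]
            assert got_ids == want_ids
            assert set(merged.provenance[i][merged.indices[i] >= 0]) == {"child:Xsub"}

    def test_non_subclustered_rows_preserved_verbatim(self, toy12):
        pg, _, _, merged, parent = merge_toy12(toy12, w=1.0)
        for i, cid in enumerate(merged.cell_ids):
            if parent.cells.loc[str(cid), "cluster"] == "Y":
                assert np.array_equal(merged.indices[i], pg.indices[i])
                assert np.array_equal(merged.distances[i], pg.distances[i])
                assert set(merged.provenance[i]) == {PARENT_TAG}

    @pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 1.0])
    def test_toy12_matches_oracle(self, toy12, w):
        pg, scaled, cfg, merged, _ = merge_toy12(toy12, w=w)
        oracle = brute_merge(pg, scaled, cfg, ["X"] * 6 + ["Y"] * 6)
        assert graphs_equal(merged, oracle)

    def test_parent_cross_edges_monotone_in_w(self, toy12):
        counts = []
        for w in (0.0, 0.25, 0.5, 1.0):
            _, scaled, cfg, merged, parent = merge_toy12(toy12, w=w)
            labels = parent.cells["cluster"].to_numpy()
            cross = 0
            member = set(scaled["Xsub"][1].cell_ids)
            for i in range(merged.n_cells):
                if str(merged.cell_ids[i]) not in member:
                    continue
                for s in range(merged.K):
                    j = merged.indices[i, s]
                    if j >= 0 and merged.provenance[i, s] == PARENT_TAG and labels[j] != labels[i]:
                        cross += 1
            counts.append(cross)
        assert counts == sorted(counts)
        assert counts[0] == 0  # w=0: no parent-derived edges at all

    def test_randomized_instances_match_oracle(self):
        """Bit-exact agreement with the independent merge on randomized
        instances across the full w range."""
        for seed in range(8):
            parent, scaled, labels = random_merge_instance(seed)
            for w in (0.0, 0.5, 1.0):
                cfg = srp.ReprojectionConfig(K=parent.K, w=w)
                got = srp.merge_neighbors(parent, scaled, cfg, labels)
                want = brute_merge(parent, scaled, cfg, labels)
                assert graphs_equal(got, want), f"seed={seed} w={w}"

    def test_duplicate_edge_keeps_smaller_distance(self):
        """A neighbor reachable through both graphs appears once, with the
        smaller of the two distances."""
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [10.0, 0], [11.0, 0], [12.0, 0]])
        pi = make_pi(coords, ["a", "a", "a", "b", "b", "b"])
        child = make_pi(np.array([0.0, 0.1, 0.2]), ["x", "x", "y"], prefix="c")
        srp.attach_subcluster(pi, "s", ["c0", "c1", "c2"], child)
        pg = srp.build_knn(pi, "pca", K=3)
        cg = srp.build_knn(child, "pca", K=2)
        link = pi.children["s"]
        cfg = srp.ReprojectionConfig(K=3, w=1.0)
        merged = srp.merge_neighbors(pg, {"s": (cg, link)}, cfg, pi.cells["cluster"])
        for i in range(3):  # subclustered cells
            ids = [j for j in merged.indices[i] if j >= 0]
            assert len(ids) == len(set(ids))
            oracle = brute_merge(pg, {"s": (cg, link)}, cfg, pi.cells["cluster"].tolist())
            assert graphs_equal(merged, oracle)

    def test_overlapping_children_rejected(self):
        pi = make_pi(np.arange(10, dtype=float), ["a"] * 5 + ["b"] * 5)
        c1 = make_pi(np.arange(5, dtype=float), ["x"] * 5, prefix="c")
        pg = srp.build_knn(pi, "pca", K=2)
        cg = srp.build_knn(c1, "pca", K=2)
        cfg = srp.ReprojectionConfig(K=2, w=1.0)
        children = {"one": (cg, ["c0", "c1", "c2"]), "two": (cg, ["c2", "c3", "c4"])}
        with pytest.raises(ParameterError):
            srp.merge_neighbors(pg, children, cfg, pi.cells["cluster"])

    def test_w_outside_range_rejected(self):
        with pytest.raises(ParameterError):
            srp.ReprojectionConfig(K=3, w=1.5)
        with pytest.raises(ParameterError):
            srp.ReprojectionConfig(K=3, w=-0.1)

    def test_k1_rounding_half_away_from_zero(self):
        assert srp.ReprojectionConfig(K=10, w=0.25).K1 == 3  # 2.5 rounds up
        assert srp.ReprojectionConfig(K=10, w=0.24).K1 == 2
        assert srp.ReprojectionConfig(K=20, w=1.0).K1 == 20
        assert srp.ReprojectionConfig(K=20, w=0.0).K1 == 0


class TestMergeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000), w=st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_sorted_full_and_deduplicated(self, seed, w):
        """Merged rows are ascending in distance, carry K distinct neighbors
        whenever enough candidates exist, and never contain self-edges."""
        parent, scaled, labels = random_merge_instance(seed, n_max=60)
        cfg = srp.ReprojectionConfig(K=parent.K, w=w)
        merged = srp.merge_neighbors(parent, scaled, cfg, labels)
        merged.validate()
        members = set()
        for graph, ids in scaled.values():
            members.update(str(c) for c in ids)
        for i in range(merged.n_cells):
            row = merged.indices[i][merged.indices[i] >= 0]
            d = merged.distances[i][merged.indices[i] >= 0]
            assert (np.diff(d) >= 0).all()
            assert len(set(row)) == len(row)
            assert i not in row
            cid = str(merged.cell_ids[i])
            if cid in members:
                # parent row has K candidates and the child graph has K more,
                # so a full row is always available
                assert len(row) == merged.K
            else:
                assert len(row) == parent.K


class TestEmbed:
    def test_deterministic_given_seed(self, toy12):
        _, _, _, merged, _ = merge_toy12(toy12, w=1.0)
        cfg = srp.ReprojectionConfig(K=3, seed=11, embed_params={"n_epochs": 50})
        e1 = srp.embed_merged(merged, cfg)
        e2 = srp.embed_merged(merged, cfg)
        assert np.array_equal(e1, e2)
        assert e1.shape == (12, 2)
        assert np.isfinite(e1).all()

    def test_empty_row_raises(self, toy12):
        _, _, _, merged, _ = merge_toy12(toy12, w=1.0)
        merged.indices[3, :] = -1
        merged.distances[3, :] = np.inf
        with pytest.raises(Exception, match="c3"):
            srp.embed_merged(merged, srp.ReprojectionConfig(K=3))


class TestReproject:
    def test_zero_children_embeds_parent_graph(self, toy12):
        parent, _ = toy12
        cfg = srp.ReprojectionConfig(K=3, seed=1, embed_params={"n_epochs": 50})
        srp.reproject(parent, children=[], config=cfg)
        assert "reprojected.umap" in parent.reductions
        merged = parent.neighbor_graphs["reprojected"]
        pg = srp.build_knn(parent, "pca", K=3)
        assert np.array_equal(merged.indices, pg.indices)
        assert np.array_equal(merged.distances, pg.distances)

    def test_provenance_audit_on_toy(self, toy12):
        """Every merged edge's provenance tag matches the object that
        contributed it."""
        parent, child = toy12
        cfg = srp.ReprojectionConfig(K=3, w=1.0, seed=1, embed_params={"n_epochs": 50})
        srp.reproject(parent, config=cfg)
        merged = parent.neighbor_graphs["reprojected"]
        pg = srp.build_knn(parent, "pca", K=3)
        cg = srp.rescale_child_distances(
            pg, srp.build_knn(child, "pca", K=3), parent.children["Xsub"]
        )
        cpos = {str(c): i for i, c in enumerate(cg.cell_ids)}
        for i in range(merged.n_cells):
            cid = str(merged.cell_ids[i])
            for s in range(merged.K):
                j, d, tag = merged.indices[i, s], merged.distances[i, s], merged.provenance[i, s]
                if j < 0:
                    continue
                if tag == PARENT_TAG:
                    row = list(pg.indices[i])
                    assert j in row and pg.distances[i, row.index(j)] == d
                else:
                    assert tag == "child:Xsub"
                    r = cpos[cid]
                    row = [cpos[str(cg.cell_ids[x])] for x in range(len(cg.cell_ids))]
                    crow = list(cg.indices[r])
                    jj = [x for x in crow if str(cg.cell_ids[x]) == str(merged.cell_ids[j])]
                    assert jj, "child edge must exist in the child graph"
                    assert cg.distances[r, crow.index(jj[0])] == d

    def test_two_level_recursion_uses_child_merged_graph(self):
        root, truth = srp.generate(srp.two_level_plan(seed=3, n_cells=500))
        child = root.children["sub0"].child
        assert list(child.children) == ["subsub0"]
        cfg = srp.ReprojectionConfig(K=10, w=1.0, seed=2, embed_params={"n_epochs": 50})
        srp.reproject(root, config=cfg)
        # recursion left a merged graph on the child as well
        assert "reprojected" in child.neighbor_graphs
        assert "reprojected.umap" in root.reductions
        leaf = srp.resolve_labels(root, "leaf")
        assert leaf.nunique() > root.cells["cluster"].nunique()

    def test_stage_tagged_errors(self, toy12):
        parent, _ = toy12
        with pytest.raises(MissingReductionError, match="build_knn"):
            srp.reproject(
                parent, config=srp.ReprojectionConfig(K=3, reduction="nope")
            )
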
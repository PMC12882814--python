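"""Neighborhood statistics: nh_sum, permutation enrichment, composition ratios."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcniche import (
    delaunay_graph,
    group_composition,
    k_layer_neighborhood,
    nh_sum,
    pairwise_enrichment,
    permutation_enrichment,
    prune_percentile,
)


def cellmap(ids, types, coords=None):
    n = len(ids)
    coords = coords if coords is not None else np.zeros((n, 2))
    return pd.DataFrame(
        {"cell_id": ids, "sample_id": "S", "x_um": coords[:, 0], "y_um": coords[:, 1],
         "cell_type": types}
    )


def random_typed_cells(rng, n, types=("A", "B", "C")):
    coords = rng.uniform(0, 500, (n, 2))
    cells = cellmap([f"c{i}" for i in range(n)], rng.choice(types, n), coords)
    return cells, prune_percentile(delaunay_graph(cells), 99)


class TestNhSum:
    def test_isolated_node_row_is_zero(self):
        cells = cellmap(["a", "b", "c"], ["A", "B", "B"])
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("b", "c", length=1.0)
        Y = nh_sum(cells, g, k=2)
        assert Y.loc["a"].sum() == 0
        assert Y.loc["b", "B"] == 1

    def test_all_column_is_row_sum(self, rng):
        cells, g = random_typed_cells(rng, 120)
        Y = nh_sum(cells, g, k=3)
        assert (Y["all"] == Y.drop(columns="all").sum(axis=1)).all()
        assert (Y >= 0).all().all()

    def test_negative_k_rejected(self, rng):
        cells, g = random_typed_cells(rng, 10)
        with pytest.raises(ValueError):
            nh_sum(cells, g, k=-1)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_bfs_oracle(self, rng, k):
        cells, g = random_typed_cells(rng, 150)
        Y = nh_sum(cells, g, k=k)
        types = dict(zip(cells["cell_id"], cells["cell_type"]))
        for cid in rng.choice(cells["cell_id"], 25, replace=False):
            nbh = k_layer_neighborhood(g, {cid}, k)
            for t in ("A", "B", "C"):
                assert Y.loc[cid, t] == sum(1 for m in nbh if types[m] == t)
            assert Y.loc[cid, "all"] == len(nbh)


class TestPermutationEnrichment:
    def test_all_nonselected_target_gives_unit_score_and_p_one(self, rng):
        cells, g = random_typed_cells(rng, 80, types=("T",))
        cells.loc[:9, "cell_type"] = "S"
        selected = set(cells["cell_id"][:10])
        res = permutation_enrichment(cells, g, selected, "T", k=2, n_perm=50, seed=0)
        # neighborhoods can contain selected cells, so densities are < 1,
        # but the null is degenerate at the observed value
        assert res.score == pytest.approx(1.0, abs=1e-9) or res.observed == pytest.approx(
            res.null_scores[0] * res.baseline
        )
        assert res.p_value == 1.0
        assert np.allclose(res.null_scores, res.null_scores[0])

    def test_planted_enrichment_maximal_significance(self, rng):
        # targets exist only inside selected 1-layer neighborhoods
        cells, g = random_typed_cells(rng, 200, types=("bg",))
        selected = set(np.array(cells["cell_id"])[rng.choice(200, 10, replace=False)])
        inside = set()
        for s in selected:
            inside |= k_layer_neighborhood(g, {s}, 1)
        inside -= selected
        target_ids = list(inside)[:20]
        cells.loc[cells["cell_id"].isin(target_ids), "cell_type"] = "tgt"
        res = permutation_enrichment(cells, g, selected, "tgt", k=1, n_perm=1000, seed=1)
        assert res.score > 1
        assert res.p_value == pytest.approx(1 / 1001)

    def test_seed_determinism_and_seed_sensitivity(self, rng):
        cells, g = random_typed_cells(rng, 100)
        selected = set(cells["cell_id"][:10])
        r1 = permutation_enrichment(cells, g, selected, "B", k=2, n_perm=200, seed=7)
        r2 = permutation_enrichment(cells, g, selected, "B", k=2, n_perm=200, seed=7)
        r3 = permutation_enrichment(cells, g, selected, "B", k=2, n_perm=200, seed=8)
        assert np.array_equal(r1.null_scores, r2.null_scores)
        assert r1.p_value == r2.p_value
        assert not np.array_equal(r1.null_scores, r3.null_scores)

    def test_invariant_to_relabeling_other_types(self, rng):
        cells, g = random_typed_cells(rng, 100, types=("A", "B", "C"))
        selected = set(cells["cell_id"][:8])
        res_a = permutation_enrichment(cells, g, selected, "B", k=2, n_perm=100, seed=3)
        relabeled = cells.copy()
        relabeled.loc[relabeled["cell_type"] == "C", "cell_type"] = "D"
        res_b = permutation_enrichment(relabeled, g, selected, "B", k=2, n_perm=100, seed=3)
        assert res_a.observed == res_b.observed
        assert np.array_equal(res_a.null_scores, res_b.null_scores)

    def test_baseline_zero_reported_not_crashed(self, rng):
        cells, g = random_typed_cells(rng, 50, types=("A",))
        selected = set(cells["cell_id"][:5])
        cells.loc[cells["cell_id"].isin(selected), "cell_type"] = "tgt"
        res = permutation_enrichment(cells, g, selected, "tgt", k=1, n_perm=20, seed=0)
        assert np.isnan(res.score)
        assert res.notes

    def test_calibration_under_random_labels(self):
        """Mean score ≈ 1 and p approximately uniform under the null."""
        scores, pvals = [], []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            coords = rng.uniform(0, 500, (200, 2))
            cells = cellmap([f"c{i}" for i in range(200)],
                            rng.choice(["tgt", "bg"], 200, p=[0.3, 0.7]), coords)
            g = prune_percentile(delaunay_graph(cells), 99)
            selected = set(np.array(cells["cell_id"])[rng.choice(200, 20, replace=False)])
            res = permutation_enrichment(cells, g, selected, "tgt", k=5, n_perm=200,
                                         seed=int(rng.integers(2**31)))
            scores.append(res.score)
            pvals.append(res.p_value)
        assert np.mean(scores) == pytest.approx(1.0, abs=0.05)
        assert 0.01 <= np.mean(np.array(pvals) <= 0.05) <= 0.12


class TestPairwiseEnrichment:
    def test_interleaved_lattice_enriches_cross_type(self):
        # checkerboard: every neighbor of an A is a B
        ids, types, coords = [], [], []
        for i in range(12):
            for j in range(12):
                ids.append(f"c{i}_{j}")
                types.append("A" if (i + j) % 2 == 0 else "B")
                coords.append((10.0 * i, 10.0 * j))
        cells = cellmap(ids, types, np.array(coords))
        g = delaunay_graph(cells)
        z = pairwise_enrichment(cells, g, n_perm=100, seed=0)
        assert z.loc["A", "B"] > 3
        obs = z.attrs["observed"]
        assert obs.loc["A", "A"] == 0  # same-label edges excluded

    def test_segregated_blocks_deplete_cross_type(self, rng):
        coords_a = rng.uniform(0, 100, (60, 2))
        coords_b = rng.uniform(0, 100, (60, 2)) + [600, 0]
        cells = cellmap([f"c{i}" for i in range(120)], ["A"] * 60 + ["B"] * 60,
                        np.vstack([coords_a, coords_b]))
        g = prune_percentile(delaunay_graph(cells), 99)
        z = pairwise_enrichment(cells, g, n_perm=100, seed=0)
        assert z.loc["A", "B"] < 0
        assert z.loc["B", "A"] < 0

    def test_random_labels_rarely_exceed_three_sigma(self):
        exceed, total = 0, 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            coords = rng.uniform(0, 400, (150, 2))
            cells = cellmap([f"c{i}" for i in range(150)],
                            rng.choice(["A", "B", "C"], 150), coords)
            g = delaunay_graph(cells)
            z = pairwise_enrichment(cells, g, n_perm=200, seed=1000 + rep)
            vals = z.to_numpy()
            vals = vals[np.isfinite(vals)]
            exceed += int((np.abs(vals) > 3).sum())
            total += vals.size
        assert exceed / total < 0.03

    def test_singleton_class_flagged(self, rng):
        cells, g = random_typed_cells(rng, 40, types=("A", "B"))
        cells.loc[0, "cell_type"] = "rare"
        z = pairwise_enrichment(cells, g, n_perm=50, seed=0)
        assert "rare" in z.index


class TestGroupComposition:
    def test_hand_computed_six_cell_example(self):
        Y = pd.DataFrame(
            {"T1": [2, 0, 1, 3, 0, 1],
             "T2": [0, 1, 1, 0, 2, 0],
             "T3": [1, 1, 0, 0, 0, 2],
             "T4": [0, 0, 0, 1, 1, 0]},
            index=[f"c{i}" for i in range(6)],
        )
        Y["all"] = Y.sum(axis=1)
        groups = {"c0": "g1", "c1": "g1", "c2": "g2", "c3": "g2", "c4": "g3", "c5": "g3"}
        eps = 0.001
        out = group_composition(Y, groups, pseudocount=eps)
        # hand computation for g1, T1: in-group Σ=2, all=5; rest Σ=5, all=12
        expected = ((2 + eps) / (5 + eps)) / ((5 + eps) / (12 + eps))
        assert out.loc["g1", "T1"] == pytest.approx(expected)
        # and for g3, T3: in-group Σ=2, all=6; rest Σ=2, all=11
        expected33 = ((2 + eps) / (6 + eps)) / ((2 + eps) / (11 + eps))
        assert out.loc["g3", "T3"] == pytest.approx(expected33)

    def test_identical_composition_gives_unit_ratios(self):
        row = {"T1": 3, "T2": 1, "all": 4}
        Y = pd.DataFrame([row] * 8, index=[f"c{i}" for i in range(8)])
        groups = {"c0": "g", "c1": "g"}
        out = group_composition(Y, groups)
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-2)

    def test_zero_counts_guarded_by_pseudocount(self):
        Y = pd.DataFrame({"T1": [0, 0, 0, 0], "all": [0, 0, 0, 0]},
                         index=list("abcd"))
        out = group_composition(Y, {"a": "g"})
        assert np.isfinite(out.to_numpy()).all()

    def test_empty_group_rejected(self):
        Y = pd.DataFrame({"T1": [1], "all": [1]}, index=["a"])
        with pytest.raises(KeyError):
            group_composition(Y, {"zz": "g"})

    def test_renormalization_centers_selected_type(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.integers(0, 5, (9, 3)), columns=["T1", "T2", "T3"],
                         index=[f"c{i}" for i in range(9)])
        Y["all"] = Y.sum(axis=1)
        groups = {f"c{i}": f"g{i % 3}" for i in range(9)}
        out = group_composition(Y, groups, renormalize_type="T2")
        assert out["T2"].mean() == pytest.approx(1.0)
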
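"""Vessel typing and perivascular association rules."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from dcniche import (
    AssociationConfig,
    ClusterSet,
    SurfaceSet,
    VesselSet,
    associate_cells,
    associate_clusters,
    ccl19_coverage,
    ccl21_membership,
    classify_vessels,
    vessel_dc_load,
)

from conftest import disk, square


def vessel_pair(bv_at=(0.0, 0.0), lv_at=(200.0, 0.0), r=10.0):
    return VesselSet(
        surfaces=SurfaceSet(["bv", "lv"], [disk(*bv_at, r), disk(*lv_at, r)], ["CD31", "CD31"]),
        classes=["BV", "LV"],
    )


class TestClassifyVessels:
    def test_overlap_rule_and_boundary(self):
        cd31 = SurfaceSet(["v1", "v2", "v3"],
                          [square(0, 0, 10, 10), square(50, 0, 60, 10), square(100, 0, 110, 10)])
        # v1: no overlap; v2: half covered; v3: a sliver exactly at the cutoff
        cutoff = 0.0001
        sliver = square(100, 0, 100 + 10 * cutoff, 10)  # area ratio exactly cutoff
        lyve1 = SurfaceSet(["l1", "l2"], [square(50, 0, 55, 10), sliver])
        out = classify_vessels(cd31, lyve1, ratio_cutoff=cutoff)
        assert out.classes == ["BV", "LV", "LV"]  # at-cutoff resolves to LV

    def test_no_lyve1_everything_is_bv(self):
        cd31 = SurfaceSet(["v"], [square(0, 0, 10, 10)])
        assert classify_vessels(cd31, SurfaceSet([], [])).classes == ["BV"]


class TestAssociateCells:
    def test_nearer_vessel_wins(self):
        vessels = vessel_pair()
        dcs = SurfaceSet(["d"], [disk(15, 0, 2)])  # ~3 μm from BV border
        out = associate_cells(dcs, vessels)
        assert out.loc[0, "label"] == "BV"
        assert out.loc[0, "d_bv"] < out.loc[0, "d_lv"]

    def test_beyond_cutoff_is_none(self):
        vessels = vessel_pair()
        dcs = SurfaceSet(["d"], [disk(100, 90, 2)])  # > 20 μm from both
        out = associate_cells(dcs, vessels)
        assert out.loc[0, "label"] == "none"

    def test_exact_tie_resolves_to_bv(self):
        vessels = vessel_pair(bv_at=(0, 0), lv_at=(60, 0), r=10.0)
        dcs = SurfaceSet(["d"], [disk(30, 0, 2)])  # equidistant, within 20 μm
        out = associate_cells(dcs, vessels)
        assert out.loc[0, "d_bv"] == pytest.approx(out.loc[0, "d_lv"], abs=1e-9)
        assert out.loc[0, "label"] == "BV"

    def test_missing_class_flagged_and_defaults(self):
        vessels = VesselSet(SurfaceSet(["bv"], [disk(0, 0, 10)]), ["BV"])
        dcs = SurfaceSet(["d1", "d2"], [disk(15, 0, 2), disk(200, 0, 2)])
        out = associate_cells(dcs, vessels)
        assert out.attrs["missing_classes"] == ["LV"]
        assert list(out["label"]) == ["BV", "none"]

    def test_cellmap_points_and_centroid_mode(self):
        vessels = vessel_pair()
        cells = pd.DataFrame(
            {"cell_id": ["c1"], "sample_id": "S", "x_um": [40.0], "y_um": [0.0],
             "cell_type": "DC"}
        )
        cfg = AssociationConfig.human_multispectral()
        out = associate_cells(cells, vessels, cfg)
        assert out.loc[0, "d_bv"] == pytest.approx(40.0)  # centroid-to-centroid
        assert out.loc[0, "label"] == "BV"

    def test_shrinking_cutoff_never_creates_association(self, rng):
        vessels = vessel_pair()
        dcs = SurfaceSet(
            [f"d{i}" for i in range(50)],
            [disk(x, y, 2) for x, y in rng.uniform(-50, 250, (50, 2))],
        )
        wide = associate_cells(dcs, vessels, AssociationConfig(vessel_cutoff=30))
        narrow = associate_cells(dcs, vessels, AssociationConfig(vessel_cutoff=10))
        moved = (wide["label"].to_numpy() == "none") & (narrow["label"].to_numpy() != "none")
        assert not moved.any()

    def test_labels_partition_cells(self, small_scene):
        out = associate_cells(small_scene.dc_surfaces, small_scene.vessels)
        fractions = out["label"].value_counts(normalize=True)
        assert fractions.sum() == pytest.approx(1.0)
        assert set(out["label"]) <= {"BV", "LV", "none"}


class TestAssociateClusters:
    def _setup(self):
        vessels = vessel_pair(bv_at=(0, 0), lv_at=(500, 0))
        r = np.sqrt(120 / np.pi)
        near = [disk(15 + 10 * i, 0, r) for i in range(3)]   # within 20 μm of BV
        far = [disk(250, 200 + 15 * i, r) for i in range(2)]  # near nothing
        dets = SurfaceSet([f"n{i}" for i in range(3)] + [f"f{i}" for i in range(2)], near + far)
        return vessels, dets

    def test_fully_proximal_cluster_is_bv(self):
        vessels, dets = self._setup()
        clusters = ClusterSet(members=[["n0", "n1", "n2"]])
        out = associate_clusters(clusters, dets, vessels)
        assert out.loc[0, "label"] == "BV"
        assert out.loc[0, "frac_near_bv"] == pytest.approx(1.0)

    def test_below_half_area_is_unassociated(self):
        vessels, dets = self._setup()
        # 2 of 5 members proximal: 40% of area
        clusters = ClusterSet(members=[["n0", "n1", "f0", "f1"]])
        out = associate_clusters(
            clusters, dets, vessels, AssociationConfig(vessel_cutoff=20, cluster_area_fraction=0.51)
        )
        assert out.loc[0, "label"] == "none"

    def test_matches_per_detection_brute_force(self, rng):
        vessels = vessel_pair(bv_at=(0, 0), lv_at=(300, 0))
        cfg = AssociationConfig()
        for _ in range(5):
            centers = rng.uniform(-40, 340, (30, 2)) * [1, 0.2]
            dets = SurfaceSet([f"d{i}" for i in range(30)],
                              [disk(x, y, 4) for x, y in centers])
            members = [f"d{i}" for i in rng.choice(30, size=10, replace=False)]
            out = associate_clusters(ClusterSet(members=[sorted(members)]), dets, vessels, cfg)
            # brute force: per-detection distances to each vessel class
            bv, lv = vessels.surfaces.polygons
            a_bv = a_lv = tot = 0.0
            for m in members:
                poly = dets.polygons[dets.index_of(m)]
                tot += poly.area
                if poly.distance(bv) <= cfg.vessel_cutoff:
                    a_bv += poly.area
                if poly.distance(lv) <= cfg.vessel_cutoff:
                    a_lv += poly.area
            if a_bv / tot >= 0.5 and a_bv >= a_lv:
                expected = "BV"
            elif a_lv / tot >= 0.5:
                expected = "LV"
            else:
                expected = "none"
            assert out.loc[0, "label"] == expected


class TestCcl19Coverage:
    def test_any_positive_overlap_counts_as_covered(self):
        vessels = VesselSet(
            SurfaceSet(["v1", "v2"], [square(0, 0, 10, 10), square(50, 0, 60, 10)]),
            ["BV", "BV"],
        )
        ccl19 = SurfaceSet(["c"], [square(9.99, 0, 12, 10)])  # sliver on v1 only
        out = ccl19_coverage(vessels, ccl19)
        assert out["covered"] == [True, False]
        assert out["bv_covered_area_fraction"] + out["bv_uncovered_area_fraction"] == pytest.approx(1.0)

    def test_touching_without_area_overlap_is_not_covered(self):
        vessels = VesselSet(SurfaceSet(["v"], [square(0, 0, 10, 10)]), ["BV"])
        ccl19 = SurfaceSet(["c"], [square(10, 0, 20, 10)])  # shares an edge only
        assert ccl19_coverage(vessels, ccl19)["covered"] == [False]

    def test_planted_coverage_recovered(self, small_scene):
        out = ccl19_coverage(small_scene.vessels, small_scene.ccl19)
        truth = small_scene.truth["ccl19_covered"]
        got = dict(zip(small_scene.vessels.surfaces.ids, out["covered"]))
        assert got == truth


class TestCcl21Membership:
    def test_single_member_inside_suffices(self):
        dets = SurfaceSet(["a", "b"], [disk(5, 5, 2), disk(100, 100, 2)])
        regions = SurfaceSet(["r"], [square(0, 0, 20, 20)])
        clusters = ClusterSet(members=[["a", "b"]])
        assert ccl21_membership(clusters, dets, regions) == [True]

    def test_all_outside_is_false_and_vertex_order_invariant(self):
        dets = SurfaceSet(["a"], [disk(100, 100, 2)])
        clusters = ClusterSet(members=[["a"]])
        from shapely.geometry import Polygon
        r1 = SurfaceSet(["r"], [Polygon([(0, 0), (20, 0), (20, 20), (0, 20)])])
        r2 = SurfaceSet(["r"], [Polygon([(20, 20), (0, 20), (0, 0), (20, 0)])])
        assert ccl21_membership(clusters, dets, r1) == [False]
        assert ccl21_membership(clusters, dets, r1) == ccl21_membership(clusters, dets, r2)

    def test_centroid_on_boundary_counts(self):
        dets = SurfaceSet(["a"], [disk(20, 10, 2)])  # centroid on region edge
        regions = SurfaceSet(["r"], [square(0, 0, 20, 20)])
        assert ccl21_membership(ClusterSet(members=[["a"]]), dets, regions) == [True]


class TestVesselDcLoad:
    def test_five_proximal_dcs_reach_cluster_area(self):
        vessel = disk(0, 0, 10)
        r = np.sqrt(120 / np.pi)
        dcs = SurfaceSet([f"d{i}" for i in range(5)],
                         [disk(20 + 3 * i, 0, r) for i in range(5)])
        out = vessel_dc_load(vessel, dcs)
        assert out["n_proximal"] == 5
        assert out["total_dc_area_um2"] == pytest.approx(dcs.areas.sum())
        assert out["cluster_associated"]

    def test_area_below_500_is_not_cluster_associated(self):
        vessel = disk(0, 0, 10)
        r = np.sqrt(499 / np.pi)
        dcs = SurfaceSet(["d"], [disk(20, 0, r)])
        out = vessel_dc_load(vessel, dcs)
        assert out["total_dc_area_um2"] < 500
        assert not out["cluster_associated"]

    def test_sum_matches_brute_force(self, rng):
        vessel = disk(0, 0, 10)
        centers = rng.uniform(-80, 80, (40, 2))
        dcs = SurfaceSet([f"d{i}" for i in range(40)], [disk(x, y, 4) for x, y in centers])
        out = vessel_dc_load(vessel, dcs, cutoff=20)
        expected = sum(p.area for p in dcs.polygons if p.distance(vessel) <= 20)
        assert out["total_dc_area_um2"] == pytest.approx(expected)


def test_association_recovery_on_planted_scenes():
    """BV-associated fraction recovers the planted perivascular fraction."""
    from dcniche import SceneConfig, generate_scene

    ests = []
    for seed in range(5):
        scene = generate_scene(SceneConfig(n_dc=200, n_treg=0, n_other=0,
                                           perivascular_fraction=0.3, seed=seed))
        out = associate_cells(scene.dc_surfaces, scene.vessels)
        ests.append((out["label"] == "BV").mean())
    assert abs(np.mean(ests) - 0.3) < 0.05
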
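"""Nearest-neighbor tables, region summaries, colocalization."""

import numpy as np
import pandas as pd
import pytest

import bodyquant as bq
from conftest import make_mask
from oracles import brute_force_nn


def points_table(points, ids=None, class_name="generic", volumes=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    volumes = np.full(n, 1e-4) if volumes is None else np.asarray(volumes)
    return pd.DataFrame(
        {
            "object_id": ids,
            "class": class_name,
            "volume_mm3": volumes,
            "centroid_z_um": points[:, 0],
            "centroid_y_um": points[:, 1],
            "centroid_x_um": points[:, 2],
        }
    )


class TestNNDistances:
    def test_pythagoras(self):
        src = points_table([[0, 0, 0]], class_name="metastasis")
        tgt = points_table([[0, 3, 4]], class_name="TLS")
        tab = bq.nn_distances(src, tgt)
        assert tab["distance_um"].iloc[0] == pytest.approx(5.0, abs=1e-12)

    def test_single_object_vs_itself_has_no_neighbor(self):
        t = points_table([[1, 2, 3]])
        tab = bq.nn_distances(t, t, exclude_self=True)
        assert tab["distance_um"].isna().all()
        assert tab["nearest_target_id"].isna().all()

    def test_self_comparison_requires_exclude_self(self):
        t = points_table([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError, match="exclude_self"):
            bq.nn_distances(t, t)

    def test_tie_broken_by_lower_target_id(self):
        src = points_table([[0, 0, 0]], class_name="a")
        tgt = points_table([[0, 0, 5], [0, 5, 0]], ids=[7, 3], class_name="b")
        tab = bq.nn_distances(src, tgt)
        assert tab["nearest_target_id"].iloc[0] == 3

    @pytest.mark.parametrize("n_src,n_tgt", [(50, 60), (30, 1500)])
    def test_matches_brute_force_oracle(self, n_src, n_tgt, rng):
        src_pts = rng.random((n_src, 3)) * 500
        tgt_pts = rng.random((n_tgt, 3)) * 500
        src = points_table(src_pts, class_name="metastasis")
        tgt = points_table(tgt_pts, class_name="TLS")
        tab = bq.nn_distances(src, tgt)
        ids, dists = brute_force_nn(
            src_pts, src["object_id"].to_numpy(), tgt_pts, tgt["object_id"].to_numpy()
        )
        assert np.array_equal(tab["nearest_target_id"].to_numpy(dtype=int), ids)
        assert np.allclose(tab["distance_um"], dists, atol=1e-9)

    def test_within_class_matches_oracle(self, rng):
        pts = rng.random((80, 3)) * 300
        t = points_table(pts)
        tab = bq.nn_distances(t, t, exclude_self=True)
        ids, dists = brute_force_nn(
            pts, t["object_id"].to_numpy(), pts, t["object_id"].to_numpy(),
            exclude_same_id=True,
        )
        assert np.array_equal(tab["nearest_target_id"].to_numpy(dtype=int), ids)
        assert np.allclose(tab["distance_um"], dists, atol=1e-9)

    def test_translation_invariance(self, rng):
        src_pts = rng.random((40, 3)) * 100
        tgt_pts = rng.random((40, 3)) * 100
        shift = np.array([123.4, -55.5, 7.7])
        t1 = bq.nn_distances(points_table(src_pts, class_name="a"),
                             points_table(tgt_pts, class_name="b"))
        t2 = bq.nn_distances(points_table(src_pts + shift, class_name="a"),
                             points_table(tgt_pts + shift, class_name="b"))
        assert np.allclose(t1["distance_um"], t2["distance_um"], atol=1e-9)


class TestVolumeDistanceJoin:
    def test_carries_both_volumes(self):
        met = points_table([[0, 0, 0]], class_name="metastasis", volumes=[0.05])
        tls = points_table([[0, 0, 10]], ids=[9], class_name="TLS", volumes=[0.002])
        tab = bq.volume_distance_join(met, tls)
        assert tab["source_volume_mm3"].iloc[0] == 0.05
        assert tab["target_volume_mm3"].iloc[0] == 0.002
        assert tab["distance_um"].iloc[0] == pytest.approx(10.0)

    def test_no_tls_gives_all_missing_and_zero_eligible(self):
        met = points_table([[0, 0, 0], [5, 5, 5]], class_name="metastasis")
        tls = points_table(np.empty((0, 3)), class_name="TLS")
        tab = bq.volume_distance_join(met, tls)
        assert tab["distance_um"].isna().all()
        summary = bq.volume_distance_summary(tab)
        assert summary["n_eligible"] == 0
        assert summary["n_missing_distance"] == 2


class TestRegionSummary:
    def _regions(self):
        data = np.zeros((4, 9, 4), dtype=np.int32)
        data[:, 0:3, :] = 1
        data[:, 3:6, :] = 2
        # y in [6,9) stays background
        return bq.LabelVolume(data, (10, 10, 10), label_names={1: "lung", 2: "gut"})

    def test_all_objects_one_region(self):
        regions = self._regions()
        objs = points_table([[20, 15, 20], [10, 25, 10]], class_name="metastasis")
        tab = bq.region_summary(objs, regions)
        lung = tab[tab["region"] == "lung"].iloc[0]
        assert lung["fraction_metastasis"] == 1.0

    def test_fractions_sum_to_one_including_none(self):
        regions = self._regions()
        objs = points_table(
            [[20, 15, 20], [10, 45, 10], [10, 70, 10]], class_name="metastasis"
        )
        tab = bq.region_summary(objs, regions)
        assert tab["fraction_metastasis"].sum() == pytest.approx(1.0, abs=1e-9)
        none_row = tab[tab["region"] == "none"].iloc[0]
        assert none_row["count_metastasis"] == 1  # centroid on background kept

    def test_empty_object_table(self):
        tab = bq.region_summary(points_table(np.empty((0, 3))), self._regions())
        assert set(tab["region"]) == {"lung", "gut", "none"}

    def test_density_uses_region_volume(self):
        regions = self._regions()
        objs = points_table([[20, 15, 20]], class_name="metastasis")
        tab = bq.region_summary(objs, regions)
        lung = tab[tab["region"] == "lung"].iloc[0]
        expected_vol = 4 * 3 * 4 * 1000 / 1e9  # voxels * voxel volume mm3
        assert lung["region_volume_mm3"] == pytest.approx(expected_vol, rel=1e-12)
        assert lung["density_per_mm3_metastasis"] == pytest.approx(
            1 / expected_vol, rel=1e-12
        )


class TestDensityCorrelation:
    def _table(self, dens_a, dens_b):
        n = len(dens_a)
        return pd.DataFrame(
            {
                "region": [f"r{i}" for i in range(n)],
                "density_per_mm3_a": dens_a,
                "density_per_mm3_b": dens_b,
            }
        )

    def test_proportional_densities_give_r_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r, _ = bq.density_correlation(self._table(a, [2 * x for x in a]), "a", "b")
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks_give_spearman_minus_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r, _ = bq.density_correlation(
            self._table(a, a[::-1]), "a", "b", method="spearman"
        )
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        a = rng.random(10)
        b = rng.random(10)
        r, _ = bq.density_correlation(self._table(a, b), "a", "b")
        am, bm = a - a.mean(), b - b.mean()
        expected = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bq.density_correlation(self._table([1, 1, 1], [1, 2, 3]), "a", "b")

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            bq.density_correlation(self._table([1, 2], [3, 4]), "a", "b")


class TestDistributionSummary:
    def test_fraction_at_cutoff(self):
        s = bq.distribution_summary([1, 2, 3, 4], cutoffs=[2])
        assert s["fraction_le"][2.0] == 0.5

    def test_all_equal_at_own_cutoff(self):
        s = bq.distribution_summary([5, 5, 5], cutoffs=[5])
        assert s["fraction_le"][5.0] == 1.0

    def test_missing_values_excluded_and_counted(self):
        s = bq.distribution_summary([1.0, np.nan, 3.0], cutoffs=[2])
        assert s["n"] == 2
        assert s["n_excluded"] == 1

    def test_lognormal_fraction_matches_cdf(self, rng):
        from scipy.stats import lognorm

        median, sd = 0.002, 0.8
        vols = median * np.exp(sd * rng.standard_normal(4000))
        cutoff = 0.005
        s = bq.distribution_summary(vols, cutoffs=[cutoff])
        expected = lognorm.cdf(cutoff, s=sd, scale=median)
        assert s["fraction_le"][cutoff] == pytest.approx(expected, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bq.distribution_summary([np.nan])


class TestColocalization:
    def test_identical_masks_ratio_one(self, rng):
        arr = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        arr[0, 0, 0] = 1
        m = make_mask(arr)
        assert bq.colocalization_ratio(m, m, 0.0) == 1.0

    def test_disjoint_masks_ratio_zero(self):
        a = np.zeros((4, 4, 8), dtype=np.uint8)
        b = np.zeros((4, 4, 8), dtype=np.uint8)
        a[:, :, 0] = 1
        b[:, :, 7] = 1
        assert bq.colocalization_ratio(make_mask(a), make_mask(b), 0.0) == 0.0

    def test_half_overlap_slab(self):
        a = np.zeros((4, 4, 8), dtype=np.uint8)
        b = np.zeros((4, 4, 8), dtype=np.uint8)
        a[:, :, 0:4] = 1
        b[:, :, 2:6] = 1
        assert bq.colocalization_ratio(make_mask(a), make_mask(b), 0.0) == 0.5

    def test_monotone_in_tolerance(self):
        a = np.zeros((4, 4, 12), dtype=np.uint8)
        b = np.zeros((4, 4, 12), dtype=np.uint8)
        a[:, :, 0:6] = 1
        b[:, :, 5:7] = 1
        ratios = [
            bq.colocalization_ratio(make_mask(a), make_mask(b), tol)
            for tol in (0.0, 7.0, 14.0, 50.0)
        ]
        assert all(r2 >= r1 for r1, r2 in zip(ratios, ratios[1:]))
        assert ratios[0] < ratios[-1]

    def test_empty_source_rejected(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.ones((3, 3, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            bq.colocalization_ratio(make_mask(a), make_mask(b))

    def test_geometry_mismatch_rejected(self):
        a = make_mask(np.ones((3, 3, 3), dtype=np.uint8), spacing=(10, 10, 10))
        b = make_mask(np.ones((3, 3, 3), dtype=np.uint8), spacing=(5, 10, 10))
        with pytest.raises(bq.GeometryMismatchError):
            bq.colocalization_ratio(a, b)
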
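import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netdc import groupstats
from netdc.errors import InputError
from netdc.images import VolumeMap


def maps_from_values(values):
    """Build per-subject (V,1,1) VolumeMaps from an (n, V) array."""
    values = np.asarray(values, dtype=float)
    return [VolumeMap(data=row[:, None, None], affine=np.eye(4), kind="dc_z")
            for row in values]


def simple_design(n1, n2):
    x = np.c_[np.ones(n1 + n2), np.r_[np.ones(n1), np.zeros(n2)]]
    return groupstats.DesignMatrix(matrix=x, columns=["intercept", "group"])


class TestVoxelwiseGlm:
    def test_identical_maps_give_zero_t(self):
        maps = maps_from_values(np.tile(np.arange(5.0), (8, 1)))
        t_map, df = groupstats.voxelwise_glm_ttest(maps, simple_design(4, 4))
        np.testing.assert_array_equal(t_map.data.ravel(), 0.0)
        assert df == 6

    def test_matches_pooled_two_sample_t(self, rng):
        y = rng.standard_normal((12, 7))
        maps = maps_from_values(y)
        t_map, df = groupstats.voxelwise_glm_ttest(maps, simple_design(6, 6))
        oracle = stats.ttest_ind(y[:6], y[6:], equal_var=True).statistic
        np.testing.assert_allclose(t_map.data.ravel(), oracle, atol=1e-10)
        assert df == 10

    def test_constant_shift_leaves_t_unchanged(self, rng):
        y = rng.standard_normal((10, 6))
        t0, _ = groupstats.voxelwise_glm_ttest(maps_from_values(y), simple_design(5, 5))
        t1, _ = groupstats.voxelwise_glm_ttest(maps_from_values(y + 42.0),
                                               simple_design(5, 5))
        np.testing.assert_allclose(t0.data, t1.data, atol=1e-8)

    def test_covariate_collinear_with_group_rejected(self):
        n = 10
        group = np.r_[np.ones(5), np.zeros(5)]
        x = np.c_[np.ones(n), group, 2.0 * group]  # covariate duplicates group
        with pytest.raises(InputError, match="collinear"):
            groupstats.DesignMatrix(matrix=x, columns=["intercept", "group", "cov"])

    def test_covariate_adjustment_removes_confound(self, rng):
        # signal driven purely by a covariate: adjusted group t stays small
        n = 20
        cov = rng.standard_normal(n)
        y = np.outer(cov, np.ones(5)) + 0.01 * rng.standard_normal((n, 5))
        x = np.c_[np.ones(n), np.r_[np.ones(10), np.zeros(10)], cov]
        design = groupstats.DesignMatrix(matrix=x, columns=["intercept", "group", "cov"])
        t_map, _ = groupstats.voxelwise_glm_ttest(maps_from_values(y), design)
        assert np.all(np.abs(t_map.data.ravel()) < 3.0)


class TestFormClusters:
    def _tmap(self, data):
        return VolumeMap(data=np.asarray(data, dtype=float), affine=np.eye(4),
                         kind="t_stat")

    def test_zero_map_has_no_clusters(self):
        labels, clusters = groupstats.form_clusters(self._tmap(np.zeros((4, 4, 4))),
                                                    df=20)
        assert clusters == []
        assert labels.max() == 0

    def test_single_voxel_cluster(self):
        data = np.zeros((4, 4, 4))
        data[2, 2, 2] = 10.0
        labels, clusters = groupstats.form_clusters(self._tmap(data), df=20)
        assert len(clusters) == 1
        assert clusters[0]["extent"] == 1
        assert labels[2, 2, 2] == 1

    def test_diagonal_blobs_split_by_connectivity(self):
        # two L-shaped blobs whose closest voxels differ by (0,1,1):
        # diagonal (edge) contact only, never face contact
        data = np.zeros((6, 6, 6))
        blob1 = [(1, 1, 1), (1, 1, 2), (2, 1, 1)]
        blob2 = [(2, 2, 2), (2, 2, 3), (3, 2, 2)]
        for ijk in blob1 + blob2:
            data[ijk] = 10.0
        _, six = groupstats.form_clusters(self._tmap(data), df=20, connectivity=6)
        _, twentysix = groupstats.form_clusters(self._tmap(data), df=20, connectivity=26)
        assert len(six) == 2
        assert len(twentysix) == 1

    def test_sign_split_and_deterministic_ordering(self):
        data = np.zeros((6, 6, 6))
        data[0, 0, 0:3] = 8.0      # positive, extent 3
        data[4, 4, 4] = -9.0       # negative, extent 1
        labels, clusters = groupstats.form_clusters(self._tmap(data), df=20)
        assert [c["extent"] for c in clusters] == [3, 1]
        assert clusters[0]["sign"] == 1 and clusters[1]["sign"] == -1
        assert labels[0, 0, 1] == 1 and labels[4, 4, 4] == 2

    def test_axis_relabeling_preserves_components(self, rng):
        data = np.zeros((5, 6, 7))
        data[1:3, 2, 2] = 9.0
        data[4, 5, 6] = 9.0
        _, base = groupstats.form_clusters(self._tmap(data), df=15)
        _, transposed = groupstats.form_clusters(
            self._tmap(np.transpose(data, (2, 0, 1))), df=15)
        assert sorted(c["extent"] for c in base) == sorted(c["extent"] for c in transposed)


class TestPeakWorldCoordinates:
    def test_identity_affine_returns_voxel_index(self):
        data = np.zeros((5, 5, 5))
        data[1, 2, 3] = 7.0
        t_map = VolumeMap(data=data, affine=np.eye(4), kind="t_stat")
        labels = (data != 0).astype(int)
        peaks = groupstats.peak_world_coordinates(labels, t_map, np.eye(4))
        assert peaks[1][1] == (1.0, 2.0, 3.0)

    def test_scaled_shifted_affine(self):
        data = np.zeros((5, 5, 5))
        data[2, 0, 4] = -6.0
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        aff[:3, 3] = [-6.0, -6.0, -6.0]
        t_map = VolumeMap(data=data, affine=aff, kind="t_stat")
        labels = (data != 0).astype(int)
        peaks = groupstats.peak_world_coordinates(labels, t_map, aff)
        assert peaks[1][0] == -6.0
        assert peaks[1][1] == (0.0, -6.0, 6.0)

    def test_tie_breaks_to_smaller_linear_index(self):
        data = np.zeros((4, 4, 4))
        data[3, 3, 3] = 5.0
        data[0, 0, 1] = 5.0   # same |t|, smaller linear index
        labels = (data != 0).astype(int)  # one cluster id=1 (disjoint but same id is fine)
        t_map = VolumeMap(data=data, affine=np.eye(4), kind="t_stat")
        peaks = groupstats.peak_world_coordinates(labels, t_map, np.eye(4))
        assert peaks[1][2] == (0, 0, 1)


class TestClusterFdr:
    def test_zero_permutations_rejected(self, rng):
        maps = maps_from_values(rng.standard_normal((8, 5)))
        with pytest.raises(InputError):
            groupstats.cluster_fdr(maps, simple_design(4, 4), n_permutations=0)

    def test_no_clusters_gives_empty_report(self, rng):
        maps = maps_from_values(0.01 * rng.standard_normal((8, 5)))
        _, labels, report = groupstats.cluster_fdr(maps, simple_design(4, 4),
                                                   n_permutations=10, rng=0)
        assert report.clusters == []
        assert labels.max() == 0

    def test_freedman_lane_scheme_also_detects_planted_effect(self, rng):
        n1 = n2 = 8
        y = rng.standard_normal((n1 + n2, 27))
        y[:n1, :3] += 8.0
        grid = [VolumeMap(data=row.reshape(3, 3, 3), affine=np.eye(4), kind="dc_z")
                for row in y]
        _, _, report = groupstats.cluster_fdr(grid, simple_design(n1, n2),
                                              n_permutations=99, rng=1,
                                              scheme="freedman_lane")
        assert report.significant
        with pytest.raises(InputError, match="scheme"):
            groupstats.cluster_fdr(grid, simple_design(n1, n2),
                                   n_permutations=9, scheme="bootstrap")

    def test_strong_effect_found_and_bh_bounds_hold(self, rng):
        # 3 voxels shifted strongly in group 1; permutation p add-one bounded below
        n1 = n2 = 8
        y = rng.standard_normal((n1 + n2, 27))
        y[:n1, :3] += 8.0
        grid = [VolumeMap(data=row.reshape(3, 3, 3), affine=np.eye(4), kind="dc_z")
                for row in y]
        _, labels, report = groupstats.cluster_fdr(grid, simple_design(n1, n2),
                                                   n_permutations=99, rng=1)
        assert report.clusters, "planted effect not detected"
        best = report.clusters[0]
        assert best["sign"] == 1
        assert best["p_uncorrected"] >= 1.0 / 100.0       # add-one floor
        for c in report.clusters:
            assert c["p_fdr"] >= c["p_uncorrected"] - 1e-12
            assert 0.0 <= c["p_fdr"] <= 1.0
        assert best["significant"]


class TestSummaryStats:
    def test_identical_groups_give_zero_t(self):
        t, p, df = groupstats.two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0 and df == 18

    def test_raw_column_path_matches_scipy(self, rng):
        a = rng.normal(10, 2, 20)
        b = rng.normal(11, 2, 25)
        t, p, df = groupstats.two_sample_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        oracle = stats.ttest_ind(a, b, equal_var=True)
        np.testing.assert_allclose(t, oracle.statistic, atol=1e-10)
        np.testing.assert_allclose(p, oracle.pvalue, atol=1e-10)

    def test_report_covers_all_variables(self, rng):
        n = 12
        table = pd.DataFrame({
            "group": ["patient"] * n + ["control"] * n,
            "age": rng.normal(30, 5, 2 * n),
            "education": rng.normal(12, 2, 2 * n),
            "MoCA": rng.normal(27, 1, 2 * n),
            "BDI": rng.normal(8, 2, 2 * n),
            "sex": rng.choice(["M", "F"], 2 * n),
        })
        report = groupstats.summary_stat_tests(table)
        assert set(report["variable"]) == {"age", "education", "MoCA", "BDI", "sex"}
        assert (report["p"].between(0, 1)).all()

    def test_tiny_group_rejected(self):
        table = pd.DataFrame({"group": ["patient", "control", "control"],
                              "age": [30.0, 28.0, 29.0], "sex": ["F", "F", "M"],
                              "education": [12.0] * 3, "MoCA": [27.0] * 3,
                              "BDI": [8.0] * 3})
        with pytest.raises(InputError):
            groupstats.summary_stat_tests(table)
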
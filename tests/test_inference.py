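import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from dalff.inference import (
    build_design,
    connectivity_structure,
    estimate_smoothness,
    extract_cluster_table,
    fit_voxelwise_glm,
    grf_cluster_correct,
    one_sample_tmap,
    permutation_cluster_correct,
    t_to_z,
)


def smooth_maps(rng, n, shape, fwhm_vox=2.0):
    sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
    return ndimage.gaussian_filter(rng.standard_normal((n,) + shape), (0,) + (sigma,) * 3)


def make_covariates(n_patient, n_control, rng):
    n = n_patient + n_control
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["patient"] * n_patient + ["control"] * n_control,
            "age": rng.uniform(20, 80, n),
            "sex": rng.integers(0, 2, n),
            "score": rng.poisson(4, n),
        }
    )


class TestGlm:
    def test_matches_pooled_two_sample_t(self, rng):
        # oracle: textbook pooled two-sample t per voxel
        maps = rng.normal(size=(12, 50))
        cov = make_covariates(6, 6, rng)[["subject_id", "group"]]
        result = fit_voxelwise_glm(maps, cov)
        x, y = maps[:6], maps[6:]
        nx, ny = 6, 6
        sp = np.sqrt(((nx - 1) * x.var(axis=0, ddof=1) + (ny - 1) * y.var(axis=0, ddof=1)) / (nx + ny - 2))
        t_direct = (x.mean(axis=0) - y.mean(axis=0)) / (sp * np.sqrt(1 / nx + 1 / ny))
        assert result.df == 10
        assert np.allclose(result.t_map, t_direct, atol=1e-10)

    def test_null_calibration(self, rng):
        maps = rng.normal(size=(40, 1000))
        cov = make_covariates(20, 20, rng)
        result = fit_voxelwise_glm(maps, cov)
        p = 2 * stats.t.sf(np.abs(result.t_map), result.df)
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 4 * se

    def test_duplicated_group_column_rejected(self, rng):
        maps = rng.normal(size=(12, 10))
        cov = make_covariates(6, 6, rng)
        design, names = build_design(cov)
        design = np.column_stack([design, design[:, 1]])
        names = names + ["group_copy"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_voxelwise_glm(maps, cov, design=design, design_names=names)

    def test_constant_covariate_rejected(self, rng):
        maps = rng.normal(size=(12, 10))
        cov = make_covariates(6, 6, rng)
        cov["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            fit_voxelwise_glm(maps, cov)

    def test_too_few_subjects_rejected(self, rng):
        maps = rng.normal(size=(5, 10))
        cov = make_covariates(2, 3, rng)
        with pytest.raises(ValueError, match=">= 3 subjects"):
            fit_voxelwise_glm(maps, cov)

    def test_invariant_to_covariate_rescaling(self, rng):
        maps = rng.normal(size=(16, 30))
        cov = make_covariates(8, 8, rng)
        t1 = fit_voxelwise_glm(maps, cov).t_map
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] / 10.0  # decades instead of years
        t2 = fit_voxelwise_glm(maps, cov2).t_map
        assert np.allclose(t1, t2, atol=1e-8)


class TestOneSample:
    def test_matches_direct_formula(self, rng):
        maps = rng.normal(size=(20, 100))
        t, df = one_sample_tmap(maps)
        expected = maps.mean(axis=0) / (maps.std(axis=0, ddof=1) / np.sqrt(20))
        assert df == 19
        assert np.allclose(t, expected, atol=1e-10)

    def test_all_zero_maps(self):
        t, _ = one_sample_tmap(np.zeros((5, 10)))
        assert np.all(t == 0)

    def test_constant_nonzero_capped(self):
        t, _ = one_sample_tmap(np.full((5, 4), 3.0))
        assert np.all(t == 50.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            one_sample_tmap(np.zeros((1, 5)))


class TestSmoothness:
    def test_recovers_known_fwhm(self, rng):
        # 6 mm kernel on a 3 mm grid
        shape = (32, 32, 32)
        sigma = 6.0 / 3.0 / (2 * np.sqrt(2 * np.log(2)))
        maps = ndimage.gaussian_filter(rng.standard_normal((20,) + shape), (0,) + (sigma,) * 3)
        fwhm = estimate_smoothness(maps, np.ones(shape, bool), (3.0, 3.0, 3.0))
        assert np.all(np.abs(fwhm - 6.0) / 6.0 < 0.15)

    def test_white_noise_below_voxel_scale(self, rng):
        maps = rng.standard_normal((20, 24, 24, 24))
        fwhm = estimate_smoothness(maps, np.ones((24, 24, 24), bool), (2.0, 2.0, 2.0))
        assert np.all(fwhm < 4.0)

    def test_voxel_size_equivariance(self, rng):
        maps = smooth_maps(rng, 10, (16, 16, 16))
        mask = np.ones((16, 16, 16), bool)
        f1 = estimate_smoothness(maps, mask, (2.0, 2.0, 2.0))
        f2 = estimate_smoothness(maps, mask, (4.0, 4.0, 4.0))
        assert np.allclose(f2, 2 * f1)

    def test_flat_residuals_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            estimate_smoothness(np.zeros((3, 4, 4, 4)), np.ones((4, 4, 4), bool), (2, 2, 2))


class TestTtoZ:
    def test_tail_probabilities_match(self):
        t_vals = np.array([-3.0, -0.5, 0.0, 1.2, 4.0])
        z = t_to_z(t_vals, df=20)
        assert np.allclose(stats.norm.sf(z), stats.t.sf(t_vals, 20), rtol=1e-10)

    def test_sign_preserved(self):
        z = t_to_z(np.array([-2.0, 2.0]), df=15)
        assert z[0] < 0 < z[1]


class TestClusterTable:
    def test_schema_fixture_row(self):
        # single 59-voxel component with an injected peak value and location
        shape = (12, 12, 12)
        comp = np.zeros(shape, bool)
        comp[2:5, 3:8, 4:8] = True  # 3*5*4 = 60; drop one voxel -> 59
        comp[2, 3, 4] = False
        stat = np.zeros(shape)
        stat[comp] = 3.0
        stat[3, 5, 5] = 4.1322
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-27.0, -6.0, -15.0]  # puts voxel (3, 5, 5) at (-18, 9, 0)
        table = extract_cluster_table([(comp, "+", 0.001)], stat, affine)
        row = table.iloc[0]
        assert row.n_voxels == 59
        assert row.peak_stat == pytest.approx(4.1322)
        assert (row.peak_x, row.peak_y, row.peak_z) == (-18.0, 9.0, 0.0)

    def test_two_components_conserve_voxels(self):
        shape = (10, 10, 10)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[0:2, 0:2, 0:2] = True
        b[6:9, 6:9, 6:9] = True
        stat = (a.astype(float) - b.astype(float)) * 3
        table = extract_cluster_table([(a, "+", 0.01), (b, "-", 0.01)], stat, np.eye(4))
        assert len(table) == 2
        assert table.n_voxels.sum() == a.sum() + b.sum()

    def test_negative_component_peak(self):
        shape = (6, 6, 6)
        comp = np.zeros(shape, bool)
        comp[1:3, 1:3, 1:3] = True
        stat = np.zeros(shape)
        stat[comp] = -2.0
        stat[2, 2, 2] = -5.5
        table = extract_cluster_table([(comp, "-", 0.01)], stat, np.eye(4))
        assert table.iloc[0].sign == "-"
        assert table.iloc[0].peak_stat == -5.5

    def test_empty_input(self):
        assert len(extract_cluster_table([], np.zeros((3, 3, 3)), np.eye(4))) == 0

    def test_peak_inside_cluster(self, rng):
        shape = (8, 8, 8)
        comp = np.zeros(shape, bool)
        comp[2:6, 2:6, 2:6] = True
        stat = rng.normal(size=shape)
        table = extract_cluster_table([(comp, "+", 0.01)], stat, np.eye(4))
        peak_idx = tuple(int(v) for v in table.iloc[0][["peak_x", "peak_y", "peak_z"]])
        assert comp[peak_idx]


class TestGrfCorrection:
    def test_zero_map_empty_table(self, rng):
        cov = make_covariates(5, 5, rng)
        maps = rng.normal(size=(10, 4 * 4 * 4)) * 1e-8
        result = fit_voxelwise_glm(maps, cov)
        table, labels = grf_cluster_correct(
            result, np.ones((4, 4, 4), bool), np.eye(4), (3, 3, 3), fwhm_mm=np.array([6.0] * 3)
        )
        assert len(table) == 0
        assert np.all(labels == 0)

    def test_planted_block_recovered(self, rng):
        shape = (16, 16, 16)
        n = 40
        maps = smooth_maps(rng, n, shape)
        truth = np.zeros(shape, bool)
        truth[5:11, 5:11, 5:11] = True
        maps[:20][:, truth] += 2.5  # patients
        cov = make_covariates(20, 20, rng)
        result = fit_voxelwise_glm(maps.reshape(n, -1), cov)
        table, labels = grf_cluster_correct(result, np.ones(shape, bool), np.eye(4), (3, 3, 3))
        found = labels > 0
        dice = 2 * (found & truth).sum() / (found.sum() + truth.sum())
        assert dice >= 0.5
        assert (table.sign == "+").any()

    def test_invalid_thresholds_rejected(self, rng):
        cov = make_covariates(5, 5, rng)
        result = fit_voxelwise_glm(rng.normal(size=(10, 8)), cov)
        with pytest.raises(ValueError):
            grf_cluster_correct(result, np.ones((2, 2, 2), bool), np.eye(4), (3, 3, 3), voxel_p=1.5)


class TestPermutationCorrection:
    def test_degenerate_design_rejected(self, rng):
        cov = make_covariates(1, 1, rng)[["subject_id", "group"]]
        with pytest.raises(ValueError):
            permutation_cluster_correct(
                rng.normal(size=(2, 8)), cov, np.ones((2, 2, 2), bool), np.eye(4), n_perm=100
            )

    def test_small_n_perm_rejected(self, rng):
        cov = make_covariates(5, 5, rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_cluster_correct(
                rng.normal(size=(10, 8)), cov, np.ones((2, 2, 2), bool), np.eye(4), n_perm=10
            )

    def test_agrees_with_grf_on_strong_effect(self, rng):
        shape = (14, 14, 14)
        n = 30
        maps = smooth_maps(rng, n, shape)
        truth = np.zeros(shape, bool)
        truth[4:10, 4:10, 4:10] = True
        maps[:15][:, truth] += 3.0
        cov = make_covariates(15, 15, rng)
        flat = maps.reshape(n, -1)
        result = fit_voxelwise_glm(flat, cov)
        mask = np.ones(shape, bool)
        _, grf_labels = grf_cluster_correct(result, mask, np.eye(4), (3, 3, 3))
        _, perm_labels = permutation_cluster_correct(
            flat, cov, mask, np.eye(4), n_perm=150, seed=0
        )
        a, b = grf_labels > 0, perm_labels > 0
        dice = 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)
        assert dice >= 0.7


def test_connectivity_structures():
    assert connectivity_structure(6).sum() == 7
    assert connectivity_structure(26).sum() == 27
    with pytest.raises(ValueError):
        connectivity_structure(4)
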
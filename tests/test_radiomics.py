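"""Radiomics operators against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from esotox.radiomics import (OFFSETS_3D, RadiomicsConfig,
                              TextureUndefinedError, discretize,
                              entropy_feature, expected_feature_count,
                              extract_radiomics, first_order_features,
                              glcm_features, glcm_matrix, glrlm_features,
                              glrlm_matrix, log_filter, wavelet_bands)
from esotox.volume import VolumeGrid


class TestDiscretize:
    def test_maximum_maps_into_top_bin(self):
        labels = discretize(np.arange(101.0), 20)
        assert labels[-1] == 20
        assert labels[0] == 1

    def test_constant_region_single_bin(self):
        labels = discretize(np.full(50, 3.3), 8)
        assert set(labels) == {1}

    @pytest.mark.parametrize("bins", [2, 7, 32])
    def test_occupancy_matches_histogram_oracle(self, rng, bins):
        values = rng.uniform(-10, 10, 500)
        labels = discretize(values, bins)
        counts = np.bincount(labels, minlength=bins + 1)[1:]
        expected, _ = np.histogram(values, bins=bins,
                                   range=(values.min(), values.max()))
        np.testing.assert_array_equal(counts, expected)


class TestFirstOrder:
    def test_constant_region(self):
        f = first_order_features(np.full(20, 5.0))
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert entropy_feature(np.full(20, 5.0), 16) == 0.0

    def test_simple_values(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0]))
        assert f["Mean"] == 2.0
        assert f["Range"] == 2.0
        assert f["Median"] == 2.0

    def test_skewness_kurtosis_match_direct_moment_oracle(self, rng):
        v = rng.gamma(2.0, 1.5, 100)
        f = first_order_features(v)
        m = v - v.mean()
        m2 = np.mean(m**2)
        skew = np.mean(m**3) / m2**1.5
        kurt = np.mean(m**4) / m2**2  # non-excess
        assert f["Skewness"] == pytest.approx(skew, rel=1e-10)
        assert f["Kurtosis"] == pytest.approx(kurt, rel=1e-10)


def brute_force_glcm(labels, mask, offsets=OFFSETS_3D):
    """Independent co-occurrence enumeration by explicit voxel loops."""
    nb = int(labels[mask.astype(bool)].max())
    counts = np.zeros((nb, nb))
    shape = labels.shape
    for (dx, dy, dz) in offsets:
        for i, j, k in itertools.product(*(range(n) for n in shape)):
            i2, j2, k2 = i + dx, j + dy, k + dz
            if not (0 <= i2 < shape[0] and 0 <= j2 < shape[1] and 0 <= k2 < shape[2]):
                continue
            if mask[i, j, k] and mask[i2, j2, k2]:
                a, b = labels[i, j, k] - 1, labels[i2, j2, k2] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_constant_region(self):
        labels = np.ones((4, 4, 4), dtype=np.int64)
        mask = np.ones((4, 4, 4), dtype=bool)
        f = glcm_features(labels, mask)
        assert f["Contrast"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Dissimilarity"] == 0.0

    def test_matrix_is_symmetric(self, rng):
        labels = rng.integers(1, 6, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.8
        mask[0, 0, 0] = mask[0, 0, 1] = True
        p = glcm_matrix(labels, mask)
        np.testing.assert_allclose(p, p.T)

    def test_two_voxel_pair_contrast_closed_form(self):
        labels = np.array([[[1]], [[2]]])  # 2 x 1 x 1, two levels
        mask = np.ones((2, 1, 1), dtype=bool)
        f = glcm_features(labels, mask)
        # p = [[0, .5], [.5, 0]]; contrast = sum p(i,j)(i-j)^2 = 1
        assert f["Contrast"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_exhaustive_enumeration_on_4cubed(self, rng):
        labels = rng.integers(1, 5, (4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        p = glcm_matrix(labels, mask)
        p_oracle = brute_force_glcm(labels, mask)
        np.testing.assert_allclose(p, p_oracle, atol=1e-12)
        nb = p.shape[0]
        ii, jj = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
        contrast_oracle = float((p_oracle * (ii - jj) ** 2).sum())
        assert glcm_features(labels, mask)["Contrast"] == pytest.approx(
            contrast_oracle, abs=1e-10)

    def test_single_voxel_mask_rejected(self):
        labels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(TextureUndefinedError):
            glcm_matrix(labels, mask)


def brute_force_runs(labels, mask, direction):
    """Independent run enumeration: walk every line voxel by voxel."""
    shape = labels.shape
    d = np.array(direction)
    runs = []
    for start in itertools.product(*(range(n) for n in shape)):
        prev = np.array(start) - d
        if (0 <= prev).all() and (prev < shape).all() and mask[tuple(prev)] \
                and labels[tuple(prev)] == labels[start] and mask[start]:
            continue  # not a run start
        if not mask[start]:
            continue
        length, pos = 0, np.array(start)
        while (0 <= pos).all() and (pos < shape).all() and mask[tuple(pos)] \
                and labels[tuple(pos)] == labels[start]:
            length += 1
            pos = pos + d
        runs.append((labels[start], length))
    return runs


class TestGLRLM:
    def test_constant_line_single_run_lre(self):
        n = 7
        labels = np.ones((1, 1, n), dtype=np.int64)
        mask = np.ones((1, 1, n), dtype=bool)
        matrix = glrlm_matrix(labels, mask, (0, 0, 1))
        assert matrix.sum() == 1
        assert matrix[0, n - 1] == 1
        # LRE of the along-line direction: one run of length n -> n^2
        l = np.arange(1, matrix.shape[1] + 1)
        lre = (matrix.sum(axis=0) * l**2).sum() / matrix.sum()
        assert lre == n**2

    def test_alternating_line_all_runs_length_one(self):
        labels = np.array([[[1, 2] * 4]], dtype=np.int64)
        mask = np.ones_like(labels, dtype=bool)
        f = glrlm_features(labels, mask)
        assert f["Rp"] == pytest.approx(1.0)
        assert f["Sre"] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 0, 1), (1, 1, 0),
                                           (1, -1, 1), (0, 1, -1)])
    def test_matrix_matches_run_walk_oracle(self, rng, direction):
        labels = rng.integers(1, 4, (4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.85
        mask[0, 0, 0] = mask[1, 0, 0] = True
        matrix = glrlm_matrix(labels, mask, direction)
        oracle = np.zeros_like(matrix)
        for level, length in brute_force_runs(labels, mask, direction):
            oracle[level - 1, length - 1] += 1
        np.testing.assert_array_equal(matrix, oracle)

    def test_sre_matches_enumeration(self, rng):
        labels = rng.integers(1, 4, (4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        f = glrlm_features(labels, mask)
        sres = []
        for d in OFFSETS_3D:
            runs = brute_force_runs(labels, mask, d)
            lengths = np.array([l for _, l in runs], dtype=float)
            sres.append((1.0 / lengths**2).sum() / len(lengths))
        assert f["Sre"] == pytest.approx(np.mean(sres), rel=1e-10)


class TestFilters:
    def test_wavelet_constant_volume(self):
        vol = VolumeGrid(np.full((8, 8, 8), 5.0))
        bands = wavelet_bands(vol)
        assert set(bands) == {"".join(p) for p in itertools.product("LH", repeat=3)}
        np.testing.assert_allclose(bands["LLL"].values, 5.0, atol=1e-10)
        for name, band in bands.items():
            if name != "LLL":
                np.testing.assert_allclose(band.values, 0.0, atol=1e-10)

    def test_log_constant_volume_is_zero(self):
        vol = VolumeGrid(np.full((12, 12, 12), 40.0))
        out = log_filter(vol, 2.0)
        np.testing.assert_allclose(out.values[2:-2, 2:-2, 2:-2], 0.0, atol=1e-8)

    def test_log_gaussian_blob_peak_matches_scale_space_closed_form(self):
        # blob exp(-r^2/(2 s^2)); LoG(sigma) at centre = -3 s^3 / (s^2+sigma^2)^(5/2)
        s, sigma = 4.0, 2.0
        n = 41
        c = (n - 1) / 2
        grid = np.arange(n)
        X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
        blob = np.exp(-((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) / (2 * s**2))
        out = log_filter(VolumeGrid(blob), sigma)
        expected = -3.0 * s**3 / (s**2 + sigma**2) ** 2.5
        assert out.values[int(c), int(c), int(c)] == pytest.approx(expected, rel=0.05)


@pytest.fixture(scope="module")
def ct_mask():
    rng = np.random.default_rng(9)
    ct = VolumeGrid(rng.normal(40, 30, (12, 12, 12)))
    mask = np.zeros((12, 12, 12), dtype=np.uint8)
    mask[2:10, 2:10, 2:10] = 1
    return ct, VolumeGrid(mask)


class TestExtraction:
    def test_identical_patients_identical_vectors(self, ct_mask):
        ct, mask = ct_mask
        config = RadiomicsConfig(bin_counts=(8, 16), log_sigmas_mm=(1.0,))
        a = extract_radiomics(ct, mask, config)
        b = extract_radiomics(ct.copy(), mask.copy(), config)
        assert a == b

    @pytest.mark.parametrize("config", [
        RadiomicsConfig(bin_counts=(8,), image_filters=("original",)),
        RadiomicsConfig(bin_counts=(8, 16), image_filters=("original", "wavelet"),
                        texture_families=("GLCM",)),
        RadiomicsConfig(bin_counts=(8, 16, 32), log_sigmas_mm=(1.0, 2.0)),
    ])
    def test_feature_count_matches_config_formula(self, ct_mask, config):
        ct, mask = ct_mask
        features = extract_radiomics(ct, mask, config)
        assert len(features) == expected_feature_count(config)

    def test_constant_ct_all_contrasts_zero(self):
        ct = VolumeGrid(np.full((10, 10, 10), 25.0))
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[2:8, 2:8, 2:8] = 1
        features = extract_radiomics(
            ct, VolumeGrid(mask),
            RadiomicsConfig(bin_counts=(8,), image_filters=("original",)))
        assert all(v == 0.0 for k, v in features.items() if "Contrast" in k)

    def test_rotation_about_z_leaves_direction_merged_texture_invariant(self, rng):
        vals = rng.normal(0, 1, (10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.7
        mask[:2, :2, :2] = True
        ct = VolumeGrid(vals)
        rot_ct = VolumeGrid(np.rot90(vals, axes=(0, 1)).copy())
        rot_mask = np.rot90(mask, axes=(0, 1)).copy()
        from esotox.radiomics import discretize as disc
        labels = np.zeros(vals.shape, dtype=np.int64)
        labels[mask] = disc(vals[mask], 8)
        rlabels = np.rot90(labels, axes=(0, 1)).copy()
        for name, value in glcm_features(labels, mask).items():
            assert glcm_features(rlabels, rot_mask)[name] == pytest.approx(value, abs=1e-9)
        for name, value in glrlm_features(labels, mask).items():
            assert glrlm_features(rlabels, rot_mask)[name] == pytest.approx(value, abs=1e-9)

    def test_unsupported_families_rejected(self):
        with pytest.raises(NotImplementedError):
            RadiomicsConfig(texture_families=("GLSZM",))
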
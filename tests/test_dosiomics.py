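"""Dose moments, DVH metrics and dose texture against analytic oracles."""

import numpy as np
import pytest

from esotox.dosiomics import (DosiomicsConfig, UndefinedCentroidError,
                              dose_moments, dose_texture, dvh, dx,
                              expected_dosiomics_count, extract_dosiomics,
                              moment_indices, vx)
from esotox.volume import VolumeGrid


def brute_force_eta(dose, mask, spacing):
    """Independent triple-loop computation of the 63 invariant moments."""
    sx, sy, sz = spacing
    dv = sx * sy * sz
    total = 0.0
    cx = cy = cz = 0.0
    nx, ny, nz = dose.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    d = dose[i, j, k]
                    total += d
                    cx += i * sx * d
                    cy += j * sy * d
                    cz += k * sz * d
    cx, cy, cz = cx / total, cy / total, cz / total
    mu000 = total * dv
    out = {}
    for p, q, r in moment_indices():
        mu = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if mask[i, j, k]:
                        mu += ((i * sx - cx) ** p * (j * sy - cy) ** q
                               * (k * sz - cz) ** r * dose[i, j, k] * dv)
        out[f"moment_eta_{p}{q}{r}"] = mu / mu000 ** (1.0 + (p + q + r) / 3.0)
    return out


def gaussian_dose_volume(spacing, n):
    """Smooth analytic dose field sampled at the requested resolution, with a
    spherical mask — same physical object at every spacing."""
    s = spacing
    coords = (np.arange(n) + 0.5) * s
    c = n * s / 2.0
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    r2 = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2
    dose = 60.0 * np.exp(-((X - c - 3.0) ** 2 + (Y - c) ** 2) / 200.0 - (Z - c) ** 2 / 800.0)
    mask = r2 <= (n * s / 2.0 - 2.0) ** 2
    return (VolumeGrid(dose, (s, s, s)), VolumeGrid(mask.astype(np.uint8), (s, s, s)))


class TestMoments:
    def test_63_indices_from_64_combinations(self):
        idx = moment_indices()
        assert len(idx) == 63
        assert (0, 0, 0) not in idx
        assert len(idx) + 1 == 4 ** 3  # 64 combinations before exclusion

    def test_exactly_63_features_emitted(self, rng):
        dose = VolumeGrid(rng.uniform(1, 10, (5, 5, 5)))
        mask = VolumeGrid(np.ones((5, 5, 5), dtype=np.uint8))
        assert len(dose_moments(dose, mask)) == 63

    def test_mirror_symmetric_dose_zero_odd_moments(self):
        # symmetric about the centroid in x -> eta vanishes for odd p
        x = np.exp(-((np.arange(7) - 3.0) ** 2) / 4.0)
        dose = np.broadcast_to(x[:, None, None], (7, 5, 5)).copy()
        moments = dose_moments(VolumeGrid(dose), VolumeGrid(np.ones((7, 5, 5), np.uint8)))
        for name, value in moments.items():
            p = int(name.split("_")[-1][0])
            if p % 2 == 1:
                assert value == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_triple_loop_on_3cubed(self, rng):
        dose = rng.uniform(0.5, 5.0, (3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        spacing = (1.0, 1.0, 2.0)
        ours = dose_moments(VolumeGrid(dose, spacing),
                            VolumeGrid(mask.astype(np.uint8), spacing))
        oracle = brute_force_eta(dose, mask, spacing)
        for name in oracle:
            assert ours[name] == pytest.approx(oracle[name], abs=1e-10)

    def test_scale_invariance_under_grid_resampling(self):
        # same physical dose object sampled at 1 mm and 2 mm: eta drifts < 2%
        fine = gaussian_dose_volume(1.0, 32)
        coarse = gaussian_dose_volume(2.0, 16)
        eta_fine = dose_moments(*fine)
        eta_coarse = dose_moments(*coarse)
        for name, value in eta_fine.items():
            if abs(value) > 1e-4:  # drift meaningful only away from zero
                drift = abs(eta_coarse[name] - value) / abs(value)
                assert drift < 0.02, (name, value, eta_coarse[name])

    def test_dose_scaling_covariance_law(self, rng):
        """Under D -> kD each eta transforms exactly as k^(-(p+q+r)/3) eta."""
        dose = rng.uniform(0.5, 5.0, (6, 6, 6))
        mask = VolumeGrid(np.ones((6, 6, 6), np.uint8))
        k = 3.7
        base = dose_moments(VolumeGrid(dose), mask)
        scaled = dose_moments(VolumeGrid(k * dose), mask)
        for name, value in base.items():
            n = sum(int(c) for c in name.split("_")[-1])
            assert scaled[name] == pytest.approx(k ** (-n / 3.0) * value, rel=1e-9)

    def test_zero_total_dose_rejected(self):
        dose = VolumeGrid(np.zeros((4, 4, 4)))
        mask = VolumeGrid(np.ones((4, 4, 4), np.uint8))
        with pytest.raises(UndefinedCentroidError):
            dose_moments(dose, mask)


class TestDVH:
    def _uniform(self, gy=20.0, shape=(10, 10, 10)):
        dose = VolumeGrid(np.full(shape, gy))
        mask = VolumeGrid(np.ones(shape, np.uint8))
        return dvh(dose, mask)

    def test_uniform_dose_vx(self):
        curve = self._uniform(20.0)
        assert vx(curve, 10.0).pct == 100.0
        assert vx(curve, 30.0).pct == 0.0
        assert vx(curve, 10.0).cc == pytest.approx(1.0)  # 1000 voxels of 1 mm^3

    def test_v0_conservation_equals_mask_volume(self, rng):
        shape = (7, 7, 7)
        dose = VolumeGrid(rng.uniform(0.5, 60.0, shape), (1.0, 1.0, 2.5))
        mask = VolumeGrid((rng.random(shape) < 0.6).astype(np.uint8), (1.0, 1.0, 2.5))
        curve = dvh(dose, mask)
        expected_cc = mask.values.sum() * 2.5 / 1000.0
        assert curve.volume_cc[0] == pytest.approx(expected_cc, abs=1e-9)
        assert curve.total_cc == pytest.approx(expected_cc, abs=1e-9)

    def test_curve_is_monotone_non_increasing(self, rng):
        dose = VolumeGrid(rng.uniform(0, 60, (8, 8, 8)))
        curve = dvh(dose, VolumeGrid(np.ones((8, 8, 8), np.uint8)))
        assert np.all(np.diff(curve.volume_cc) <= 0)
        assert curve.volume_cc[-1] == 0.0

    def test_linear_ramp_v30_and_d50(self):
        # 0 -> 60 Gy linearly along the tube axis
        n = 60
        ramp = np.broadcast_to(np.linspace(0, 60, n)[None, None, :], (4, 4, n)).copy()
        curve = dvh(VolumeGrid(ramp), VolumeGrid(np.ones((4, 4, n), np.uint8)))
        layer_pct = 100.0 / n  # one voxel layer
        assert vx(curve, 30.0).pct == pytest.approx(50.0, abs=layer_pct)
        assert dx(curve, 50.0) == pytest.approx(30.0, abs=60.0 / n)

    def test_dx_boundaries(self, rng):
        dose = VolumeGrid(rng.uniform(5.0, 55.0, (6, 6, 6)))
        curve = dvh(dose, VolumeGrid(np.ones((6, 6, 6), np.uint8)))
        assert dx(curve, 100.0) == pytest.approx(curve.min_dose)
        assert dx(curve, 0.0) == pytest.approx(curve.max_dose)
        assert vx(curve, curve.min_dose - 1.0).pct == 100.0

    def test_dvh_shifts_exactly_under_dose_scaling(self, rng):
        dose = rng.uniform(0, 60, (6, 6, 6))
        mask = VolumeGrid(np.ones((6, 6, 6), np.uint8))
        k = 2.5
        a = dvh(VolumeGrid(dose), mask)
        b = dvh(VolumeGrid(k * dose), mask)
        for x in (5.0, 20.0, 40.0):
            assert vx(b, k * x).pct == vx(a, x).pct


class TestDoseTexture:
    def test_uniform_dose_contrast_zero(self):
        dose = VolumeGrid(np.full((6, 6, 6), 20.0))
        mask = VolumeGrid(np.ones((6, 6, 6), np.uint8))
        features = dose_texture(dose, mask, 16, families=("GLCM",))
        assert features["glcm_Contrast_bin16"] == 0.0

    def test_extract_prefixes_and_counts(self, rng):
        dose = VolumeGrid(rng.uniform(1, 60, (8, 8, 8)))
        mask = VolumeGrid(np.ones((8, 8, 8), np.uint8))
        config = DosiomicsConfig()
        features = extract_dosiomics(dose, mask, config)
        assert all(name.startswith("dose_") for name in features)
        moment_block = [n for n in features if n.startswith("dose_moment_eta_")]
        assert len(moment_block) == 63
        assert len(features) == expected_dosiomics_count(config)

    def test_identical_patients_identical_vectors(self, rng):
        dose = VolumeGrid(rng.uniform(1, 60, (8, 8, 8)))
        mask = VolumeGrid(np.ones((8, 8, 8), np.uint8))
        assert extract_dosiomics(dose, mask) == extract_dosiomics(dose.copy(), mask.copy())

    def test_v099_interpretations_differ(self, rng):
        dose = VolumeGrid(rng.uniform(0.5, 60, (8, 8, 8)))
        mask = VolumeGrid(np.ones((8, 8, 8), np.uint8))
        absolute = extract_dosiomics(dose, mask, DosiomicsConfig(v099_interpretation="gy"))
        relative = extract_dosiomics(dose, mask, DosiomicsConfig(v099_interpretation="relative"))
        assert absolute["dose_dvh_V0.99Gy_pct"] >= relative["dose_dvh_V0.99Gy_pct"]
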
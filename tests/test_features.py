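"""Family extractors: worked micro-examples, analytic limits, bounds, and a
direct-summation oracle on random matrices."""

import numpy as np
import pytest

from conftest import grid_to_qvoi
from hetex.config import HetexConfig
from hetex.features import (canonical_feature_names, compute_all_features,
                            cooccurrence_features, ngldm_features,
                            ngtdm_features, normalized_cooccurrence_features,
                            register_feature, run_length_features,
                            size_zone_features, texture_spectrum_features,
                            tfc_cooccurrence_features, unregister_feature,
                            voxel_statistics)
from hetex.parent_matrices import (CooccurrenceMatrix, NgldmMatrix,
                                   RunLengthMatrix, SizeZoneMatrix,
                                   cooccurrence, ngtdm)
from hetex.volume_io import ImageVolume, VoiMask


def _cooc(p, values=None):
    p = np.asarray(p, dtype=float)
    values = np.arange(1, len(p) + 1, dtype=float) if values is None else values
    return CooccurrenceMatrix(p, 1, np.asarray(values, float))


class TestCooccurrenceFeatures:
    def test_worked_example(self):
        f = cooccurrence_features(_cooc([[0.5, 0.25], [0.25, 0.0]]))
        assert f["contrast"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.5)
        assert f["second_angular_moment"] == pytest.approx(0.375)
        assert f["homogeneity"] == pytest.approx(0.75)
        assert f["dissimilarity"] == pytest.approx(0.5)
        assert f["inverse_difference_moment"] == pytest.approx(0.75)

    def test_single_entry_limits(self):
        f = cooccurrence_features(_cooc([[1.0, 0.0], [0.0, 0.0]]))
        assert f["contrast"] == 0.0
        assert f["entropy"] == 0.0
        assert f["second_angular_moment"] == 1.0

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(30):
            raw = rng.random((5, 5))
            p = (raw + raw.T) / (raw + raw.T).sum()
            f = cooccurrence_features(_cooc(p))
            assert f["contrast"] >= 0
            assert 0 < f["second_angular_moment"] <= 1

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 9))
            raw = rng.random((k, k))
            p = (raw + raw.T) / (raw + raw.T).sum()
            f = cooccurrence_features(_cooc(p))
            exp = {"second_angular_moment": 0.0, "contrast": 0.0, "entropy": 0.0,
                   "homogeneity": 0.0, "dissimilarity": 0.0,
                   "inverse_difference_moment": 0.0}
            for i in range(k):
                for j in range(k):
                    v = p[i, j]
                    exp["second_angular_moment"] += v * v
                    exp["contrast"] += (i - j) ** 2 * v
                    exp["entropy"] -= v * np.log2(v) if v > 0 else 0.0
                    exp["homogeneity"] += v / (1 + abs(i - j))
                    exp["dissimilarity"] += abs(i - j) * v
                    exp["inverse_difference_moment"] += v / (1 + (i - j) ** 2)
            for key, val in exp.items():
                assert f[key] == pytest.approx(val, rel=1e-12)


class TestNormalizedCooccurrence:
    def test_diagonal_matrix_correlation_one(self):
        md = CooccurrenceMatrix(np.diag([0.5, 0.5]), 1,
                                np.array([-1.0, 1.0]), True, False)
        assert normalized_cooccurrence_features(md)["correlation"] == pytest.approx(1.0)
        # hand-computed non-diagonal case: [[1,1,2,2]], one direction
        q = grid_to_qvoi([[1, 1, 2, 2]], L=2)
        m = cooccurrence(q, 1, normalized=True, directions=[(0, 0, 1)])
        f = normalized_cooccurrence_features(m)
        assert f["correlation"] == pytest.approx(1.0 / 3.0)

    def test_degenerate_constant_voi(self):
        q = grid_to_qvoi(np.ones((2, 3, 3), dtype=int), L=2)
        m = cooccurrence(q, normalized=True)
        warn = []
        f = normalized_cooccurrence_features(m, warn)
        assert f["correlation"] == 0.0
        assert warn and "zero marginal variance" in warn[0]

    def test_correlation_bounded(self, rng):
        for _ in range(30):
            raw = rng.random((4, 4))
            p = (raw + raw.T) / (raw + raw.T).sum()
            values = np.arange(1.0, 5.0)
            marg = p.sum(1)
            mu = marg @ values
            sd = np.sqrt(marg @ (values - mu) ** 2)
            m = CooccurrenceMatrix(p, 1, (values - mu) / sd, True, False)
            assert -1 - 1e-9 <= normalized_cooccurrence_features(m)["correlation"] <= 1 + 1e-9


class TestRunLengthFeatures:
    def test_worked_example(self):
        r = np.array([[0, 1, 0], [0, 0, 1]])  # runs (1,2) and (2,3)
        f = run_length_features(RunLengthMatrix(r, 2, 5, 1))
        assert f["short_run_emphasis"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["long_run_emphasis"] == pytest.approx(6.5)
        assert f["run_percentage"] == pytest.approx(2 / 5)

    def test_single_run(self):
        r = np.zeros((2, 6), dtype=int)
        r[0, 5] = 1
        f = run_length_features(RunLengthMatrix(r, 1, 6, 1))
        assert f["short_run_emphasis"] == pytest.approx(1 / 36)
        assert f["long_run_emphasis"] == pytest.approx(36)
        assert f["run_percentage"] == pytest.approx(1 / 6)

    def test_bounds(self, rng):
        for _ in range(20):
            r = rng.integers(0, 5, size=(3, 4))
            if r.sum() == 0:
                r[0, 0] = 1
            f = run_length_features(RunLengthMatrix(r, int(r.sum()), 50, 13))
            assert f["short_run_emphasis"] <= 1 + 1e-12
            assert f["long_run_emphasis"] >= 1 - 1e-12


class TestSizeZoneFeatures:
    def test_worked_example(self):
        z = np.array([[0, 0, 1], [0, 0, 1]])  # zones (1, 3) and (2, 3)
        f = size_zone_features(SizeZoneMatrix(z, 2, 6))
        assert f["short_zone_emphasis"] == pytest.approx(1 / 9)
        assert f["zone_percentage"] == pytest.approx(2 / 6)

    def test_single_small_low_zone(self):
        z = np.zeros((3, 2), dtype=int)
        z[0, 0] = 1  # one zone, level 1, size 1
        f = size_zone_features(SizeZoneMatrix(z, 1, 1))
        assert f["low_intensity_short_zone_emphasis"] == pytest.approx(1.0)

    def test_fragmented_maximal_sze(self):
        z = np.zeros((4, 3), dtype=int)
        z[:, 0] = [3, 2, 4, 1]  # all zones size 1
        f = size_zone_features(SizeZoneMatrix(z, 10, 10))
        assert f["short_zone_emphasis"] == pytest.approx(1.0)


class TestNgtdmFeatures:
    def test_constant_voi_degenerate(self):
        v = ngtdm(grid_to_qvoi(np.ones((3, 3, 3), dtype=int), L=2))
        f = ngtdm_features(v)
        assert f["contrast"] == 0.0
        assert f["complexity"] == 0.0
        assert f["coarseness"] == pytest.approx(1e12)

    def test_checkerboard_less_coarse_than_constant(self):
        yy, xx = np.indices((6, 6))
        checker = ((yy + xx) % 2 + 1).astype(int)
        f_check = ngtdm_features(ngtdm(grid_to_qvoi(checker, L=2)))
        f_const = ngtdm_features(ngtdm(grid_to_qvoi(np.ones((6, 6), int), L=2)))
        assert f_check["coarseness"] < f_const["coarseness"]
        assert f_check["contrast"] > 0


class TestNgldmFeatures:
    def test_single_entry(self):
        q = np.zeros((2, 27), dtype=int)
        q[0, 3] = 1
        f = ngldm_features(NgldmMatrix(q, 1, 0))
        assert f["entropy"] == 0.0
        assert f["second_moment"] == 1.0

    def test_constant_cube_maximizes_large_number_emphasis(self, rng):
        const = grid_to_qvoi(np.ones((4, 4, 4), dtype=int), L=3)
        f_const = ngldm_features(__import__("hetex.parent_matrices", fromlist=["ngldm"]).ngldm(const))
        for _ in range(5):
            grid = rng.integers(1, 4, size=(4, 4, 4))
            qr = grid_to_qvoi(grid, L=3)
            f_rand = ngldm_features(__import__("hetex.parent_matrices", fromlist=["ngldm"]).ngldm(qr))
            assert f_rand["large_number_emphasis"] <= f_const["large_number_emphasis"]
            assert f_rand["entropy"] >= 0


class TestTextureSpectrumFeatures:
    def test_constant_voi_max_spectrum_one(self):
        from hetex.parent_matrices import texture_spectrum
        ts = texture_spectrum(grid_to_qvoi(np.ones((5, 5), int), L=2))
        f = texture_spectrum_features(ts)
        assert f["max_spectrum"] == 1.0

    def test_symmetric_spectrum_bws_one_and_bounds(self, rng):
        from hetex.parent_matrices import TextureSpectrum, texture_unit_complement
        comp = texture_unit_complement()
        s = rng.integers(0, 5, size=3 ** 8)
        sym = s + s[comp]
        f = texture_spectrum_features(TextureSpectrum(sym, int(sym.sum())))
        assert f["black_white_symmetry"] == pytest.approx(1.0)
        f2 = texture_spectrum_features(TextureSpectrum(s + 1, int((s + 1).sum())))
        assert 0.0 <= f2["black_white_symmetry"] <= 1.0


class TestTfcFamilies:
    def test_constant_voi_limits(self):
        from hetex.parent_matrices import tfc, tfc_cooccurrence
        t = tfc(grid_to_qvoi(np.ones((5, 5), int), L=2))
        warn = []
        from hetex.features import tfc_features
        f = tfc_features(t, warn)
        assert f["homogeneity"] == 1.0
        assert f["coarseness"] == 1.0
        assert f["mean_convergence"] == 0.0 and warn
        m = tfc_cooccurrence(t)
        fc = tfc_cooccurrence_features(m)
        assert fc["second_angular_moment"] == 1.0
        assert fc["entropy"] == 0.0
        assert fc["code_similarity"] == 1.0

    def test_two_code_matrix_matches_direct_summation(self):
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        values = np.array([0.0, 34.0])
        f = tfc_cooccurrence_features(_cooc(p, values))
        mu = 0.5 * 0 + 0.5 * 34
        assert f["second_angular_moment"] == pytest.approx(0.34)
        assert f["contrast"] == pytest.approx(34 ** 2 * 0.2)
        assert f["intensity"] == pytest.approx(34 * 34 * 0.4)
        assert f["variance"] == pytest.approx(0.5 * mu ** 2 + 0.5 * (34 - mu) ** 2)
        assert f["code_similarity"] == pytest.approx(0.8)
        # correlation of this symmetric 2-code matrix, computed by hand:
        cov = (0.4 * (0 - mu) * (0 - mu) + 0.4 * (34 - mu) * (34 - mu)
               + 0.2 * (0 - mu) * (34 - mu))
        assert f["correlation"] == pytest.approx(cov / f["variance"], rel=1e-12)


class TestVoxelStatistics:
    def _stats(self, values, spacing=(1.0, 1.0, 10.0), units="SUV"):
        values = np.asarray(values, dtype=float)
        vol = ImageVolume(values.reshape(1, 1, -1), spacing, intensity_units=units)
        mask = VoiMask(np.ones(vol.shape, bool))
        return voxel_statistics(vol, mask)

    def test_textbook_moments(self):
        f = self._stats([2, 4, 4, 4, 5, 5, 7, 9])
        assert f["suv_mean"] == pytest.approx(5.0)
        assert f["suv_variance"] == pytest.approx(4.0)
        assert f["suv_sd"] == pytest.approx(2.0)

    def test_symmetric_zero_skewness(self):
        f = self._stats([1, 2, 3])
        assert f["suv_skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["suv_skewness_bias_corrected"] == pytest.approx(0.0, abs=1e-12)

    def test_scipy_agrees_on_bias_corrected_moments(self, rng):
        from scipy import stats as sps
        values = rng.normal(5, 2, size=40)
        f = self._stats(values)
        assert f["suv_skewness"] == pytest.approx(sps.skew(values, bias=True))
        assert f["suv_skewness_bias_corrected"] == pytest.approx(
            sps.skew(values, bias=False))
        assert f["suv_kurtosis"] == pytest.approx(
            sps.kurtosis(values, bias=True, fisher=False))
        assert f["suv_kurtosis_bias_corrected"] == pytest.approx(
            sps.kurtosis(values, bias=False, fisher=False))

    def test_volume_and_tlg(self):
        values = np.full(100, 5.0)
        vol = ImageVolume(values.reshape(1, 10, 10), (1.0, 1.0, 10.0),
                          intensity_units="SUV")  # 10 mm^3 = 0.01 mL / voxel
        f = voxel_statistics(vol, VoiMask(np.ones(vol.shape, bool)))
        assert f["tumor_volume"] == pytest.approx(1.0)
        assert f["tlg"] == pytest.approx(5.0)
        assert f["suv_variance"] == 0.0 and f["suv_sd"] == 0.0

    def test_sul_peak_uniform_volume(self):
        vol = ImageVolume(np.full((10, 10, 10), 3.0), (4.0, 4.0, 4.0),
                          intensity_units="SUV")
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        f = voxel_statistics(vol, VoiMask(mask))
        assert f["sul_peak"] == pytest.approx(3.0)


class TestFullExtraction:
    def test_phantom_yields_72_canonical_features(self, fragmented_phantom):
        vol, mask, _ = fragmented_phantom
        fv = compute_all_features(vol, mask)
        assert list(fv) == canonical_feature_names()
        assert len(fv) == 72
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_constant_sphere_analytic_limits(self, uniform_phantom):
        vol, mask, _ = uniform_phantom
        fv = compute_all_features(vol, mask)
        assert fv["COOC_contrast"] == 0.0
        assert fv["COOC_entropy"] == 0.0
        assert fv["COOC_second_angular_moment"] == 1.0
        assert fv["ISZ_zone_percentage"] == pytest.approx(1.0 / mask.n_voxels)
        assert fv["NID_contrast"] == 0.0

    def test_seed_changes_values_not_schema(self):
        from hetex.phantom import LesionSpec, PhantomSpec, make_phantom
        vals = []
        for seed in (1, 2):
            spec = PhantomSpec(lesions=[LesionSpec((13, 12, 12), 18.0, 5.0,
                                                   zones=10, level_spread=2.0)],
                               noise_sd=0.05, seed=seed)
            vol, mask, _ = make_phantom(spec)
            vals.append(compute_all_features(vol, mask))
        assert list(vals[0]) == list(vals[1])
        assert any(vals[0][k] != vals[1][k] for k in vals[0])

    def test_entropy_orders_fragmented_above_uniform(self, uniform_phantom,
                                                     fragmented_phantom):
        fu = compute_all_features(*uniform_phantom[:2])
        ff = compute_all_features(*fragmented_phantom[:2])
        assert ff["COOC_entropy"] > fu["COOC_entropy"]

    def test_user_registered_feature_appended(self, uniform_phantom):
        register_feature("USER_n_voxels", lambda ctx: float(ctx.mask.n_voxels))
        try:
            vol, mask, _ = uniform_phantom
            fv = compute_all_features(vol, mask)
            assert len(fv) == 73
            assert fv["USER_n_voxels"] == mask.n_voxels
        finally:
            unregister_feature("USER_n_voxels")

    def test_family_error_carries_family_name(self):
        # 2-voxel VOI: too thin for the slice-wise texture spectrum
        vol = ImageVolume(np.array([[[1.0, 2.0]]]), (1, 1, 1))
        mask = VoiMask(np.ones((1, 1, 2), bool))
        with pytest.raises(ValueError, match="TS:"):
            compute_all_features(vol, mask)
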
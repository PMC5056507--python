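"""Texture features against closed forms and naive double-loop oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage, stats

from spnradiomics import (
    ImageSlice,
    ROIMask,
    extract_all,
    feature_names,
    glcm,
    glcm_features,
    histogram_features,
    log_filter,
    quantize,
)
from spnradiomics.features import GLCMMatrix, log_kernel

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------

def glcm_oracle(levels, mask, theta, ng):
    """Count all co-occurring pairs one by one."""
    steps = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = steps[theta]
    P = np.zeros((ng, ng))
    nrow, ncol = levels.shape
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                P[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                P[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return P / P.sum()


def glcm_stats_oracle(P):
    """Double-loop Haralick statistics from the formulas."""
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    contrast = corr = entropy = energy = homog = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            contrast += (i - j) ** 2 * p
            if p > 0:
                entropy -= p * math.log2(p)
            energy += p * p
            homog += p / (1 + (i - j) ** 2)
            if sx * sy > 0:
                corr += (i + 1 - mux) * (j + 1 - muy) * p / (sx * sy)
    return {
        "contrast": contrast, "correlation": corr, "entropy": entropy,
        "energy": energy, "homogeneity": homog,
    }


def histogram_oracle(x, beta):
    """Top-beta subset statistics by explicit sorting."""
    x = sorted(x, reverse=True)
    m = max(1, int(math.floor(beta * len(x) + 0.5)))
    top = x[:m]
    mean = sum(top) / m
    sd = math.sqrt(sum((v - mean) ** 2 for v in top) / m)
    return mean, sd


# ---------------------------------------------------------------------------
# LoG filtering
# ---------------------------------------------------------------------------

class TestLoGFilter:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(log_filter(img, 0.0), img)

    def test_constant_image_filters_to_zero(self):
        out = log_filter(np.full((20, 20), 123.0), 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    @pytest.mark.parametrize("sigma", [1.0, 1.5, 2.0, 2.5])
    def test_impulse_response_equals_sampled_kernel(self, sigma):
        n = 2 * math.ceil(4 * sigma) + 21
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = log_filter(img, sigma)
        k = log_kernel(sigma)
        r = k.shape[0] // 2
        c = n // 2
        np.testing.assert_allclose(
            out[c - r : c + r + 1, c - r : c + r + 1], k, atol=1e-12
        )
        assert abs(k.sum()) < 1e-14  # exact zero-sum correction
        np.testing.assert_allclose(k, k.T)  # radial symmetry
        np.testing.assert_allclose(k, k[::-1, ::-1])

    def test_unsupported_sigma_rejected(self):
        with pytest.raises(ValueError, match="unsupported filter scale"):
            log_filter(np.zeros((4, 4)), 0.7)


# ---------------------------------------------------------------------------
# histogram features
# ---------------------------------------------------------------------------

class TestHistogramFeatures:
    def test_closed_forms_1234(self):
        h = histogram_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert h["mean"] == pytest.approx(2.5)
        assert h["SD"] == pytest.approx(math.sqrt(1.25))
        assert h["50_mean"] == pytest.approx(3.5)  # top M=2 values {3,4}
        assert h["SD_50"] == pytest.approx(0.5)
        assert h["25_mean"] == pytest.approx(4.0)  # M = round(1) = 1
        assert h["10_mean"] == pytest.approx(4.0)  # M floors at 1

    def test_top_beta_matches_sorting_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 40))
            h = histogram_features(x)
            for beta, tag in [(0.5, "50"), (0.25, "25"), (0.1, "10")]:
                mean, sd = histogram_oracle(list(x), beta)
                assert h[f"{tag}_mean"] == pytest.approx(mean, abs=1e-10)
                assert h[f"SD_{tag}"] == pytest.approx(sd, abs=1e-10)

    def test_moments_match_scipy_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 50))
            h = histogram_features(x)
            assert h["skewness"] == pytest.approx(stats.skew(x, bias=True), abs=1e-10)
            assert h["kurtosis"] == pytest.approx(
                stats.kurtosis(x, fisher=False, bias=True), abs=1e-10
            )

    def test_gaussian_limit_kurtosis_three_skewness_zero(self, rng):
        x = rng.standard_normal(100_000)
        h = histogram_features(x)
        assert h["kurtosis"] == pytest.approx(3.0, abs=0.05)
        assert h["skewness"] == pytest.approx(0.0, abs=0.05)

    def test_constant_input_degenerate(self):
        h = histogram_features(np.full(10, 7.0))
        assert h["SD"] == 0.0 and h["kurtosis"] == 0.0 and h["skewness"] == 0.0

    def test_shift_invariance_of_shape_statistics(self, rng):
        x = rng.normal(size=30)
        a, b = histogram_features(x), histogram_features(x + 100.0)
        assert b["mean"] == pytest.approx(a["mean"] + 100.0)
        for key in ("SD", "skewness", "kurtosis"):
            assert b[key] == pytest.approx(a[key], abs=1e-9)


# ---------------------------------------------------------------------------
# quantization and GLCM
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_one_value_per_bin(self):
        np.testing.assert_array_equal(
            quantize(np.arange(64.0), ng=64), np.arange(1, 65)
        )

    def test_constant_maps_to_level_one(self):
        np.testing.assert_array_equal(quantize(np.full(5, 3.0)), np.ones(5))

    def test_pure_function(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(quantize(x, 32), quantize(x, 32))

    def test_max_maps_to_ng(self, rng):
        q = quantize(rng.normal(size=100), ng=16)
        assert q.min() == 1 and q.max() == 16


class TestGLCM:
    def test_single_pair_symmetric(self):
        levels = np.array([[1, 2]])
        m = glcm(levels, np.ones((1, 2), bool), theta=0, ng=2)
        np.testing.assert_allclose(m.P, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_region_single_entry(self):
        levels = np.ones((3, 3), dtype=int)
        for theta in (0, 45, 90, 135):
            m = glcm(levels, np.ones((3, 3), bool), theta=theta, ng=1)
            assert m.P[0, 0] == 1.0

    def test_checkerboard_diagonal_matches_enumeration(self):
        yy, xx = np.mgrid[0:4, 0:4]
        levels = ((yy + xx) % 2) + 1  # checkerboard of levels {1, 2}
        mask = np.ones((4, 4), bool)
        for theta in (0, 45, 90, 135):
            got = glcm(levels, mask, theta=theta, ng=2)
            np.testing.assert_allclose(got.P, glcm_oracle(levels, mask, theta, 2))
        # along diagonals the checkerboard pairs like with like
        diag = glcm(levels, mask, theta=45, ng=2)
        assert diag.P[0, 1] == 0.0 and diag.P[1, 0] == 0.0

    def test_random_inputs_match_enumeration(self, rng):
        for _ in range(25):
            ng = int(rng.integers(2, 6))
            levels = rng.integers(1, ng + 1, size=(6, 6))
            mask = rng.random((6, 6)) < 0.7
            for theta in (0, 45, 90, 135):
                try:
                    got = glcm(levels, mask, theta=theta, ng=ng)
                except ValueError:
                    continue  # no valid pair in this direction
                np.testing.assert_allclose(
                    got.P, glcm_oracle(levels, mask, theta, ng), atol=1e-12
                )

    def test_no_valid_pairs_raises(self):
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(ValueError, match="too small or fragmented"):
            glcm(np.ones((2, 2), int), mask, theta=0, ng=1)


class TestGLCMFeatures:
    def test_single_entry_matrix(self):
        f = glcm_features(GLCMMatrix(P=np.array([[1.0, 0], [0, 0]]), ng=2, theta=0))
        assert f["contrast"] == 0.0 and f["energy"] == 1.0
        assert f["entropy"] == 0.0 and f["homogeneity"] == 1.0
        assert f["correlation"] == 0.0  # degenerate marginals

    def test_uniform_matrix(self):
        k = 4
        P = np.full((2, 2), 1.0 / k)
        f = glcm_features(GLCMMatrix(P=P, ng=2, theta=0))
        assert f["entropy"] == pytest.approx(math.log2(k))
        assert f["energy"] == pytest.approx(1.0 / k)

    def test_random_matrices_match_double_loop(self, rng):
        for _ in range(100):
            ng = int(rng.integers(2, 9))
            A = rng.random((ng, ng))
            P = (A + A.T) / (A + A.T).sum()
            got = glcm_features(GLCMMatrix(P=P, ng=ng, theta=0))
            want = glcm_stats_oracle(P)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-12), key

    def test_statistic_ranges(self, rng):
        for _ in range(50):
            ng = int(rng.integers(2, 9))
            A = rng.random((ng, ng))
            P = (A + A.T) / (A + A.T).sum()
            f = glcm_features(GLCMMatrix(P=P, ng=ng, theta=0))
            assert f["contrast"] >= 0
            assert 0 <= f["energy"] <= 1
            assert 0 <= f["entropy"] <= 2 * math.log2(ng)
            assert 0 < f["homogeneity"] <= 1
            assert abs(f["correlation"]) <= 1 + 1e-12


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_feature_dictionary_is_150_names(self, nodule):
        image, refined = nodule
        fv = extract_all(image, refined)
        assert len(fv) == 150
        assert list(fv) == feature_names()
        assert all(np.isfinite(v) for v in fv.values())

    def test_constant_roi(self):
        img = ImageSlice(np.full((20, 20), 80.0))
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        fv = extract_all(img, ROIMask(mask, refined=True))
        assert fv["his_mean_0"] == pytest.approx(80.0)
        for theta in (0, 45, 90, 135):
            assert fv[f"contrast_{theta}_0"] == 0.0

    def test_translation_invariance(self, small_spec):
        from spnradiomics import generate_nodule

        img, mask = generate_nodule("benign", 1, small_spec, 2)
        pad = 10
        big = np.full((68, 68), img.pixels.min())
        big_mask = np.zeros((68, 68), bool)
        for dr, dc in [(0, 0), (5, 5)]:
            big_i = big.copy()
            big_m = big_mask.copy()
            big_i[pad + dr : pad + dr + 48, pad + dc : pad + dc + 48] = img.pixels
            big_m[pad + dr : pad + dr + 48, pad + dc : pad + dc + 48] = mask.mask
            fv = extract_all(
                ImageSlice(big_i, spacing=img.spacing), ROIMask(big_m, refined=True)
            )
            if dr == 0:
                base = fv
        for name in base:
            assert fv[name] == pytest.approx(base[name], abs=1e-9), name

    def test_unrefined_mask_rejected(self, small_spec):
        from spnradiomics import generate_nodule

        img, mask = generate_nodule("benign", 1, small_spec, 0)
        with pytest.raises(ValueError, match="refined"):
            extract_all(img, mask)
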
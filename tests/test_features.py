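"""The five texture-feature classes and the 165-entry extraction contract."""

import numpy as np
import pytest
from scipy import ndimage, stats

import fibrotex as fx
from fibrotex.features import (
    CLASS_FEATURES,
    FEATURE_NAMES,
    SOURCES,
    VoronoiDecomposition,
    autocorrelation_features,
    average_subject_features,
    cooccurrence_features,
    extract_feature_vector,
    feature_catalog,
    gmm_features,
    histogram_features,
    normalized_acf,
    polygon_moments,
    quantize_gray_levels,
    voronoi_decompose,
    voronoi_features,
)
from fibrotex.standardize import TransformStack, standardize_roi

from ._oracles import (
    acf_by_loops,
    glcm_by_loops,
    glcm_stats_by_loops,
    histogram_stats_by_formula,
    moments_by_loops,
)


class TestHistogram:
    def test_constant_image_conventions(self):
        f = histogram_features(np.full((8, 8), 0.5))
        assert f["mean"] == 0.5
        assert f["sd"] == 0.0
        assert f["entropy"] == 0.0
        assert f["energy"] == 1.0
        assert f["mode_over_iqr"] == pytest.approx(0.5 / 1e-6)

    def test_two_point_distribution(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        f = histogram_features(img)
        assert f["mean"] == 0.5
        assert f["sd"] == 0.5
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["energy"] == pytest.approx(0.5)

    def test_matches_formula_by_formula_oracle(self):
        rng = np.random.default_rng(10)
        img = rng.random((64, 64))
        ours = histogram_features(img)
        theirs = histogram_stats_by_formula(img)
        for name, expected in theirs.items():
            assert ours[name] == pytest.approx(expected, rel=1e-10), name

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.zeros((3, 3)))


class TestGaussianMixture:
    def test_single_population_not_favored(self):
        # samples from one Gaussian: in the clear majority of draws the
        # two-component fit must not beat the one-component AIC
        # (AIC2 >= AIC1 <=> log-likelihood gain <= 3)
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            img = rng.normal(0.5, 0.1, 4096).reshape(64, 64)
            f = gmm_features(img, max_pixels=4096)
            wins += f["loglik_gain"] <= 3.0
        assert wins >= 14

    def test_bimodal_parameter_recovery(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0.2, 0.05, 2048), rng.normal(0.8, 0.05, 2048)])
        f = gmm_features(v.reshape(64, 64), max_pixels=4096)
        assert 0.18 <= f["mean_low"] <= 0.22
        assert 0.78 <= f["mean_high"] <= 0.82
        # AIC2 < AIC1: two components clearly favored
        assert f["loglik_gain"] > 3.0
        assert f["separation"] > 5.0

    def test_matches_sklearn_em_oracle(self):
        # independent EM implementation on the same sample
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0.25, 0.06, 1000), rng.normal(0.75, 0.08, 1000)])
        f = gmm_features(v.reshape(40, 50), max_pixels=2000)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-6, max_iter=500).fit(
            v[:, None]
        )
        means = np.sort(gm.means_.ravel())
        assert f["mean_low"] == pytest.approx(means[0], abs=0.01)
        assert f["mean_high"] == pytest.approx(means[1], abs=0.01)

    def test_constant_image_conventions(self):
        f = gmm_features(np.full((10, 10), 0.3))
        assert f["weight_low"] == 1.0
        assert f["separation"] == 0.0
        assert f["aic_ratio"] == 1.0


class TestAutocorrelation:
    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        img = rng.standard_normal((128, 128))
        for axis in (0, 1):
            acf = normalized_acf(img, axis, 8)
            n_pairs = 128 * 120
            assert np.abs(acf).max() < 3 / np.sqrt(n_pairs) * 2

    def test_cosine_closed_form(self):
        x = np.arange(64, dtype=float)
        img = np.cos(2 * np.pi * x / 16)[None, :].repeat(64, axis=0)
        acf = normalized_acf(img, axis=1, max_lag=16)
        for k in (1, 2, 4, 8, 16):
            assert acf[k - 1] == pytest.approx(np.cos(2 * np.pi * k / 16), abs=0.05)
        assert acf[7] == pytest.approx(-1.0, abs=0.01)
        assert acf[15] == pytest.approx(1.0, abs=0.01)

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.random((20, 24))
        for axis in (0, 1):
            for lag in (1, 3, 7):
                assert normalized_acf(img, axis, 8)[lag - 1] == pytest.approx(
                    acf_by_loops(img, axis, lag), rel=1e-10
                )

    def test_isotropic_noise_near_unit_anisotropy(self):
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            img = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 2.0)
            f = autocorrelation_features(img)
            assert 0.8 <= f["anisotropy"] <= 1.25

    def test_zero_variance_conventions(self):
        f = autocorrelation_features(np.full((32, 32), 1.0))
        assert f["acf_lag1"] == 0.0
        assert f["corr_length_row"] == 0.0
        assert f["anisotropy"] == 1.0


class TestCooccurrence:
    def test_two_row_hand_counted_example(self):
        # [[0,0],[1,1]]: horizontal pairs same-level, vertical all cross-level;
        # equal-width quantization maps the two values to levels 0 and 15
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        f = cooccurrence_features(img)
        assert f["contrast_a0"] == 0.0
        assert f["energy_a0"] == pytest.approx(0.5)
        assert f["contrast_a90"] == pytest.approx(15.0**2)

    def test_checkerboard_diagonal_structure(self):
        img = np.indices((16, 16)).sum(axis=0) % 2 * 1.0
        f = cooccurrence_features(img)
        assert f["contrast_a0"] == pytest.approx(15.0**2)
        assert f["contrast_a45"] == 0.0
        assert f["contrast_a135"] == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.random((8, 8))
        q = quantize_gray_levels(img, 16)
        ours = cooccurrence_features(img)
        for ang in (0, 45, 90, 135):
            P = glcm_by_loops(q, 16, ang)
            expected = glcm_stats_by_loops(P)
            for stat, val in expected.items():
                assert ours[f"{stat}_a{ang}"] == pytest.approx(val, abs=1e-10), (stat, ang)

    def test_constant_image_conventions(self):
        f = cooccurrence_features(np.full((8, 8), 0.2))
        assert f["energy_a0"] == 1.0
        assert f["contrast_a0"] == 0.0
        assert f["homogeneity_a0"] == 1.0
        assert f["correlation_a0"] == 0.0


class TestVoronoi:
    def test_regular_lattice_recovers_cell_geometry(self):
        # dark dips on an 8 px period lattice: interior polygons are ~8x8 cells
        h = w = 64
        img = np.full((h, w), 0.6)
        yy, xx = np.mgrid[0:h, 0:w]
        for cy in range(4, h, 8):
            for cx in range(4, w, 8):
                img -= 0.4 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / 4.0))
        d = voronoi_decompose(img)
        f = voronoi_features(d)
        assert abs(f["mean_area"] - 64.0) / 64.0 < 0.10

    def test_seed_recovery_from_generator_ground_truth(self):
        p = fx.SyntheticParams(severity=4.0, noise_sd=0.02, trend_amplitude=0.0, seed=0)
        roi, true_seeds = fx.generate_reticular_roi(p, return_seeds=True)
        img = standardize_roi(roi).pixels
        d = voronoi_decompose(img)
        assert abs(len(d.seed_points) - len(true_seeds)) / len(true_seeds) <= 0.20
        from scipy.spatial import cKDTree

        detected_mm = d.seed_points * roi.pixel_spacing_mm
        nn = cKDTree(true_seeds).query(detected_mm)[0]
        assert nn.mean() < p.septum_width_mm

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="insufficient nodule structure"):
            voronoi_decompose(np.full((32, 32), 0.5))

    def test_disc_moments_match_continuous_closed_form(self):
        R = 20
        yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
        coords = np.column_stack(np.nonzero(yy**2 + xx**2 <= R**2))
        m1, m2, _ = polygon_moments(coords)
        assert m1 == pytest.approx(2 * R / 3, rel=0.02)
        assert m2 == pytest.approx(R**2 / 2, rel=0.02)

    def test_congruent_polygons_have_zero_spread(self):
        square = np.column_stack(np.nonzero(np.ones((5, 5))))
        polys = [square + np.array([10 * k, 0]) for k in range(4)]
        d = VoronoiDecomposition(
            seed_points=np.zeros((4, 2)), polygons=polys, image_shape=(64, 64)
        )
        f = voronoi_features(d)
        for name in ("sd_moment1", "sd_moment2", "sd_moment3", "sd_area"):
            assert f[name] == 0.0

    def test_moments_match_brute_force_loops(self, reticular_stack):
        d = voronoi_decompose(reticular_stack.original)
        f = voronoi_features(d)
        m = np.array([moments_by_loops(p) for p in d.polygons])
        assert f["mean_moment1"] == pytest.approx(m[:, 0].mean(), abs=1e-12)
        assert f["mean_moment2"] == pytest.approx(m[:, 1].mean(), abs=1e-12)
        assert f["mean_moment3"] == pytest.approx(m[:, 2].mean(), abs=1e-12)
        assert f["sd_moment1"] == pytest.approx(m[:, 0].std(), abs=1e-12)


class TestExtraction:
    def test_cardinality_contract(self, reticular_stack):
        fv = extract_feature_vector(reticular_stack)
        assert len(fv) == 165
        for src in SOURCES:
            assert sum(1 for k in fv if k.startswith(src + ".")) == 55
        assert not any(np.isnan(v) for v in fv.values())
        assert tuple(fv) == FEATURE_NAMES

    def test_published_predictor_names_exist(self, reticular_stack):
        fv = extract_feature_vector(reticular_stack)
        for name in (
            "original.histogram.mean",
            "original.gmm.sd_low",
            "original.gmm.aic_ratio",
            "original.voronoi.sd_moment1",
            "original.voronoi.mean_moment2",
            "gradient.voronoi.mean_moment2",
            "gradient.gmm.sd_low",
            "laplacian.histogram.mode_over_iqr",
            "laplacian.voronoi.mean_moment3",
        ):
            assert name in fv

    def test_degenerate_stack_imputed_not_nan(self, caplog):
        stack = TransformStack(
            original=np.full((32, 32), 0.5),
            gradient=np.zeros((32, 32)),
            laplacian=np.zeros((32, 32)),
        )
        fv = extract_feature_vector(stack)
        assert len(fv) == 165
        assert not any(np.isnan(v) for v in fv.values())
        assert fv["original.voronoi.mean_moment1"] == 0.0  # imputed

    def test_translation_near_invariance(self, reticular_stack):
        img = reticular_stack.original
        shifted = np.roll(img, (7, 13), axis=(0, 1))
        a, b = histogram_features(img), histogram_features(shifted)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k
        ga, gb = gmm_features(img), gmm_features(shifted)
        for k in ("mean_low", "mean_high", "sd_low", "sd_high", "weight_low"):
            assert ga[k] == pytest.approx(gb[k], abs=0.05), k
        ca, cb = cooccurrence_features(img), cooccurrence_features(shifted)
        for k in ca:
            assert ca[k] == pytest.approx(cb[k], rel=0.10, abs=0.02), k
        aa, ab = autocorrelation_features(img), autocorrelation_features(shifted)
        for k in ("acf_lag1", "acf_lag2", "acf_lag4", "acf_lag8"):
            assert aa[k] == pytest.approx(ab[k], abs=0.06), k

    def test_named_predictors_separate_severity_extremes(self):
        # features the prediction models rely on must react to fibrosis
        # severity; absolute-brightness features (e.g. the plain mean) are
        # excluded because per-ROI min-max rescaling deliberately removes
        # that information from the synthetic images
        named = [
            "original.gmm.sd_low",
            "original.gmm.aic_ratio",
            "gradient.gmm.sd_low",
            "gradient.voronoi.mean_moment2",
            "laplacian.histogram.mode_over_iqr",
            "laplacian.voronoi.mean_moment3",
        ]
        groups = {0.0: [], 4.0: []}
        for sev in groups:
            for rep in range(20):
                p = fx.SyntheticParams(severity=sev, seed=500 + rep)
                stack = fx.build_transform_stack(fx.generate_reticular_roi(p))
                groups[sev].append(extract_feature_vector(stack))
        for name in named:
            lo = [g[name] for g in groups[0.0]]
            hi = [g[name] for g in groups[4.0]]
            p_val = stats.mannwhitneyu(lo, hi).pvalue
            assert p_val < 0.01, name


class TestAveraging:
    def test_identical_vectors(self, reticular_stack):
        fv = extract_feature_vector(reticular_stack)
        out = average_subject_features([fv] * 5)
        assert out == pytest.approx(fv)

    def test_two_point_mean(self):
        a = {"f": 0.0, "g": 2.0}
        b = {"f": 1.0, "g": 4.0}
        out = average_subject_features([a, b])
        assert out["f"] == 0.5 and out["g"] == 3.0

    def test_matches_column_mean_oracle(self):
        rng = np.random.default_rng(6)
        names = [f"n{i}" for i in range(10)]
        vecs = [dict(zip(names, rng.random(10))) for _ in range(5)]
        out = average_subject_features(vecs)
        mat = np.array([[v[n] for n in names] for v in vecs])
        for j, n in enumerate(names):
            assert out[n] == pytest.approx(sum(mat[:, j]) / 5, abs=1e-12)

    def test_mismatched_names_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            average_subject_features([{"a": 1.0}, {"b": 1.0}])


def test_feature_catalog_is_complete():
    cat = feature_catalog()
    assert len(cat) == 165
    assert {c["class"] for c in cat} == set(CLASS_FEATURES)
    counts = {cls: sum(1 for c in cat if c["class"] == cls) for cls in CLASS_FEATURES}
    assert counts == {
        "histogram": 42, "gmm": 24, "autocorrelation": 24,
        "cooccurrence": 48, "voronoi": 27,
    }
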
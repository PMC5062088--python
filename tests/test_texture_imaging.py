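"""GLCM construction, Haralick features, texture maps and LDA fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echoqdi.bmode_processing import compute_envelope, log_compress
from echoqdi.data_model import AcquisitionConfig, ConfigError, ValidationError
from echoqdi.phantom_simulator import PhantomSpec, simulate_rf_frame
from echoqdi.texture_imaging import (
    GLCM,
    THETA_OFFSETS,
    EmptyGLCMError,
    compute_glcm,
    fit_lda,
    haralick_features,
    lda_index,
    texture_feature_image,
    window_shape_px,
)


def brute_force_glcm(patch, d, theta, n_g):
    """Exhaustive enumeration of symmetric co-occurrence counts."""
    a, b = (off * d for off in THETA_OFFSETS[theta])
    H, W = patch.shape
    P = np.zeros((n_g, n_g), dtype=int)
    for r in range(H):
        for c in range(W):
            rr, cc = r + a, c + b
            if 0 <= rr < H and 0 <= cc < W:
                P[patch[r, c], patch[rr, cc]] += 1
                P[patch[rr, cc], patch[r, c]] += 1
    return P


def brute_force_features(p):
    """Direct double-loop evaluation of AC, SA, SV (1-based indices)."""
    n_g = p.shape[0]
    ac = sa = 0.0
    for i in range(n_g):
        for j in range(n_g):
            ac += (i + 1) * (j + 1) * p[i, j]
            sa += (i + 1 + j + 1) * p[i, j]
    sv = 0.0
    for i in range(n_g):
        for j in range(n_g):
            sv += (i + 1 + j + 1 - sa) ** 2 * p[i, j]
    return ac, sa, sv


class TestGLCM:
    def test_constant_patch_concentrates_all_mass(self):
        g = compute_glcm(np.full((3, 3), 7), theta=0)
        assert g.p[7, 7] == 1.0
        assert g.p.sum() == 1.0

    def test_two_by_two_horizontal_counts(self):
        g = compute_glcm(np.array([[0, 0], [1, 1]]), theta=0)
        assert g.P[0, 0] == 2 and g.P[1, 1] == 2
        assert g.K == 4
        assert g.p[0, 0] == 0.5 and g.p[1, 1] == 0.5

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_matches_brute_force_enumeration(self, theta):
        rng = np.random.default_rng(7)
        for _ in range(5):
            patch = rng.integers(0, 16, size=(8, 8))
            mine = compute_glcm(patch, theta=theta, n_g=16)
            assert np.array_equal(mine.P, brute_force_glcm(patch, 1, theta, 16))
            assert mine.p.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "theta,sk_angle_deg", [(0, 0), (45, 135), (90, 90), (135, 45)]
    )
    def test_matches_skimage_reference(self, theta, sk_angle_deg):
        # skimage measures angles with the row axis pointing down, so the two
        # diagonal directions are swapped relative to our offset table
        skimage = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(2)
        patch = rng.integers(0, 8, (8, 8))
        mine = compute_glcm(patch, theta=theta, n_g=8)
        ref = skimage.graycomatrix(
            patch.astype(np.uint8), [1], [np.deg2rad(sk_angle_deg)],
            levels=8, symmetric=True,
        )[:, :, 0, 0]
        assert np.array_equal(mine.P, ref)

    def test_too_small_patch_raises(self):
        with pytest.raises(EmptyGLCMError):
            compute_glcm(np.array([[1, 2, 3]]), theta=90)


class TestHaralick:
    def test_degenerate_single_cell_distribution(self):
        # all mass at gray level 4 -> Haralick index i = 5: AC=25, SA=10, SV=0
        tf = haralick_features(compute_glcm(np.full((4, 4), 4), theta=0))
        assert (tf.AC, tf.SA, tf.SV) == (25.0, 10.0, 0.0)

    def test_hand_evaluated_two_cell_distribution(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        g = GLCM(P=(2 * p).astype(int), p=p, K=2, N_g=2, d=1, theta=0)
        tf = haralick_features(g)
        assert tf.AC == pytest.approx(2.5)
        assert tf.SA == pytest.approx(3.0)
        assert tf.SV == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            raw = rng.random((12, 12))
            raw = raw + raw.T
            p = raw / raw.sum()
            g = GLCM(P=p, p=p, K=1, N_g=12, d=1, theta=0)
            tf = haralick_features(g)
            ac, sa, sv = brute_force_features(p)
            assert tf.AC == pytest.approx(ac, abs=1e-12)
            assert tf.SA == pytest.approx(sa, abs=1e-12)
            assert tf.SV == pytest.approx(sv, abs=1e-10)
            assert tf.p_xy.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_glcm_rejected(self):
        g = GLCM(P=np.eye(2), p=np.eye(2), K=2, N_g=2, d=1, theta=0)
        with pytest.raises(ValidationError):
            haralick_features(g)


def _bmode_from_gray(gray, cfg=None):
    from echoqdi.data_model import BModeImage

    cfg = cfg or AcquisitionConfig(n_lines=gray.shape[0])
    return BModeImage(gray=gray, config=cfg)


class TestTextureImage:
    def test_constant_image_has_constant_ac_zero_sv(self):
        cfg = AcquisitionConfig(n_lines=16)
        gray = np.full((16, 120), 50)
        ac, sa, sv = texture_feature_image(_bmode_from_gray(gray, cfg))
        assert np.allclose(ac.values[ac.valid_mask], 51.0**2)
        assert np.allclose(sa.values[sa.valid_mask], 2 * 51.0)
        assert np.allclose(sv.values[sv.valid_mask], 0.0, atol=1e-6)

    def test_interior_pixel_equals_windowed_oracle(self, small_frame):
        bm = log_compress(compute_envelope(small_frame))
        ac, sa, sv = texture_feature_image(bm)
        cfg = small_frame.config
        wy, wx = window_shape_px(3.0, cfg.axial_pitch_mm, cfg.lateral_pitch_mm)
        hy, hx = wy // 2, wx // 2
        for l, s in [(10, 60), (15, 150), (20, 250)]:
            win = bm.gray[l - hy : l + hy + 1, s - hx : s + hx + 1]
            feats = [haralick_features(compute_glcm(win, theta=t)) for t in THETA_OFFSETS]
            assert ac.values[l, s] == pytest.approx(np.mean([f.AC for f in feats]), rel=1e-9)
            assert sa.values[l, s] == pytest.approx(np.mean([f.SA for f in feats]), rel=1e-9)
            assert sv.values[l, s] == pytest.approx(np.mean([f.SV for f in feats]), rel=1e-6)

    def test_gray_shift_moves_ac_sa_not_sv(self):
        rng = np.random.default_rng(3)
        gray = rng.integers(50, 150, size=(16, 120))
        cfg = AcquisitionConfig(n_lines=16)
        base = texture_feature_image(_bmode_from_gray(gray, cfg))
        shifted = texture_feature_image(_bmode_from_gray(gray + 30, cfg))
        mask = base[0].valid_mask
        assert (shifted[0].values[mask] > base[0].values[mask]).all()  # AC up
        assert (shifted[1].values[mask] > base[1].values[mask]).all()  # SA up
        assert np.allclose(shifted[2].values[mask], base[2].values[mask], atol=1e-6)

    def test_brighter_phantom_has_higher_sum_average(self, config):
        # identical speckle pattern, doubled echogenicity, fixed-gain compression
        base = dict(scatterer_density=12.0, depth_extent=3.0, seed=21)
        dim = simulate_rf_frame(PhantomSpec(amplitude_mean=1.0, amplitude_sd=0.2, **base), config)
        bright = simulate_rf_frame(PhantomSpec(amplitude_mean=2.0, amplitude_sd=0.4, **base), config)
        ref = float(compute_envelope(bright).R.max())
        sa_dim = texture_feature_image(log_compress(compute_envelope(dim), reference=ref))[1]
        sa_bright = texture_feature_image(log_compress(compute_envelope(bright), reference=ref))[1]
        assert sa_bright.values[sa_bright.valid_mask].mean() > sa_dim.values[sa_dim.valid_mask].mean()

    def test_window_smaller_than_image_required(self):
        cfg = AcquisitionConfig(n_lines=4)
        with pytest.raises(ConfigError):
            texture_feature_image(_bmode_from_gray(np.zeros((4, 200), dtype=int), cfg))


def brute_force_direction(X2, labels):
    """0.1-degree grid search maximizing between/within variance ratio."""
    best, best_ratio = None, -np.inf
    for deg in np.arange(0.0, 180.0, 0.1):
        w = np.array([np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))])
        proj = X2 @ w
        mu = proj.mean()
        between = within = 0.0
        for c in set(labels):
            pc = proj[np.asarray(labels) == c]
            between += pc.size * (pc.mean() - mu) ** 2
            within += ((pc - pc.mean()) ** 2).sum()
        ratio = between / within
        if ratio > best_ratio:
            best, best_ratio = w, ratio
    return best


class TestLDA:
    def test_single_informative_axis(self):
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(size=(2 * n, 3)) * [1.0, 0.01, 1.0]
        X[n:, 1] += 5.0
        labels = ["normal"] * n + ["severe"] * n
        model = fit_lda(X, labels)
        assert abs(model.w[1]) > 0.99

    def test_matches_grid_search_oracle_on_toy_set(self):
        X2 = np.array(
            [[0.0, 0.1], [0.2, 0.0], [0.1, 0.2],
             [1.0, 1.1], [1.2, 0.9], [0.9, 1.0],
             [2.0, 2.2], [2.1, 1.9], [1.9, 2.1]]
        )
        labels = ["normal"] * 3 + ["mild"] * 3 + ["severe"] * 3
        X = np.column_stack([X2, np.zeros(9)])
        model = fit_lda(X, labels)
        w_ref = brute_force_direction(X2, labels)
        cos = abs(model.w[:2] @ w_ref) / np.linalg.norm(model.w[:2])
        assert cos > 0.999

    def test_class_mean_indices_increase_with_severity(self):
        rng = np.random.default_rng(5)
        X = np.concatenate(
            [rng.normal(loc=mu, scale=0.3, size=(30, 3)) for mu in (1.0, 2.0, 3.0)]
        )
        labels = ["normal"] * 30 + ["mild"] * 30 + ["severe"] * 30
        model = fit_lda(X, labels)
        means = [model.class_means[c] for c in ("normal", "mild", "severe")]
        assert means == sorted(means)
        assert np.linalg.norm(model.w) == pytest.approx(1.0)

    def test_index_order_invariant_to_affine_feature_maps(self):
        rng = np.random.default_rng(8)
        X = np.concatenate(
            [rng.normal(loc=mu, scale=0.4, size=(25, 3)) for mu in (1.0, 1.6, 2.4)]
        )
        labels = np.array(["normal"] * 25 + ["mild"] * 25 + ["severe"] * 25)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = rng.normal(size=3)
        idx_a = lda_index(fit_lda(X, labels), X)
        idx_b = lda_index(fit_lda(X @ A.T + shift, labels), X @ A.T + shift)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(idx_a, idx_b)
        assert abs(rho) > 0.9999

    def test_agrees_with_sklearn_eigen_solver(self):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(13)
        X = np.concatenate(
            [rng.normal(loc=mu, scale=0.5, size=(40, 3)) for mu in (1.0, 1.5, 2.2)]
        )
        labels = np.array([0] * 40 + [1] * 40 + [2] * 40)
        model = fit_lda(X, np.array(["normal", "mild", "severe"])[labels])
        ref = sklearn_lda.LinearDiscriminantAnalysis(solver="eigen").fit(X, labels)
        w_ref = ref.scalings_[:, 0]
        cos = abs(model.w @ w_ref) / np.linalg.norm(w_ref)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_singular_within_class_scatter_warns(self):
        X = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]], dtype=float)
        labels = ["normal", "normal", "severe", "severe"]
        with pytest.warns(UserWarning):
            fit_lda(X, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_lda(np.zeros((4, 3)), ["mild"] * 4)
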
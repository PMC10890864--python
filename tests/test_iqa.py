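"""Metric suite against closed forms and independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octsr import iqa


# ------------------------------------------------------------------- GCF


def gcf_oracle(image: np.ndarray) -> float:
    """Literal multi-resolution contrast factor, written independently
    with explicit loops over superpixel levels and 4-neighbourhoods."""
    k = np.clip((np.asarray(image, float) + 1.0) * 0.5, 0.0, 1.0) * 255.0
    lum = (k / 255.0) ** 2.2
    total = 0.0
    for i in range(1, 10):
        f = 2 ** (i - 1)
        h, w = lum.shape[0] // f, lum.shape[1] // f
        if h < 1 or w < 1:
            continue
        sp = np.zeros((h, w))
        for a in range(h):
            for b in range(w):
                sp[a, b] = lum[a * f:(a + 1) * f, b * f:(b + 1) * f].mean()
        acc = 0.0
        for a in range(h):
            for b in range(w):
                diffs = []
                for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    aa, bb = a + da, b + db
                    if 0 <= aa < h and 0 <= bb < w:
                        diffs.append(abs(sp[a, b] - sp[aa, bb]))
                acc += np.mean(diffs) if diffs else 0.0
        c_i = acc / (h * w)
        x = i / 9.0
        total += ((-0.406385 * x + 0.334573) * x + 0.0877526) * c_i
    return total


def test_gcf_constant_image_is_exactly_zero():
    assert iqa.gcf(np.full((32, 32), 0.3)) == 0.0


def test_gcf_checkerboard_finest_level_contrast_is_one():
    board = np.indices((16, 16)).sum(axis=0) % 2  # luminance 0 or 1
    assert iqa._mean_local_contrast(board.astype(float)) == pytest.approx(1.0)


def test_gcf_matches_independent_reimplementation():
    rng = np.random.default_rng(0)
    for _ in range(5):
        img = rng.uniform(-1, 1, size=(64, 64))
        assert abs(iqa.gcf(img) - gcf_oracle(img)) < 1e-9


def test_gcf_rejects_empty_image():
    with pytest.raises(ValueError):
        iqa.gcf(np.zeros((0, 0)))


# ------------------------------------------------------------------- FNE


def test_fne_annihilates_constant_and_affine_images():
    assert iqa.fne(np.full((16, 16), 0.7)) == 0.0
    yy, xx = np.meshgrid(np.linspace(-1, 1, 32), np.linspace(-1, 1, 32),
                         indexing="ij")
    assert iqa.fne(0.3 * yy + 0.5 * xx) < 1e-12


def test_fne_recovers_gaussian_noise_sigma():
    ests = [iqa.fne(np.random.default_rng(s).normal(0.0, 0.10, (512, 512)))
            for s in range(20)]
    assert 0.097 <= np.mean(ests) <= 0.103


def test_fne_rejects_tiny_images():
    with pytest.raises(ValueError):
        iqa.fne(np.zeros((2, 5)))


# --------------------------------------------------------------- embedding


def test_embedding_is_deterministic_and_row_aligned():
    rng = np.random.default_rng(0)
    imgs = [rng.uniform(-1, 1, size=(48, 40)) for _ in range(4)]
    emb = iqa.RandomConvEmbedder(seed=3)
    a = emb.embed(imgs)
    b = emb.embed(imgs)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (4, emb.dim)
    perm = [2, 0, 3, 1]
    np.testing.assert_allclose(emb.embed([imgs[i] for i in perm]), a[perm])


# ------------------------------------------------------------------- FID


def test_fid_identical_sets_is_zero():
    feats = np.random.default_rng(0).normal(size=(64, 8))
    assert iqa.fid(feats, feats.copy()) < 1e-6


def test_fid_mean_offset_gaussians_approaches_delta_squared():
    rng = np.random.default_rng(1)
    delta = 1.5
    a = rng.normal(size=(5000, 4))
    b = rng.normal(size=(5000, 4))
    b[:, 0] += delta
    assert iqa.fid(a, b) == pytest.approx(delta**2, abs=0.15)


def test_fid_matches_analytic_formula_for_general_gaussians():
    rng = np.random.default_rng(2)
    d = 4
    mu = np.array([0.5, -1.0, 0.25, 0.0])
    chol = np.array([[1.0, 0, 0, 0], [0.3, 0.8, 0, 0],
                     [0, 0.2, 1.2, 0], [0.1, 0, 0, 0.6]])
    sigma = chol @ chol.T
    from scipy.linalg import sqrtm
    want = float(mu @ mu + np.trace(np.eye(d) + sigma
                                    - 2 * np.real(sqrtm(sigma))))
    a = rng.normal(size=(5000, d))
    b = mu + rng.normal(size=(5000, d)) @ chol.T
    assert iqa.fid(a, b) == pytest.approx(want, rel=0.08, abs=0.1)


def test_fid_requires_two_samples():
    with pytest.raises(ValueError):
        iqa.fid(np.zeros((1, 3)), np.zeros((5, 3)))


# ------------------------------------------------------------------- KID


def kid_oracle(x, y):
    """Unbiased MMD^2 with the cubic kernel, explicit double loops."""
    m, d = x.shape
    k = lambda a, b: (float(a @ b) / d + 1.0) ** 3
    sxx = sum(k(x[i], x[j]) for i in range(m) for j in range(m) if i != j)
    syy = sum(k(y[i], y[j]) for i in range(m) for j in range(m) if i != j)
    sxy = sum(k(x[i], y[j]) for i in range(m) for j in range(m))
    return sxx / (m * (m - 1)) + syy / (m * (m - 1)) - 2 * sxy / (m * m)


def test_polynomial_kernel_value():
    a = np.array([[1.0]])
    assert iqa.polynomial_kernel(a, a)[0, 0] == pytest.approx(8.0)


def test_kid_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(7, 5))
    y = rng.normal(size=(7, 5)) + 0.5
    got = iqa.kid(x, y, subset_size=7, n_subsets=1, seed=0)
    assert abs(got - kid_oracle(x, y)) < 1e-9


def test_kid_null_distribution_is_centred_at_zero():
    rng = np.random.default_rng(4)
    sample = rng.normal(size=(400, 6))
    vals = [iqa.kid(sample[:200], sample[200:], subset_size=100,
                    n_subsets=20, seed=s) for s in range(5)]
    spread = np.std(vals) + 1e-6
    assert abs(np.mean(vals)) < 3 * spread + 0.05


def test_kid_rejects_small_subsets():
    with pytest.raises(ValueError):
        iqa.kid(np.zeros((5, 2)), np.zeros((5, 2)), subset_size=1)


# ----------------------------------------------------- manifold metrics


def pr_oracle(real, gen, k):
    from itertools import product
    dist = lambda a, b: float(np.linalg.norm(a - b))
    def radius(pts, i):
        ds = sorted(dist(pts[i], pts[j]) for j in range(len(pts)) if j != i)
        return ds[k - 1]
    rad_r = [radius(real, i) for i in range(len(real))]
    rad_g = [radius(gen, i) for i in range(len(gen))]
    prec = np.mean([any(dist(g, r) <= rad_r[i] for i, r in enumerate(real))
                    for g in gen])
    rec = np.mean([any(dist(r, g) <= rad_g[i] for i, g in enumerate(gen))
                   for r in real])
    return float(prec), float(rec)


def dc_oracle(real, gen, k):
    dist = lambda a, b: float(np.linalg.norm(a - b))
    def radius(pts, i):
        ds = sorted(dist(pts[i], pts[j]) for j in range(len(pts)) if j != i)
        return ds[k - 1]
    rad_r = [radius(real, i) for i in range(len(real))]
    dens = sum(dist(g, r) <= rad_r[i] for g in gen
               for i, r in enumerate(real)) / (k * len(gen))
    cov = np.mean([any(dist(g, r) <= rad_r[i] for g in gen)
                   for i, r in enumerate(real)])
    return float(dens), float(cov)


def test_identical_sets_saturate_pr_and_coverage():
    feats = np.random.default_rng(5).normal(size=(20, 3))
    assert iqa.precision_recall(feats, feats.copy(), k=3) == (1.0, 1.0)
    _, cov = iqa.density_coverage(feats, feats.copy(), k=5)
    assert cov == 1.0


def test_distant_sets_score_zero():
    feats = np.random.default_rng(6).normal(size=(15, 3))
    far = feats + 1000.0
    assert iqa.precision_recall(feats, far, k=3) == (0.0, 0.0)
    assert iqa.density_coverage(feats, far, k=5) == (0.0, 0.0)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_manifold_metrics_match_enumeration_on_toy_2d_sets(seed):
    rng = np.random.default_rng(seed)
    real = rng.normal(size=(9, 2))
    gen = rng.normal(scale=1.3, size=(8, 2)) + rng.uniform(-1, 1, 2)
    got_pr = iqa.precision_recall(real, gen, k=3)
    want_pr = pr_oracle(real, gen, 3)
    assert got_pr == pytest.approx(want_pr, abs=1e-9)
    got_dc = iqa.density_coverage(real, gen, k=4)
    want_dc = dc_oracle(real, gen, 4)
    assert got_dc == pytest.approx(want_dc, abs=1e-9)


def test_manifold_metrics_reject_k_at_least_set_size():
    pts = np.zeros((4, 2))
    with pytest.raises(ValueError):
        iqa.precision_recall(pts, pts, k=4)


# ------------------------------------------------------------- evaluation


def test_self_comparison_report_saturates(tmp_path):
    from octsr import dataio
    from octsr.phantom import PhantomSpec, generate_hr_image

    spec = PhantomSpec()
    for i in range(6):
        img = generate_hr_image(spec, i)
        dataio.save_image(img, tmp_path / "set" / f"im_{i}.png")
    rep = iqa.evaluate_sets(tmp_path / "set", tmp_path / "set",
                            out_json=tmp_path / "rep.json",
                            out_csv=tmp_path / "rep.csv")
    assert rep.fid < 1e-6
    assert abs(rep.kid) < 1e-3
    assert rep.abs_delta_gcf == 0.0
    assert rep.abs_delta_fne == 0.0
    assert rep.precision == rep.recall == rep.coverage == 1.0
    assert (tmp_path / "rep.json").exists() and (tmp_path / "rep.csv").exists()


def test_report_is_permutation_invariant_to_file_order():
    rng = np.random.default_rng(7)
    real = [rng.uniform(-1, 1, size=(32, 32)) for _ in range(5)]
    gen = [rng.uniform(-1, 1, size=(32, 32)) for _ in range(5)]
    emb = iqa.RandomConvEmbedder(seed=0)
    a = iqa.compare_image_sets(real, gen, embedder=emb, seed=0)
    b = iqa.compare_image_sets(real[::-1], gen[::-1], embedder=emb, seed=0)
    assert a.fid == pytest.approx(b.fid, abs=1e-6)
    assert a.abs_delta_gcf == pytest.approx(b.abs_delta_gcf, abs=1e-12)
    assert a.precision == b.precision and a.coverage == b.coverage


def test_input_dir_adds_perceptual_distance_column(tmp_path):
    from octsr import dataio
    rng = np.random.default_rng(9)
    base = [rng.uniform(-0.9, 0.9, (32, 32)) for _ in range(4)]
    for i, img in enumerate(base):
        dataio.save_image(img, tmp_path / "real" / f"{i}.png")
        dataio.save_image(img, tmp_path / "inp" / f"{i}.png")
        noisy = np.clip(img + rng.normal(0, 0.2, img.shape), -1, 1)
        dataio.save_image(noisy, tmp_path / "gen" / f"{i}.png")
    rep = iqa.evaluate_sets(tmp_path / "real", tmp_path / "gen",
                            input_dir=tmp_path / "inp")
    assert rep.perceptual_distance is not None and rep.perceptual_distance > 0
    assert "perceptual_backend" in rep.metadata
    # identical input and generated frames -> zero distance
    rep0 = iqa.evaluate_sets(tmp_path / "real", tmp_path / "inp",
                             input_dir=tmp_path / "inp")
    assert rep0.perceptual_distance == pytest.approx(0.0, abs=1e-10)


def test_reference_mismatch_is_rejected(tmp_path):
    from octsr import dataio
    rng = np.random.default_rng(8)
    for i in range(3):
        dataio.save_image(rng.uniform(-1, 1, (16, 16)), tmp_path / "r" / f"{i}.png")
        dataio.save_image(rng.uniform(-1, 1, (16, 16)), tmp_path / "g" / f"{i}.png")
    dataio.save_image(rng.uniform(-1, 1, (16, 16)), tmp_path / "ref" / "0.png")
    with pytest.raises(ValueError):
        iqa.evaluate_sets(tmp_path / "r", tmp_path / "g", tmp_path / "ref")
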
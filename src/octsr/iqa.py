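"""No-reference image-quality suite plus full-reference extras.

Implements the nine-metric evaluation used for unpaired OCT enhancement:
Frechet distance (FID) and kernel distance (KID) between embedded image
sets, the Matkovic global contrast factor (GCF), the Immerkaer fast noise
estimate (FNE) and their absolute mean differences to a reference pool, the
k-NN-manifold precision/recall and density/coverage pairs, and — for
synthetic data where clean ground truth exists — PSNR/SSIM.

The embedding for the set-based metrics is a fixed random-weight
convolutional network with a recorded seed: images are replicated to three
channels, resized to the backend's input size and mapped to mean+std pooled
activations.  All metric functions operate on plain NumPy arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, ndimage
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.transform import resize

from . import dataio, nn
from .nn.autograd import Tensor

# --------------------------------------------------------------------- GCF

# Published resolution weights: w_i = (-0.406385 i/9 + 0.334573) i/9 + 0.0877526
_GCF_LEVELS = 9


def gcf(image: np.ndarray) -> float:
    """Matkovic global contrast factor of one grayscale frame.

    Pixels (given in [-1, 1]) are mapped to 8-bit and then to perceptual
    luminance l = (k/255)^2.2.  The mean absolute luminance difference to the
    4-neighbours, averaged over pixels, is computed at 9 superpixel
    resolutions (block size 1, 2, 4, ..., 256); levels coarser than the image
    are skipped.  The GCF is the weighted sum of the per-level contrasts.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    k = np.clip((image + 1.0) * 0.5, 0.0, 1.0) * 255.0
    lum = (k / 255.0) ** 2.2
    total = 0.0
    for i in range(1, _GCF_LEVELS + 1):
        f = 2 ** (i - 1)
        h, w = lum.shape[0] // f, lum.shape[1] // f
        if h < 1 or w < 1:
            continue
        super_px = lum[: h * f, : w * f].reshape(h, f, w, f).mean(axis=(1, 3))
        c_i = _mean_local_contrast(super_px)
        x = i / 9.0
        w_i = (-0.406385 * x + 0.334573) * x + 0.0877526
        total += w_i * c_i
    return float(total)


def _mean_local_contrast(lum: np.ndarray) -> float:
    h, w = lum.shape
    diff_sum = np.zeros_like(lum)
    count = np.zeros_like(lum)
    for axis, sl_a, sl_b in (
        (0, (slice(1, None), slice(None)), (slice(None, -1), slice(None))),
        (1, (slice(None), slice(1, None)), (slice(None), slice(None, -1))),
    ):
        d = np.abs(lum[sl_a] - lum[sl_b])
        diff_sum[sl_a] += d
        diff_sum[sl_b] += d
        count[sl_a] += 1
        count[sl_b] += 1
    if not count.any():
        return 0.0
    valid = count > 0
    return float((diff_sum[valid] / count[valid]).mean())


# --------------------------------------------------------------------- FNE

_FNE_MASK = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


def fne(image: np.ndarray) -> float:
    """Immerkaer fast estimate of the additive-noise standard deviation.

    sigma = sqrt(pi/2) / (6 (W-2)(H-2)) * sum |I * M| over interior pixels,
    with M the 3x3 Laplacian-difference mask.  The mask annihilates locally
    affine image content, so smooth structure contributes nothing.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h < 3 or w < 3:
        raise ValueError("image smaller than 3x3")
    conv = ndimage.convolve(image, _FNE_MASK, mode="constant")
    acc = np.abs(conv[1:-1, 1:-1]).sum()
    return float(np.sqrt(np.pi / 2.0) * acc / (6.0 * (w - 2) * (h - 2)))


# ---------------------------------------------------------------- embedding


class RandomConvEmbedder(nn.Module):
    """Fixed random-weight embedding network for the set-based metrics."""

    def __init__(self, seed: int = 0, input_size: int = 64, channels=(16, 32, 64)):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.input_size = input_size
        c_in = 3
        self.convs = []
        for c in channels:
            self.convs.append(nn.Conv2d(c_in, c, 3, stride=2, padding=1, rng=rng))
            c_in = c
        self.dim = 2 * sum(channels)
        for p in self.parameters():
            p.requires_grad = False

    def embed(self, images) -> np.ndarray:
        """(n images of H x W in [-1,1]) -> (n, dim) feature matrix.

        Mean+std pooled activations of every level are concatenated, so the
        embedding reflects both low-level statistics (noise, contrast) and
        coarser layout.
        """
        images = list(images)
        if len(images) == 0:
            raise ValueError("need at least one image")
        batch = np.stack([
            resize(np.asarray(im, np.float64), (self.input_size, self.input_size),
                   anti_aliasing=True, mode="reflect")
            for im in images
        ]).astype(np.float32)
        x = np.repeat(batch[:, None], 3, axis=1)       # grayscale -> 3 channels
        pooled = []
        with nn.no_grad():
            h = Tensor(x)
            for conv in self.convs:
                h = conv(h).relu()
                a = h.data
                pooled.extend([a.mean(axis=(2, 3)), a.std(axis=(2, 3))])
        return np.concatenate(pooled, axis=1).astype(np.float64)


def embed_images(images, backend: "RandomConvEmbedder | None" = None,
                 seed: int = 0) -> np.ndarray:
    backend = backend or RandomConvEmbedder(seed=seed)
    return backend.embed(images)


# --------------------------------------------------------------- FID / KID


def fid(real_feats: np.ndarray, gen_feats: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussians fitted to the two feature sets."""
    real_feats = np.asarray(real_feats, np.float64)
    gen_feats = np.asarray(gen_feats, np.float64)
    if real_feats.shape[0] < 2 or gen_feats.shape[0] < 2:
        raise ValueError("need at least 2 samples per set")
    mu_r, mu_g = real_feats.mean(axis=0), gen_feats.mean(axis=0)
    sig_r = np.cov(real_feats, rowvar=False)
    sig_g = np.cov(gen_feats, rowvar=False)
    diff = mu_r - mu_g
    covmean = _sqrtm(sig_r @ sig_g)
    if not np.isfinite(covmean).all():
        offset = eps * np.eye(sig_r.shape[0])
        covmean = _sqrtm((sig_r + offset) @ (sig_g + offset))
    covmean = np.real(covmean)
    value = diff @ diff + np.trace(sig_r) + np.trace(sig_g) - 2.0 * np.trace(covmean)
    return float(max(value, 0.0))


def _sqrtm(mat: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = linalg.sqrtm(mat)
    if isinstance(out, tuple):  # older scipy returns (sqrtm, errest)
        out = out[0]
    return np.asarray(out)


def polynomial_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """k(x, y) = (x.y / d + 1)^3 — the standard KID kernel."""
    d = a.shape[1]
    return (a @ b.T / d + 1.0) ** 3


def kid(real_feats: np.ndarray, gen_feats: np.ndarray, subset_size: int | None = None,
        n_subsets: int = 100, seed: int = 0) -> float:
    """Unbiased MMD^2 with the cubic polynomial kernel, subset-averaged."""
    real_feats = np.asarray(real_feats, np.float64)
    gen_feats = np.asarray(gen_feats, np.float64)
    n = min(real_feats.shape[0], gen_feats.shape[0])
    m = subset_size or min(n, 100)
    if m < 2:
        raise ValueError("subset_size must be >= 2")
    if m > n:
        raise ValueError("subset_size exceeds the smaller set")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_subsets):
        xr = real_feats[rng.choice(real_feats.shape[0], m, replace=False)]
        xg = gen_feats[rng.choice(gen_feats.shape[0], m, replace=False)]
        vals.append(_mmd2_unbiased(xr, xg))
    return float(np.mean(vals))


def _mmd2_unbiased(x: np.ndarray, y: np.ndarray) -> float:
    m = x.shape[0]
    kxx = polynomial_kernel(x, x)
    kyy = polynomial_kernel(y, y)
    kxy = polynomial_kernel(x, y)
    sum_off = lambda k: (k.sum() - np.trace(k)) / (m * (m - 1))
    return sum_off(kxx) + sum_off(kyy) - 2.0 * kxy.mean()


# ------------------------------------------------- manifold (P&R and D&C)


def _knn_radii(feats: np.ndarray, k: int) -> np.ndarray:
    from scipy.spatial.distance import cdist

    d = cdist(feats, feats)
    np.fill_diagonal(d, np.inf)
    return np.sort(d, axis=1)[:, k - 1]


def precision_recall(real_feats: np.ndarray, gen_feats: np.ndarray,
                     k: int = 3) -> tuple[float, float]:
    """k-NN-manifold precision (fidelity) and recall (diversity)."""
    from scipy.spatial.distance import cdist

    real_feats, gen_feats = np.asarray(real_feats), np.asarray(gen_feats)
    for s in (real_feats, gen_feats):
        if s.shape[0] <= k:
            raise ValueError("each set needs more than k points")
    rad_r = _knn_radii(real_feats, k)
    rad_g = _knn_radii(gen_feats, k)
    d_gr = cdist(gen_feats, real_feats)
    precision = float((d_gr <= rad_r[None, :]).any(axis=1).mean())
    recall = float((d_gr.T <= rad_g[None, :]).any(axis=1).mean())
    return precision, recall


def density_coverage(real_feats: np.ndarray, gen_feats: np.ndarray,
                     k: int = 5) -> tuple[float, float]:
    """Density (mean real-ball membership count / k) and coverage."""
    from scipy.spatial.distance import cdist

    real_feats, gen_feats = np.asarray(real_feats), np.asarray(gen_feats)
    for s in (real_feats, gen_feats):
        if s.shape[0] <= k:
            raise ValueError("each set needs more than k points")
    rad_r = _knn_radii(real_feats, k)
    d_gr = cdist(gen_feats, real_feats)          # (|G|, |R|)
    inside = d_gr <= rad_r[None, :]
    density = float(inside.sum() / (k * gen_feats.shape[0]))
    coverage = float(inside.any(axis=0).mean())
    return density, coverage


# ------------------------------------------------------------------ report


@dataclass
class MetricReport:
    fid: float
    kid: float
    abs_delta_gcf: float
    abs_delta_fne: float
    precision: float
    recall: float
    density: float
    coverage: float
    mean_gcf_gen: float
    mean_gcf_real: float
    mean_fne_gen: float
    mean_fne_real: float
    psnr: float | None = None
    ssim: float | None = None
    # This package's own fixed-random-backbone perceptual distance between
    # paired input/generated frames; NOT comparable to published
    # perceptual-loss columns computed with pretrained backbones.
    perceptual_distance: float | None = None
    metadata: dict = field(default_factory=dict)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, json_path, csv_path=None):
        dataio.write_json(self.asdict(), json_path)
        if csv_path is not None:
            rows = ["metric,value"]
            for key, val in self.asdict().items():
                if key != "metadata" and val is not None:
                    rows.append(f"{key},{val}")
            Path(csv_path).write_text("\n".join(rows) + "\n")


def compare_image_sets(real_images, gen_images, embedder: RandomConvEmbedder | None = None,
                       k_pr: int = 3, k_dc: int = 5, kid_subsets: int = 50,
                       seed: int = 0) -> MetricReport:
    """Full no-reference report between two in-memory image sets."""
    embedder = embedder or RandomConvEmbedder(seed=seed)
    real_images, gen_images = list(real_images), list(gen_images)
    real_f = embedder.embed(real_images)
    gen_f = embedder.embed(gen_images)
    m = min(len(real_images), len(gen_images))
    subset = max(2, min(m, 50))
    gcf_r = [gcf(im) for im in real_images]
    gcf_g = [gcf(im) for im in gen_images]
    fne_r = [fne(im) for im in real_images]
    fne_g = [fne(im) for im in gen_images]
    p, r = precision_recall(real_f, gen_f, k=min(k_pr, m - 1))
    d, c = density_coverage(real_f, gen_f, k=min(k_dc, m - 1))
    return MetricReport(
        fid=fid(real_f, gen_f),
        kid=kid(real_f, gen_f, subset_size=subset, n_subsets=kid_subsets, seed=seed),
        abs_delta_gcf=abs(float(np.mean(gcf_g)) - float(np.mean(gcf_r))),
        abs_delta_fne=abs(float(np.mean(fne_g)) - float(np.mean(fne_r))),
        precision=p, recall=r, density=d, coverage=c,
        mean_gcf_gen=float(np.mean(gcf_g)), mean_gcf_real=float(np.mean(gcf_r)),
        mean_fne_gen=float(np.mean(fne_g)), mean_fne_real=float(np.mean(fne_r)),
        metadata={"embedding": "random_conv", "embed_seed": embedder.seed,
                  "embed_dim": embedder.dim, "k_pr": k_pr, "k_dc": k_dc,
                  "n_real": len(real_images), "n_gen": len(gen_images),
                  "kid_subset_size": subset, "kid_n_subsets": kid_subsets,
                  "seed": seed},
    )


def evaluate_sets(real_dir, gen_dir, input_dir=None, reference_dir=None,
                  out_json=None, out_csv=None, seed: int = 0,
                  embedder: RandomConvEmbedder | None = None) -> MetricReport:
    """Directory-level evaluation.

    ``input_dir`` (the degraded frames the generated set was produced from)
    adds the package's own perceptual distance between paired input/generated
    frames; ``reference_dir`` (synthetic clean ground truth) adds PSNR/SSIM.
    """
    real_paths = dataio.list_images(real_dir)
    gen_paths = dataio.list_images(gen_dir)
    if not real_paths or not gen_paths:
        raise FileNotFoundError("empty real or generated directory")
    real_images = [dataio.load_image(p) for p in real_paths]
    gen_images = [dataio.load_image(p) for p in gen_paths]
    report = compare_image_sets(real_images, gen_images, embedder=embedder, seed=seed)
    if input_dir is not None:
        from .contrastive import PerceptualNet, perceptual_loss

        in_paths = dataio.list_images(input_dir)
        if len(in_paths) != len(gen_paths):
            raise ValueError(
                f"input has {len(in_paths)} frames but generated has {len(gen_paths)}")
        net = PerceptualNet(seed=0)
        dists = [perceptual_loss(dataio.load_image(ip)[None, None],
                                 g[None, None], net).item()
                 for ip, g in zip(in_paths, gen_images)]
        report.perceptual_distance = float(np.mean(dists))
        report.metadata["perceptual_backend"] = "random_conv(seed=0); values " \
            "not comparable to pretrained-backbone perceptual metrics"
    if reference_dir is not None:
        ref_paths = dataio.list_images(reference_dir)
        if len(ref_paths) != len(gen_paths):
            raise ValueError(
                f"reference has {len(ref_paths)} frames but generated has {len(gen_paths)}")
        psnrs, ssims = [], []
        for gp, rp in zip(gen_paths, ref_paths):
            g = dataio.load_image(gp)
            r = dataio.load_image(rp)
            psnrs.append(peak_signal_noise_ratio(r, g, data_range=2.0))
            ssims.append(structural_similarity(r, g, data_range=2.0))
        report.psnr = float(np.mean(psnrs))
        report.ssim = float(np.mean(ssims))
    if out_json is not None:
        report.write(out_json, out_csv)
    return report


def psnr_ssim(gen_seq: np.ndarray, ref_seq: np.ndarray) -> tuple[float, float]:
    """Mean PSNR/SSIM between aligned (T, H, W) stacks on the [-1, 1] scale."""
    ps = [peak_signal_noise_ratio(r, g, data_range=2.0) for g, r in zip(gen_seq, ref_seq)]
    ss = [structural_similarity(r, g, data_range=2.0) for g, r in zip(gen_seq, ref_seq)]
    return float(np.mean(ps)), float(np.mean(ss))
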
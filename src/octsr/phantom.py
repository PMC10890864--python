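"""Synthetic retina-phantom data emulating the two OCT domains.

The high-quality (HR) domain mimics averaged pre-operative B-scans: a smooth
stack of bright/dark retinal bands with gentle curvature, strong contrast and
almost no noise.  The low-quality (LR) domain mimics real-time intra-operative
video: short clips of the same kind of anatomy degraded by multiplicative
speckle (unit-mean gamma with "looks" parameter L), reduced contrast, optical
blur and small inter-frame motion.  The two pools are built from disjoint
geometry seeds, so no LR clip has a pixel-aligned HR counterpart — the
unpaired setting the enhancement network is trained in.

Every output is a pure function of (spec, seed).  Clean, undegraded
references for each LR clip are emitted under a separate ``reference/``
subtree; they exist only so synthetic experiments can report full-reference
scores (PSNR/SSIM) and must never be used for training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import dataio

_DEFAULT_BAND_PATTERN = (0.78, 0.38, 0.62, 0.30, 0.85, 0.22, 0.55, 0.40)


@dataclass
class PhantomSpec:
    """Geometry and degradation parameters of the phantom generator."""

    height_px: int = 64
    width_px: int = 64
    n_layers: int = 6
    layer_curvature: float = 5.0        # peak boundary deflection, px
    layer_intensities: tuple = ()       # in [0, 1]; cycled over bands
    speckle_looks: float = 2.0          # gamma shape L; var of multiplier = 1/L
    contrast_scale: float = 0.45        # LR contrast compression in (0, 1]
    brightness_scale: float = 0.7       # LR signal strength in (0, 1]
    motion_amplitude_px: float = 1.2    # max inter-frame translation step
    frames_per_sequence: int = 5
    blur_sigma_px: float = 1.0
    speckle_grain_px: float = 0.6       # speckle correlation length (0 = white)
    sensor_noise_sigma: float = 0.003   # additive HR noise on [0, 1] scale
    seed: int = 0

    def __post_init__(self):
        if not self.layer_intensities:
            reps = -(-self.n_layers // len(_DEFAULT_BAND_PATTERN))
            self.layer_intensities = tuple(
                (_DEFAULT_BAND_PATTERN * reps)[: self.n_layers])
        self.validate()

    def validate(self):
        if self.height_px <= 16 or self.width_px <= 16:
            raise ValueError("phantom dimensions must exceed 16 px")
        if self.frames_per_sequence < 2:
            raise ValueError("need at least 2 frames per sequence")
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks L must be > 0")
        if not 0 < self.contrast_scale <= 1:
            raise ValueError("contrast_scale must lie in (0, 1]")
        if not 0 < self.brightness_scale <= 1:
            raise ValueError("brightness_scale must lie in (0, 1]")
        if any(not 0 <= v <= 1 for v in self.layer_intensities):
            raise ValueError("layer intensities must lie in [0, 1]")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def generate_hr_image(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Render one clean, high-contrast phantom B-scan in [-1, 1].

    The retina occupies the central vertical region: a dark background
    (vitreous) above, ``n_layers`` bands following a shared smooth curve,
    and a dark region (choroid/sclera shadow) below.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    x = np.arange(w) / max(w - 1, 1)

    # Shared boundary curve: one sine period with random phase plus a tilt.
    amp = spec.layer_curvature * rng.uniform(0.4, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    tilt = rng.uniform(-0.3, 0.3) * spec.layer_curvature
    curve = amp * np.sin(2 * np.pi * x * rng.uniform(0.6, 1.2) + phase) + tilt * (x - 0.5)

    top = h * rng.uniform(0.12, 0.28)
    bottom = h * rng.uniform(0.72, 0.88)
    # Band thicknesses: random partition of the retina depth.
    parts = rng.uniform(0.6, 1.4, size=spec.n_layers)
    parts /= parts.sum()
    edges = top + np.concatenate([[0.0], np.cumsum(parts)]) * (bottom - top)
    boundaries = edges[:, None] + curve[None, :]          # (n_layers+1, W)

    yy = np.arange(h)[:, None]
    img = np.full((h, w), 0.06, dtype=np.float64)          # dark background
    intensities = np.asarray(spec.layer_intensities)
    jitter = rng.uniform(-0.04, 0.04, size=spec.n_layers)
    for b in range(spec.n_layers):
        mask = (yy >= boundaries[b][None, :]) & (yy < boundaries[b + 1][None, :])
        img[mask] = np.clip(intensities[b] + jitter[b], 0.0, 1.0)

    # Mild smooth texture inside the tissue, then a whisper of blur so the
    # band edges are crisp but not aliased.
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 3.0)
    texture *= 0.012 / max(texture.std(), 1e-12)
    img = np.clip(img + texture, 0.0, 1.0)
    img = ndimage.gaussian_filter(img, 0.8)
    if spec.sensor_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.sensor_noise_sigma, size=(h, w))
    return (np.clip(img, 0.0, 1.0) * 2.0 - 1.0).astype(np.float32)


def generate_lr_sequence(hr_clean: np.ndarray, spec: PhantomSpec, seed: int):
    """Degrade a clean phantom into a T-frame LR clip.

    Returns ``(lr_sequence, clean_reference_sequence)``, both (T, H, W) in
    [-1, 1].  Per frame: sub-pixel rigid translation along a smooth random
    walk, contrast compression toward the mean, Gaussian blur, and i.i.d.
    unit-mean gamma speckle of shape L.  The reference shares the geometry
    (same translations) but none of the degradations.
    """
    hr_clean = np.asarray(hr_clean)
    if hr_clean.shape != (spec.height_px, spec.width_px):
        raise ValueError(
            f"hr_clean shape {hr_clean.shape} does not match spec "
            f"{(spec.height_px, spec.width_px)}")
    rng = np.random.default_rng(seed)
    t_frames = spec.frames_per_sequence
    base = (hr_clean.astype(np.float64) + 1.0) * 0.5      # [0, 1] intensity

    steps = rng.uniform(-spec.motion_amplitude_px, spec.motion_amplitude_px,
                        size=(t_frames, 2))
    steps[0] = 0.0
    offsets = np.cumsum(steps, axis=0)

    lr, ref = [], []
    for t in range(t_frames):
        shifted = ndimage.shift(base, offsets[t], order=1, mode="nearest")
        ref.append(shifted)
        frame = shifted
        if spec.contrast_scale < 1.0:
            mean = frame.mean()
            frame = mean + spec.contrast_scale * (frame - mean)
        frame = frame * spec.brightness_scale  # weak real-time signal
        if spec.blur_sigma_px > 0:
            frame = ndimage.gaussian_filter(frame, spec.blur_sigma_px)
        if np.isfinite(spec.speckle_looks):
            frame = frame * _speckle_field(rng, frame.shape, spec.speckle_looks,
                                           spec.speckle_grain_px)
        lr.append(np.clip(frame, 0.0, 1.0))
    to_signed = lambda a: (np.stack(a) * 2.0 - 1.0).astype(np.float32)
    return to_signed(lr), to_signed(ref)


def _speckle_field(rng: np.random.Generator, shape, looks: float,
                   grain_px: float) -> np.ndarray:
    """Unit-mean gamma(L) speckle, spatially correlated over ``grain_px``.

    For a positive grain the field is built through a Gaussian copula: a
    white Gaussian field is smoothed to the grain scale and mapped through
    the gamma quantile function, so the marginal law (mean 1, variance 1/L)
    is exact while neighbouring pixels share the same speckle cell.
    """
    if grain_px <= 0:
        return rng.gamma(looks, 1.0 / looks, size=shape)
    from scipy import special, stats

    z = ndimage.gaussian_filter(rng.normal(size=shape), grain_px)
    z /= max(z.std(), 1e-12)
    u = special.ndtr(z)
    return stats.gamma.ppf(u, a=looks, scale=1.0 / looks)


def build_dataset(spec: PhantomSpec, n_lr_sequences: int, n_hr_images: int,
                  out_dir, seed: int, val_fraction: float = 0.25) -> dict:
    """Write an unpaired LR/HR phantom dataset and return its manifest.

    Layout: ``lr/<seq_id>/frame_<t>.png``, ``hr/<img_id>.png``,
    ``reference/<seq_id>/frame_<t>.png`` plus ``manifest.json``.  LR and HR
    items draw geometry from disjoint seed pools, so the two domains share
    statistics but no individual scene.
    """
    if n_lr_sequences < 1 or n_hr_images < 1:
        raise ValueError("need at least one item per domain")
    out_dir = Path(out_dir)
    state = np.random.SeedSequence(seed).generate_state(2 * n_lr_sequences + n_hr_images)
    lr_geom = [int(s) for s in state[:n_lr_sequences]]
    lr_degr = [int(s) for s in state[n_lr_sequences:2 * n_lr_sequences]]
    hr_geom = [int(s) for s in state[2 * n_lr_sequences:]]
    taken = set(lr_geom)
    hr_geom = [_avoid(g, taken) for g in hr_geom]

    items = []
    n_lr_val = max(1, int(round(n_lr_sequences * val_fraction))) if n_lr_sequences > 1 else 0
    n_hr_val = max(1, int(round(n_hr_images * val_fraction))) if n_hr_images > 1 else 0
    for i, (gs, ds) in enumerate(zip(lr_geom, lr_degr)):
        clean = generate_hr_image(spec, gs)
        lr_seq, ref_seq = generate_lr_sequence(clean, spec, ds)
        sid = f"seq_{i:04d}"
        dataio.save_sequence(lr_seq, out_dir / "lr" / sid)
        dataio.save_sequence(ref_seq, out_dir / "reference" / sid)
        split = "val" if i >= n_lr_sequences - n_lr_val else "train"
        items.append({"id": sid, "role": "lr_sequence", "path": f"lr/{sid}",
                      "reference_path": f"reference/{sid}",
                      "n_frames": spec.frames_per_sequence,
                      "seed": gs, "degradation_seed": ds, "split": split})
    for j, gs in enumerate(hr_geom):
        img = generate_hr_image(spec, gs)
        iid = f"hr_{j:04d}"
        dataio.save_image(img, out_dir / "hr" / f"{iid}.png")
        split = "val" if j >= n_hr_images - n_hr_val else "train"
        items.append({"id": iid, "role": "hr_image", "path": f"hr/{iid}.png",
                      "n_frames": 1, "seed": gs, "split": split})

    manifest = {"spec": spec.asdict(), "seed": seed, "items": items}
    dataio.write_json(manifest, out_dir / "manifest.json")
    return manifest


def _avoid(value: int, taken: set) -> int:
    while value in taken:
        value = (value + 1) % (2**32)
    taken.add(value)
    return value
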
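"""Adversarial training loop for the enhancement network.

One optimisation step alternates a discriminator update (real high-quality
frames vs detached generated frames) with a generator update minimising the
weighted sum of the adversarial, patchwise-contrastive and perceptual
objectives.  Optimisation uses Adam with a linearly decaying learning rate
after a configurable knee epoch.  All randomness (weight init, data order,
patch sampling, temporal crops) flows from a single seed, and checkpoints
carry the full optimiser + RNG state so a resumed run reproduces the
non-resumed loss trajectory exactly.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import adversarial, contrastive, dataio, flow as flowmod, iqa
from .generator import GeneratorConfig, RecurrentGenerator
from .nn import Adam
from .nn.autograd import Tensor


@dataclass
class TrainConfig:
    lr: float = 1e-4
    decay_start_epoch: int = 50          # linear decay to zero afterwards
    adam_betas: tuple = (0.5, 0.999)
    batch_size: int = 8
    epochs: int = 200
    seq_len: int = 5                     # temporal crop length during training
    seed: int = 0
    weights: contrastive.LossWeights = field(default_factory=contrastive.LossWeights)
    n_patches: int = 256
    nce_hidden: int = 256
    use_projection_head: bool = True
    saturating_gan: bool = False
    zero_warp: bool = False              # train-time ablation switch
    ema_decay: float = 0.999             # generator weight averaging for eval
    disc_base_channels: int = 64
    eval_every: int = 0                  # epochs; 0 => only at the end
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if isinstance(self.weights, dict):
            self.weights = contrastive.LossWeights(**self.weights)
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        if isinstance(self.adam_betas, list):
            self.adam_betas = tuple(self.adam_betas)

    @classmethod
    def toy(cls, seed: int = 0, **over) -> "TrainConfig":
        """Desk-scale configuration used by the synthetic experiments."""
        defaults = dict(
            lr=5e-4, decay_start_epoch=6, batch_size=1, epochs=12, seq_len=3,
            seed=seed, n_patches=64, nce_hidden=64, disc_base_channels=16,
            ema_decay=0.95,
            weights=contrastive.LossWeights(1.0, 1.0, 1.0),
            generator=GeneratorConfig(n_res_blocks=4, feat_channels=24),
        )
        defaults.update(over)
        return cls(**defaults)

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _concat_frames(outputs) -> Tensor:
    from .nn.autograd import concat

    flat = [o for outs in outputs for o in outs]
    return concat(flat, axis=0) if len(flat) > 1 else flat[0]


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Constant until the knee, then linear to zero at the final epoch."""
    knee = config.decay_start_epoch
    if epoch <= knee or config.epochs <= knee:
        return config.lr
    return config.lr * (1.0 - (epoch - knee) / (config.epochs - knee))


class Trainer:
    """Owns the networks, optimisers and RNG for one training run."""

    def __init__(self, config: TrainConfig):
        self.config = config
        gcfg = copy.deepcopy(config.generator)
        if config.zero_warp:
            gcfg.zero_warp = True
        self.generator = RecurrentGenerator(gcfg, seed=config.seed)
        self.discriminator = adversarial.PatchDiscriminator(
            config.disc_base_channels, seed=config.seed + 1)
        self.perceptual = contrastive.PerceptualNet(seed=config.seed + 2)
        feat_dims = {"l0": 1}
        for lid in ("l1", "l2", "l3", "l4"):
            feat_dims[lid] = gcfg.feat_channels
        self.heads = (contrastive.ProjectionHeads(feat_dims, config.nce_hidden,
                                                  seed=config.seed + 3)
                      if config.use_projection_head else None)
        g_params = self.generator.parameters()
        if self.heads is not None:
            g_params = g_params + self.heads.parameters()
        self.opt_g = Adam(g_params, lr=config.lr, betas=config.adam_betas)
        self.opt_d = Adam(self.discriminator.parameters(), lr=config.lr,
                          betas=config.adam_betas)
        self.rng = np.random.default_rng(config.seed)
        self.step = 0
        self.epoch = 0
        self.log: list[dict] = []
        # Exponential moving average of generator weights, used for
        # evaluation and export (smooths adversarial oscillation).
        self.ema = {k: v.copy() for k, v in self.generator.state_dict().items()}

    # ------------------------------------------------------------ one step
    def train_step(self, lr_batch, hr_batch, flows_batch=None) -> dict:
        """One D update then one G update on unpaired batches.

        ``lr_batch``: list of (T, H, W) clips; ``hr_batch``: list of (H, W)
        frames; ``flows_batch``: optional precomputed per-clip flow pairs.
        """
        cfg = self.config
        w = cfg.weights
        outputs, inputs = [], []
        for i, seq in enumerate(lr_batch):
            flows = None if flows_batch is None else flows_batch[i]
            outs = self.generator.forward(seq, flows=flows)
            outputs.append(outs)
            inputs.append(np.asarray(seq, np.float32))

        fake_frames = np.concatenate(
            [o.data for outs in outputs for o in outs], axis=0)
        real_frames = np.stack([np.asarray(h, np.float32) for h in hr_batch])[:, None]

        # --- discriminator step (generated frames detached)
        self.opt_d.zero_grad()
        real_logits = self.discriminator(Tensor(real_frames))
        fake_logits = self.discriminator(Tensor(fake_frames))
        d_loss = adversarial.gan_loss_discriminator(real_logits, fake_logits)
        d_loss.backward()
        self.opt_d.step()

        # --- generator step
        self.opt_g.zero_grad()
        self.discriminator.zero_grad()
        fake_stack = _concat_frames(outputs)
        g_fake_logits = self.discriminator(fake_stack)
        gan_g = adversarial.gan_loss_generator(g_fake_logits, cfg.saturating_gan)

        # Contrastive + perceptual terms on one random frame per clip.
        contr_terms, perc_terms = [], []
        for seq, outs in zip(inputs, outputs):
            t_c = int(self.rng.integers(len(outs)))
            x_t = Tensor(seq[t_c : t_c + 1][:, None])
            y_t = outs[t_c]
            if w.lambda_contrastive > 0:
                feats_x = self.generator.extract_layer_features(x_t)
                feats_y = self.generator.extract_layer_features(y_t)
                bank = contrastive.sample_patch_triplets(
                    feats_x, feats_y, cfg.n_patches, self.rng, self.heads)
                contr_terms.append(contrastive.patch_nce_loss(bank))
            if w.lambda_perceptual > 0:
                perc_terms.append(contrastive.perceptual_loss(x_t, y_t, self.perceptual))
        n_clips = float(len(lr_batch))
        zero = Tensor(np.zeros((), np.float32))
        contr = sum(contr_terms, zero) * (1.0 / n_clips) if contr_terms else zero
        perc = sum(perc_terms, zero) * (1.0 / n_clips) if perc_terms else zero
        total = contrastive.total_generator_loss(gan_g, contr, perc, w)
        if w.lambda_gan > 0 or contr_terms or perc_terms:
            total.backward()
            self.opt_g.step()
        d = self.config.ema_decay
        for k, v in self.generator.state_dict().items():
            self.ema[k] = d * self.ema[k] + (1.0 - d) * v

        record = {
            "step": self.step, "epoch": self.epoch,
            "d_loss": float(d_loss.data), "gan_g": float(gan_g.data),
            "contrastive": float(contr.data), "perceptual": float(perc.data),
            "total": float(total.data), "lr": self.opt_g.lr,
        }
        if not all(np.isfinite(v) for v in record.values()):
            raise RuntimeError(f"non-finite loss at step {self.step}: {record}")
        self.step += 1
        self.log.append(record)
        return record

    # ------------------------------------------------------------ training
    def fit(self, dataset: "PhantomDataset", out_dir=None,
            progress: bool = False) -> dict:
        cfg = self.config
        n_seq = len(dataset.train_lr)
        if n_seq == 0 or len(dataset.train_hr) == 0:
            raise ValueError("empty training split")
        steps_per_epoch = max(1, n_seq // max(1, cfg.batch_size))
        best = {"fid": np.inf, "epoch": -1}
        out_dir = Path(out_dir) if out_dir is not None else None
        t0 = time.time()
        start_epoch = self.epoch
        for epoch in range(start_epoch, cfg.epochs):
            self.epoch = epoch
            lr_now = lr_at_epoch(cfg, epoch)
            self.opt_g.lr = lr_now
            self.opt_d.lr = lr_now
            for _ in range(steps_per_epoch):
                idx = self.rng.choice(n_seq, size=min(cfg.batch_size, n_seq),
                                      replace=False)
                hr_idx = self.rng.choice(len(dataset.train_hr),
                                         size=len(idx), replace=len(dataset.train_hr) < len(idx))
                lr_batch, flows_batch = [], []
                for i in idx:
                    clip, flows = dataset.crop(int(i), cfg.seq_len, self.rng)
                    lr_batch.append(clip)
                    flows_batch.append(flows)
                hr_batch = [dataset.train_hr[int(j)] for j in hr_idx]
                self.train_step(lr_batch, hr_batch, flows_batch)
            if cfg.eval_every and (epoch + 1) % cfg.eval_every == 0:
                self._checkpoint_if_best(dataset, best, out_dir)
            if progress:
                last = self.log[-1]
                print(f"epoch {epoch + 1}/{cfg.epochs} lr={lr_now:.2e} "
                      f"total={last['total']:.3f} d={last['d_loss']:.3f} "
                      f"({time.time() - t0:.0f}s)")
        summary = self._checkpoint_if_best(dataset, best, out_dir)
        if out_dir is not None:
            save_checkpoint(self, out_dir / "last.npz")
            dataio.write_json({"log": self.log, "best": best,
                               "val": summary, "config": cfg.asdict()},
                              out_dir / "training_log.json")
        return {"log": self.log, "best": best, "val": summary}

    def _checkpoint_if_best(self, dataset, best: dict, out_dir):
        summary = self.evaluate(dataset)
        if summary and summary["fid"] < best["fid"]:
            best.update(fid=summary["fid"], epoch=self.epoch)
            if out_dir is not None:
                save_checkpoint(self, Path(out_dir) / "best.npz")
        return summary

    def ema_generator(self) -> RecurrentGenerator:
        """Inference copy of G with exponentially averaged weights."""
        gen = RecurrentGenerator(copy.deepcopy(self.generator.config), seed=0)
        gen.load_state_dict(self.ema)
        return gen

    def evaluate(self, dataset) -> dict | None:
        """Held-out no-reference scores (+SSIM when references exist)."""
        if not dataset.val_lr or not dataset.val_hr:
            return None
        model = self.ema_generator()
        gen_frames, in_frames, ref_frames = [], [], []
        for i, clip in enumerate(dataset.val_lr):
            out = model.super_resolve(clip)
            gen_frames.extend(out)
            in_frames.extend(clip)
            if dataset.val_ref:
                ref_frames.extend(dataset.val_ref[i])
        emb = iqa.RandomConvEmbedder(seed=0)
        hr = list(dataset.val_hr)
        gen_rep = iqa.compare_image_sets(hr, gen_frames, embedder=emb, seed=0)
        result = {"fid": gen_rep.fid, "abs_delta_fne": gen_rep.abs_delta_fne,
                  "abs_delta_gcf": gen_rep.abs_delta_gcf}
        if ref_frames:
            _, ssim = iqa.psnr_ssim(np.asarray(gen_frames), np.asarray(ref_frames))
            result["ssim"] = ssim
        return result


# --------------------------------------------------------------- dataset


class PhantomDataset:
    """In-memory view of a dataset directory written by the phantom module."""

    def __init__(self, root):
        self.root = Path(root)
        manifest = dataio.read_json(self.root / "manifest.json")
        self.manifest = manifest
        self.train_lr, self.val_lr = [], []
        self.train_ref, self.val_ref = [], []
        self.train_hr, self.val_hr = [], []
        for item in manifest["items"]:
            if item["role"] == "lr_sequence":
                seq = dataio.load_sequence(self.root / item["path"])
                ref = dataio.load_sequence(self.root / item["reference_path"])
                if item["split"] == "train":
                    self.train_lr.append(seq)
                    self.train_ref.append(ref)
                else:
                    self.val_lr.append(seq)
                    self.val_ref.append(ref)
            elif item["role"] == "hr_image":
                img = dataio.load_image(self.root / item["path"])
                (self.train_hr if item["split"] == "train" else self.val_hr).append(img)
        self._flow_cache: dict[int, tuple] = {}

    def flows(self, index: int):
        if index not in self._flow_cache:
            self._flow_cache[index] = flowmod.sequence_flows(self.train_lr[index])
        return self._flow_cache[index]

    def crop(self, index: int, seq_len: int, rng: np.random.Generator):
        """Random temporal crop of clip ``index`` with matching flows."""
        clip = self.train_lr[index]
        t_total = clip.shape[0]
        seq_len = min(seq_len, t_total)
        start = int(rng.integers(t_total - seq_len + 1))
        bwd, fwd = self.flows(index)
        sl = slice(start, start + seq_len - 1)
        return clip[start : start + seq_len], (bwd[sl], fwd[sl])


# ------------------------------------------------------------ checkpoints


def save_checkpoint(trainer: Trainer, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, module in (("g", trainer.generator), ("d", trainer.discriminator)):
        for k, v in module.state_dict().items():
            arrays[f"{tag}:{k}"] = v
    if trainer.heads is not None:
        for k, v in trainer.heads.state_dict().items():
            arrays[f"h:{k}"] = v
    for k, v in trainer.ema.items():
        arrays[f"e:{k}"] = v
    for tag, opt in (("og", trainer.opt_g), ("od", trainer.opt_d)):
        st = opt.state_dict()
        for i, m in enumerate(st["m"]):
            arrays[f"{tag}:m:{i}"] = m
        for i, v in enumerate(st["v"]):
            arrays[f"{tag}:v:{i}"] = v
        arrays[f"{tag}:t"] = np.array(st["t"])
        arrays[f"{tag}:lr"] = np.array(st["lr"])
    meta = {
        "config": trainer.config.asdict(),
        "step": trainer.step,
        "epoch": trainer.epoch,
        "rng_state": trainer.rng.bit_generator.state,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> Trainer:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        trainer = Trainer(TrainConfig(**_clean_config(meta["config"])))
        g_state = {k[2:]: data[k] for k in data.files if k.startswith("g:")}
        d_state = {k[2:]: data[k] for k in data.files if k.startswith("d:")}
        trainer.generator.load_state_dict(g_state)
        trainer.discriminator.load_state_dict(d_state)
        if trainer.heads is not None:
            h_state = {k[2:]: data[k] for k in data.files if k.startswith("h:")}
            trainer.heads.load_state_dict(h_state)
        trainer.ema = {k[2:]: data[k].copy() for k in data.files if k.startswith("e:")}
        for tag, opt in (("og", trainer.opt_g), ("od", trainer.opt_d)):
            n = len(opt.params)
            opt.load_state_dict({
                "t": data[f"{tag}:t"], "lr": data[f"{tag}:lr"],
                "m": [data[f"{tag}:m:{i}"] for i in range(n)],
                "v": [data[f"{tag}:v:{i}"] for i in range(n)],
            })
        trainer.step = int(meta["step"])
        trainer.epoch = int(meta["epoch"]) + 1  # resume at the next epoch
        trainer.rng.bit_generator.state = meta["rng_state"]
    return trainer


def _clean_config(d: dict) -> dict:
    d = dict(d)
    d["weights"] = contrastive.LossWeights(**d["weights"])
    d["generator"] = GeneratorConfig(**d["generator"])
    d["adam_betas"] = tuple(d["adam_betas"])
    return d


def load_generator(path, averaged: bool = True) -> RecurrentGenerator:
    """Load the enhancement network from a checkpoint (EMA weights by default)."""
    trainer = load_checkpoint(path)
    return trainer.ema_generator() if averaged else trainer.generator


def ablation_variant(source, which: str) -> RecurrentGenerator:
    """Inference-time variant of a trained model.

    ``which``: ``"zero_warp"`` replaces the warped propagated features with
    zeros (each output frame becomes independent of its neighbours) or
    ``"none"`` for the unmodified model.  ``source`` is a checkpoint path or
    a :class:`RecurrentGenerator`.
    """
    if which not in ("zero_warp", "none"):
        raise ValueError(f"unknown ablation variant {which!r}")
    gen = source if isinstance(source, RecurrentGenerator) else load_generator(source)
    if which == "none":
        return gen
    clone = RecurrentGenerator(copy.deepcopy(gen.config), seed=0)
    clone.load_state_dict(gen.state_dict())
    clone.config.zero_warp = True
    return clone
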
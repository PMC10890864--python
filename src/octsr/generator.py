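"""Bidirectional recurrent enhancement network.

The generator maps a T-frame low-quality clip to T enhanced frames at the
same resolution (the task is quality transfer, not spatial upscaling).  Per
frame it: embeds the image with a strided 1x1 convolution; estimates optical
flow to the adjacent frame; backward-warps the hidden features propagated
from that frame; and refines the concatenation of warped state and current
embedding through a stack of residual blocks (instance norm + ReLU).  This
recurrence runs once backward (t = T-1..0, neighbour t+1) and once forward
(t = 0..T-1, neighbour t-1).  The two per-frame states are concatenated,
fused, upsampled by pixel shuffle back to the input resolution and squashed
by tanh into (-1, 1).

The same encoder (embedding + first reconstruction convolutions) doubles as
the feature extractor for the patchwise contrastive loss: features of the
input and of the generated output are taken from five taps — the raw pixels,
the embedding convolution, the first reconstruction convolution, and the
second and fourth residual blocks — with shared weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import flow as flowmod
from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

NCE_LAYERS = ("l0", "l1", "l2", "l3", "l4")


@dataclass
class GeneratorConfig:
    n_res_blocks: int = 10
    feat_channels: int = 128
    downsample_stride: int = 2
    flow_backend: str = "builtin_pyramidal"
    window: int = 4                  # time-window N (T = N + 1 at training)
    up_channels: int = 16            # channels after pixel shuffle
    zero_warp: bool = False          # ablation: propagate nothing
    input_skip: bool = False         # optional residual skip of the input frame

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.downsample_stride not in (1, 2, 4):
            raise ValueError("downsample_stride must be 1, 2 or 4")
        if self.flow_backend not in flowmod.BACKENDS + ("zero",):
            raise ValueError(f"unknown flow backend {self.flow_backend!r}")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


class _ReconstructionBranch(nn.Module):
    """Rec(.): fuse warped state with the frame embedding, refine residually."""

    def __init__(self, channels: int, n_blocks: int, *, rng):
        self.in_conv = nn.Conv2d(2 * channels, channels, 3, padding=1, rng=rng)
        self.blocks = [nn.ResidualBlock(channels, rng=rng) for _ in range(n_blocks)]

    def forward(self, state: Tensor, embed: Tensor, taps: dict | None = None) -> Tensor:
        h = self.in_conv(nn.concat([state, embed], axis=1))
        if taps is not None:
            taps["l2"] = h
        h = h.relu()
        for i, block in enumerate(self.blocks):
            h = block(h)
            if taps is not None and i + 1 in (2, 4):
                taps[f"l{1 + (i + 1) // 2 + 1}"] = h  # block 2 -> l3, block 4 -> l4
        return h


class RecurrentGenerator(nn.Module):
    """The full enhancement network G."""

    def __init__(self, config: GeneratorConfig | None = None, seed: int = 0):
        self.config = config or GeneratorConfig()
        rng = np.random.default_rng(seed)
        c = self.config.feat_channels
        s = self.config.downsample_stride
        self.embed = nn.Conv2d(1, c, 1, stride=s, rng=rng)
        self.rec_backward = _ReconstructionBranch(c, self.config.n_res_blocks, rng=rng)
        self.rec_forward = _ReconstructionBranch(c, self.config.n_res_blocks, rng=rng)
        self.fuse = nn.Conv2d(2 * c, c, 1, rng=rng)
        self.up_conv = nn.Conv2d(c, self.config.up_channels * s * s, 3, padding=1, rng=rng)
        if s > 1:
            # ICNR-style init: every pixel-shuffle phase starts from the same
            # kernel, so the untrained upsampler is free of checkerboarding.
            w = self.up_conv.weight.data
            base = w[:: s * s].copy()
            self.up_conv.weight.data = np.repeat(base, s * s, axis=0)
        self.out_conv = nn.Conv2d(self.config.up_channels, 1, 3, padding=1, rng=rng)
        # Gentle final-layer init: pre-tanh activations start small, so the
        # untrained network emits mid-range intensities rather than saturating.
        self.out_conv.weight.data *= 0.1

    # ----------------------------------------------------------- components
    def downsample_embed(self, frames: Tensor) -> Tensor:
        """Strided 1x1 embedding of (N, 1, H, W) frames in [-1, 1]."""
        _, _, h, w = frames.shape
        s = self.config.downsample_stride
        if h % s or w % s:
            raise ValueError(f"spatial size {(h, w)} not divisible by stride {s}")
        return self.embed(frames)

    def estimate_flow(self, ref: np.ndarray, adj: np.ndarray) -> np.ndarray:
        """Pixel-resolution flow aligning ``adj`` toward ``ref`` (fixed, no grad)."""
        backend = self.config.flow_backend
        return flowmod.estimate_flow(ref, adj, backend=backend)

    def _flow_to_feature_grid(self, flow: np.ndarray) -> np.ndarray:
        """Average-pool a (2, H, W) pixel flow to feature resolution."""
        s = self.config.downsample_stride
        if s == 1:
            return flow[None]
        c, h, w = flow.shape
        pooled = flow.reshape(c, h // s, s, w // s, s).mean(axis=(2, 4)) / s
        return pooled[None].astype(np.float32)

    def warp_features(self, feats: Tensor, feature_flow: np.ndarray) -> Tensor:
        return F.warp_bilinear(feats, feature_flow)

    def reconstruct(self, warped_state: Tensor, embed: Tensor,
                    direction: str, taps: dict | None = None) -> Tensor:
        branch = self.rec_backward if direction == "backward" else self.rec_forward
        return branch(warped_state, embed, taps)

    # ----------------------------------------------------------- propagation
    def propagate(self, sequence: np.ndarray, direction: str,
                  flows: list[np.ndarray] | None = None,
                  embeds: list[Tensor] | None = None) -> list[Tensor]:
        """Run one recurrence direction; returns per-frame hidden states.

        ``flows`` are pixel-resolution fields: for ``backward``, flows[t]
        aligns frame t+1 toward t; for ``forward``, flows[t] aligns frame t
        toward t+1 (see :func:`octsr.flow.sequence_flows`).
        """
        if direction not in ("backward", "forward"):
            raise ValueError("direction must be 'backward' or 'forward'")
        seq = np.asarray(sequence, dtype=np.float32)
        t_frames = seq.shape[0]
        if embeds is None:
            embeds = self._embed_all(seq)
        states: dict[int, Tensor] = {}
        order = range(t_frames - 1, -1, -1) if direction == "backward" else range(t_frames)
        prev: Tensor | None = None
        for t in order:
            if prev is None or self.config.zero_warp:
                warped = Tensor(np.zeros_like(embeds[t].data))
            else:
                adj = t + 1 if direction == "backward" else t - 1
                if flows is not None:
                    px_flow = flows[t if direction == "backward" else t - 1]
                else:
                    px_flow = self.estimate_flow(seq[t], seq[adj])
                warped = self.warp_features(prev, self._flow_to_feature_grid(px_flow))
            prev = self.reconstruct(warped, embeds[t], direction)
            states[t] = prev
        return [states[t] for t in range(t_frames)]

    def _embed_all(self, seq: np.ndarray) -> list[Tensor]:
        t_frames = seq.shape[0]
        all_embeds = self.downsample_embed(Tensor(seq[:, None]))
        return [all_embeds[t : t + 1] for t in range(t_frames)]

    def fuse_upsample(self, h_forward: Tensor, h_backward: Tensor) -> Tensor:
        """Aggr + Up of Eq.-style fusion: concat, 1x1 fuse, pixel shuffle, tanh."""
        s = self.config.downsample_stride
        h = self.fuse(nn.concat([h_forward, h_backward], axis=1)).relu()
        h = self.up_conv(h)
        h = F.pixel_shuffle(h, s) if s > 1 else h
        return self.out_conv(h.relu()).tanh()

    # -------------------------------------------------------------- pipeline
    def forward(self, sequence: np.ndarray,
                flows: tuple[list, list] | None = None) -> list[Tensor]:
        """Full pipeline; returns one (1, 1, H, W) output Tensor per frame."""
        seq = np.asarray(sequence, dtype=np.float32)
        if seq.ndim != 3 or seq.shape[0] < 1:
            raise ValueError("sequence must be (T, H, W) with T >= 1")
        if flows is None and self.config.flow_backend == "builtin_pyramidal" \
                and not self.config.zero_warp and seq.shape[0] > 1:
            flows = flowmod.sequence_flows(seq, backend=self.config.flow_backend)
        bwd_flows, fwd_flows = flows if flows is not None else (None, None)
        embeds = self._embed_all(seq)
        h_b = self.propagate(seq, "backward", bwd_flows, embeds)
        h_f = self.propagate(seq, "forward", fwd_flows, embeds)
        outputs = []
        for t in range(seq.shape[0]):
            y = self.fuse_upsample(h_f[t], h_b[t])
            if self.config.input_skip:
                y = (y + Tensor(seq[t : t + 1][:, None])).tanh()
            outputs.append(y)
        return outputs

    def super_resolve(self, sequence: np.ndarray) -> np.ndarray:
        """Inference: (T, H, W) in [-1, 1] -> enhanced (T, H, W) in (-1, 1).

        Inputs whose spatial size is not a stride multiple are edge-padded
        for the forward pass and cropped back afterwards.
        """
        seq = np.asarray(sequence, dtype=np.float32)
        s = self.config.downsample_stride
        h, w = seq.shape[1], seq.shape[2]
        ph, pw = (-h) % s, (-w) % s
        if ph or pw:
            seq = np.pad(seq, ((0, 0), (0, ph), (0, pw)), mode="edge")
        with nn.no_grad():
            outs = self.forward(seq)
        out = np.concatenate([o.data[:, 0] for o in outs], axis=0)
        return out[:, :h, :w]

    # ---------------------------------------------------- feature extraction
    def extract_layer_features(self, frame: Tensor | np.ndarray,
                               layers=NCE_LAYERS) -> dict[str, Tensor]:
        """Encoder taps for the contrastive loss (weights shared with G).

        ``frame`` is (N, 1, H, W); the reconstruction path runs with a
        zero propagated state, i.e. the single-frame encoder of the network.
        """
        unknown = set(layers) - set(NCE_LAYERS)
        if unknown:
            raise ValueError(f"unknown layer ids: {sorted(unknown)}")
        x = frame if isinstance(frame, Tensor) else Tensor(np.asarray(frame, np.float32))
        taps: dict[str, Tensor] = {"l0": x}
        emb = self.downsample_embed(x)
        taps["l1"] = emb
        if {"l2", "l3", "l4"} & set(layers):
            if self.config.n_res_blocks < 4:
                raise ValueError("layers l3/l4 need at least 4 residual blocks")
            zero = Tensor(np.zeros_like(emb.data))
            self.rec_backward(zero, emb, taps)
        return {k: taps[k] for k in layers}
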
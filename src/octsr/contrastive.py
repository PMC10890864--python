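"""Multilayer patchwise contrastive loss, perceptual loss, total objective.

For each encoder tap l, a set of spatial sites is drawn without replacement.
The feature vectors of the *input* frame at those sites are the queries
{u_i}; the features of the *generated* frame at the same sites are the
positives {v_i}; the remaining sampled input sites provide each query's
negatives (internal negatives, K = P - 1).  After an optional two-layer
projection head, all vectors are l2-normalised and scored with the InfoNCE
objective at temperature tau:

    L = -sum_l  mean_i  log[ exp(u_i.v_i / tau) /
                             (exp(u_i.v_i / tau) + sum_k exp(u_i.n_k / tau)) ]

The per-layer reduction is the mean over queries (summed over layers) so the
loss scale does not depend on the patch count; the raw double sum is
available with ``reduction="sum"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor


@dataclass
class LossWeights:
    """Weights of the total objective: gan + contrastive + perceptual."""

    lambda_gan: float = 1.0
    lambda_contrastive: float = 20.0
    lambda_perceptual: float = 1.0

    def validate(self):
        if min(self.lambda_gan, self.lambda_contrastive, self.lambda_perceptual) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LayerBank:
    """Sampled patch features of one encoder layer."""

    queries: Tensor          # (P, d) unit-normalised
    positives: Tensor        # (P, d) unit-normalised, same sites as queries
    negatives: Tensor | None = None   # (P, K, d); None => internal negatives
    coords: np.ndarray | None = None  # (P, 2) sampled (y, x) sites

    @property
    def n_queries(self) -> int:
        return self.queries.shape[0]

    @property
    def n_negatives(self) -> int:
        if self.negatives is not None:
            return self.negatives.shape[1]
        return self.n_queries - 1


@dataclass
class PatchFeatureBank:
    layers: dict = field(default_factory=dict)   # layer id -> LayerBank
    temperature: float = 0.07


class ProjectionHeads(nn.Module):
    """Per-layer 2-layer MLP (ReLU) applied to patch features before scoring."""

    def __init__(self, in_dims: dict[str, int], hidden: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layer_ids = sorted(in_dims)
        self.heads = [
            _Mlp(in_dims[k], hidden, rng=rng) for k in self.layer_ids
        ]

    def project(self, layer_id: str, feats: Tensor) -> Tensor:
        return self.heads[self.layer_ids.index(layer_id)](feats)


class _Mlp(nn.Module):
    def __init__(self, d_in, hidden, *, rng):
        self.fc1 = nn.Linear(d_in, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, hidden, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def sample_patch_triplets(feats_x: dict[str, Tensor], feats_y: dict[str, Tensor],
                          n_patches: int, rng: np.random.Generator,
                          heads: ProjectionHeads | None = None,
                          temperature: float = 0.07) -> PatchFeatureBank:
    """Draw spatially corresponding query/positive patches per layer.

    ``feats_x``/``feats_y`` map layer id -> (1, C, H, W) feature tensors of
    the input and generated frames (spatially congruent per layer).
    """
    bank = PatchFeatureBank(temperature=temperature)
    for lid in sorted(feats_x):
        fx, fy = feats_x[lid], feats_y[lid]
        if fx.shape[2:] != fy.shape[2:]:
            raise ValueError(f"{lid}: input/output feature grids differ")
        _, _, h, w = fx.shape
        n_sites = h * w
        if n_patches > n_sites:
            raise ValueError(f"{lid}: {n_patches} patches > {n_sites} sites")
        flat = rng.choice(n_sites, size=n_patches, replace=False)
        ys, xs = np.divmod(flat, w)
        u = F.gather_spatial(fx, ys, xs)[0]     # (P, C)
        v = F.gather_spatial(fy, ys, xs)[0]
        if heads is not None:
            u = heads.project(lid, u)
            v = heads.project(lid, v)
        bank.layers[lid] = LayerBank(
            queries=F.l2_normalize(u, axis=1),
            positives=F.l2_normalize(v, axis=1),
            coords=np.stack([ys, xs], axis=1),
        )
    return bank


def patch_nce_loss(bank: PatchFeatureBank, reduction: str = "mean") -> Tensor:
    """InfoNCE over all layers of the bank; see module docstring."""
    if bank.temperature <= 0:
        raise ValueError("temperature must be positive")
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    inv_t = 1.0 / bank.temperature
    total: Tensor | None = None
    for lid in sorted(bank.layers):
        lb = bank.layers[lid]
        u, v = lb.queries, lb.positives
        p = lb.n_queries
        pos = (u * v).sum(axis=1, keepdims=True)              # (P, 1)
        if lb.negatives is not None:
            # (P, 1, d) @ (P, d, K) -> (P, 1, K)
            k = lb.negatives.shape[1]
            neg = (u.reshape(p, 1, -1) @ lb.negatives.transpose(0, 2, 1)).reshape(p, k)
            logits = nn.concat([pos, neg], axis=1) * inv_t
        elif p > 1:
            sim = u @ u.transpose(1, 0)                       # (P, P)
            rows = np.repeat(np.arange(p), p - 1)
            cols = np.concatenate([np.delete(np.arange(p), i) for i in range(p)])
            neg = sim[rows, cols].reshape(p, p - 1)
            logits = nn.concat([pos, neg], axis=1) * inv_t
        else:
            logits = pos * inv_t
        per_query = logits.logsumexp(axis=1) - logits[:, 0]   # (P,)
        term = per_query.mean() if reduction == "mean" else per_query.sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("empty bank")
    return total


class PerceptualNet(nn.Module):
    """Fixed (non-trained) convolutional feature network with recorded seed.

    Three stride-2 convolutions with ReLU; the perceptual distance is the
    mean squared difference of the final feature maps.
    """

    def __init__(self, seed: int = 0, channels=(8, 16, 32)):
        rng = np.random.default_rng(seed)
        self.seed = seed
        c_in = 1
        self.convs = []
        for c in channels:
            self.convs.append(nn.Conv2d(c_in, c, 3, stride=2, padding=1, rng=rng))
            c_in = c
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        return h


def perceptual_loss(x_t, y_hat_t, net: PerceptualNet) -> Tensor:
    """Mean squared distance between deep features of the two frames."""
    xt = x_t if isinstance(x_t, Tensor) else Tensor(np.asarray(x_t, np.float32))
    yt = y_hat_t if isinstance(y_hat_t, Tensor) else Tensor(np.asarray(y_hat_t, np.float32))
    if xt.shape != yt.shape:
        raise ValueError("perceptual loss needs same-shape frames")
    return F.mse(net(xt), net(yt))


def total_generator_loss(gan_g, contr, perc, weights: LossWeights):
    """Weighted sum of the three generator objectives.

    Setting a weight to zero reproduces the corresponding training ablation
    (without perceptual / without contrastive / without adversarial term).
    """
    weights.validate()
    return (weights.lambda_gan * gan_g
            + weights.lambda_contrastive * contr
            + weights.lambda_perceptual * perc)
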
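"""Patch discriminator and the adversarial objective.

The discriminator is the standard 70x70-receptive-field patch critic: four
4x4 convolutions (stride 2, 2, 2, 1) with instance normalisation after all
but the first, leaky-ReLU slopes of 0.2, and a final 4x4 convolution to one
logit channel.  Each output logit scores the realness of one receptive-field
patch of a single frame; temporal context is deliberately absent (the
generator, not the critic, owns time).

Losses use the logistic (log) form of the two-player objective.  The
generator's default is the non-saturating variant -log D(G(x)); the literal
log(1 - D(G(x))) minimisation is available via ``saturating=True``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.autograd import Tensor


class PatchDiscriminator(nn.Module):
    def __init__(self, base_channels: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base_channels
        self.conv1 = nn.Conv2d(1, b, 4, stride=2, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(b, 2 * b, 4, stride=2, padding=1, rng=rng)
        self.norm2 = nn.InstanceNorm2d(2 * b)
        self.conv3 = nn.Conv2d(2 * b, 4 * b, 4, stride=2, padding=1, rng=rng)
        self.norm3 = nn.InstanceNorm2d(4 * b)
        self.conv4 = nn.Conv2d(4 * b, 8 * b, 4, stride=1, padding=1, rng=rng)
        self.norm4 = nn.InstanceNorm2d(8 * b)
        self.head = nn.Conv2d(8 * b, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, frame: Tensor) -> Tensor:
        if frame.shape[1] != 1:
            raise ValueError("discriminator expects single-channel frames")
        h = self.conv1(frame).leaky_relu(0.2)
        h = self.norm2(self.conv2(h)).leaky_relu(0.2)
        h = self.norm3(self.conv3(h)).leaky_relu(0.2)
        h = self.norm4(self.conv4(h)).leaky_relu(0.2)
        return self.head(h)

    discriminate = forward


def gan_loss_discriminator(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """-E log sigma(real) - E log(1 - sigma(fake)), mean over patches."""
    return (-real_logits).softplus().mean() + fake_logits.softplus().mean()


def gan_loss_generator(fake_logits: Tensor, saturating: bool = False) -> Tensor:
    """Generator's half of the objective.

    Non-saturating default: mean of -log sigma(fake).  The saturating form
    minimises E log(1 - sigma(fake)) literally.
    """
    if saturating:
        return -(fake_logits.softplus().mean())
    return (-fake_logits).softplus().mean()
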
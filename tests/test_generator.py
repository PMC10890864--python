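"""Architecture and information-flow contracts of the recurrent generator."""

import numpy as np
import pytest

from octsr.generator import GeneratorConfig, RecurrentGenerator
from octsr.nn import concat
from octsr.nn import functional as F
from octsr.nn.autograd import Tensor
from octsr.phantom import PhantomSpec, generate_hr_image, generate_lr_sequence

TOY = dict(n_res_blocks=4, feat_channels=24)


@pytest.fixture(scope="module")
def toy_gen():
    return RecurrentGenerator(GeneratorConfig(**TOY), seed=0)


@pytest.fixture(scope="module")
def clip():
    spec = PhantomSpec()
    hr = generate_hr_image(spec, 1)
    lr, _ = generate_lr_sequence(hr, spec, 2)
    return lr


# ------------------------------------------------------------------ embed


def test_embed_shape_contract(toy_gen):
    out = toy_gen.downsample_embed(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
    assert out.shape == (1, 24, 32, 32)


def test_embed_rejects_indivisible_size(toy_gen):
    with pytest.raises(ValueError):
        toy_gen.downsample_embed(Tensor(np.zeros((1, 1, 63, 64), np.float32)))


def test_stride1_identity_weights_pass_input_through():
    gen = RecurrentGenerator(
        GeneratorConfig(n_res_blocks=4, feat_channels=1, downsample_stride=1), seed=0)
    gen.embed.weight.data = np.ones((1, 1, 1, 1), np.float32)
    gen.embed.bias.data = np.zeros(1, np.float32)
    x = np.random.default_rng(0).normal(size=(1, 1, 16, 16)).astype(np.float32)
    np.testing.assert_allclose(gen.downsample_embed(Tensor(x)).data, x, atol=1e-7)


def test_embed_gradient_reaches_every_sampled_pixel(toy_gen):
    # A strided 1x1 convolution reads exactly the stride lattice; every pixel
    # on that lattice must receive gradient (off-lattice pixels cannot, by
    # construction of the published embedding).
    x = Tensor(np.zeros((1, 1, 16, 16), np.float32), requires_grad=True)
    toy_gen.downsample_embed(x).sum().backward()
    s = toy_gen.config.downsample_stride
    assert np.abs(x.grad[0, 0, ::s, ::s]).min() > 0
    assert not np.abs(x.grad[0, 0, 1::s, 1::s]).any()


# ------------------------------------------------------------------- warp


def test_warp_zero_flow_is_exact_identity():
    rng = np.random.default_rng(0)
    feats = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    out = F.warp_bilinear(feats, np.zeros((1, 2, 8, 8), np.float32))
    np.testing.assert_array_equal(out.data, feats.data)


def test_warp_inverts_integer_shift_in_interior():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(1, 3, 16, 16)).astype(np.float32)
    shifted = np.roll(base, shift=1, axis=3)  # content moved +1 in x
    flow = np.zeros((1, 2, 16, 16), np.float32)
    flow[:, 0] = 1.0  # sample at x+1 recovers the unshifted features
    out = F.warp_bilinear(Tensor(shifted), flow)
    np.testing.assert_allclose(out.data[:, :, :, :-1], base[:, :, :, :-1], atol=1e-5)


def test_warp_out_of_bounds_clamps_to_border():
    feats = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
    flow = np.full((1, 2, 4, 4), 100.0, np.float32)  # beyond the grid
    out = F.warp_bilinear(Tensor(feats), flow)
    assert np.all(out.data == feats[0, 0, -1, -1])


def test_warp_rejects_non_finite_flow():
    with pytest.raises(ValueError):
        F.warp_bilinear(Tensor(np.zeros((1, 1, 4, 4), np.float32)),
                        np.full((1, 2, 4, 4), np.nan))


# ------------------------------------------------------------ reconstruct


def test_reconstruct_shape_and_residual_identity(toy_gen):
    rng = np.random.default_rng(2)
    state = Tensor(rng.normal(size=(1, 24, 8, 8)).astype(np.float32))
    emb = Tensor(rng.normal(size=(1, 24, 8, 8)).astype(np.float32))
    out = toy_gen.reconstruct(state, emb, "backward")
    assert out.shape == (1, 24, 8, 8)

    # zero every residual branch: output equals the post-projection input
    gen = RecurrentGenerator(GeneratorConfig(**TOY), seed=1)
    for block in gen.rec_backward.blocks:
        block.conv2.weight.data[:] = 0.0
        block.conv2.bias.data[:] = 0.0
    projected = gen.rec_backward.in_conv(concat([state, emb], axis=1)).relu()
    out = gen.reconstruct(state, emb, "backward")
    np.testing.assert_allclose(out.data, projected.data, atol=1e-6)


def test_reconstruct_is_seed_reproducible(clip):
    a = RecurrentGenerator(GeneratorConfig(**TOY), seed=7).super_resolve(clip[:2])
    b = RecurrentGenerator(GeneratorConfig(**TOY), seed=7).super_resolve(clip[:2])
    np.testing.assert_array_equal(a, b)


# -------------------------------------------------------------- propagate


def test_single_frame_propagation_reduces_to_zero_state_reconstruct(toy_gen, clip):
    seq = clip[:1]
    states = toy_gen.propagate(seq, "backward")
    emb = toy_gen._embed_all(seq)[0]
    zero = Tensor(np.zeros_like(emb.data))
    direct = toy_gen.reconstruct(zero, emb, "backward")
    np.testing.assert_allclose(states[0].data, direct.data, atol=1e-6)
    fwd = toy_gen.propagate(seq, "forward")
    direct_f = toy_gen.reconstruct(zero, emb, "forward")
    np.testing.assert_allclose(fwd[0].data, direct_f.data, atol=1e-6)


def test_zero_warp_makes_frames_independent(clip):
    cfg = GeneratorConfig(zero_warp=True, **TOY)
    gen = RecurrentGenerator(cfg, seed=0)
    out_a = gen.super_resolve(clip[:3])
    perturbed = clip[:3].copy()
    perturbed[2] = -perturbed[2]
    out_b = gen.super_resolve(perturbed)
    np.testing.assert_array_equal(out_a[0], out_b[0])
    np.testing.assert_array_equal(out_a[1], out_b[1])
    assert not np.array_equal(out_a[2], out_b[2])


def test_branch_causality(toy_gen, clip):
    """Perturbing the last frame alters h_0 backward but not h_0 forward."""
    seq = clip[:3]
    pert = seq.copy()
    pert[2] = np.clip(pert[2] + 0.5, -1, 1)
    hb = toy_gen.propagate(seq, "backward")[0].data
    hb_p = toy_gen.propagate(pert, "backward")[0].data
    assert not np.array_equal(hb, hb_p)
    hf = toy_gen.propagate(seq, "forward")[0].data
    hf_p = toy_gen.propagate(pert, "forward")[0].data
    np.testing.assert_array_equal(hf, hf_p)


def test_temporal_sensitivity_with_warping(toy_gen, clip):
    """With propagation enabled, frame t responds to a change at frame t+1."""
    seq = clip[:3]
    pert = seq.copy()
    pert[1] = np.clip(pert[1] + 0.3, -1, 1)
    out_a = toy_gen.super_resolve(seq)
    out_b = toy_gen.super_resolve(pert)
    assert not np.array_equal(out_a[0], out_b[0])


# ----------------------------------------------------------- fuse/upsample


def test_pixel_shuffle_rearrangement_definition():
    s = 2
    x = np.arange(2 * 8 * 3 * 3, dtype=np.float32).reshape(2, 8, 3, 3)
    out = F.pixel_shuffle(Tensor(x), s).data
    assert out.shape == (2, 2, 6, 6)
    for c in range(2):
        for y in range(6):
            for xx in range(6):
                src = c * s * s + (y % s) * s + (xx % s)
                assert out[0, c, y, xx] == x[0, src, y // s, xx // s]


def test_outputs_bounded_and_resolution_preserved(toy_gen, clip):
    out = toy_gen.super_resolve(clip)
    assert out.shape == clip.shape
    assert np.all(np.abs(out) < 1.0)


def test_accepts_inference_lengths_two_to_nine():
    spec = PhantomSpec(height_px=32, width_px=32, frames_per_sequence=9)
    hr = generate_hr_image(spec, 0)
    lr, _ = generate_lr_sequence(hr, spec, 0)
    gen = RecurrentGenerator(GeneratorConfig(**TOY), seed=0)
    for t in range(2, 10):
        out = gen.super_resolve(lr[:t])
        assert out.shape == (t, 32, 32)


# ------------------------------------------------------- default topology


def test_default_architecture_matches_published_sizes():
    gen = RecurrentGenerator(GeneratorConfig(), seed=0)
    assert len(gen.rec_backward.blocks) == 10
    assert len(gen.rec_forward.blocks) == 10
    assert gen.rec_backward.blocks[0].conv1.weight.shape == (128, 128, 3, 3)
    assert gen.embed.weight.shape == (128, 1, 1, 1)
    x = np.random.default_rng(0).uniform(-1, 1, size=(2, 32, 32)).astype(np.float32)
    out = gen.super_resolve(x)
    assert out.shape == (2, 32, 32)
    assert np.all(np.abs(out) < 1.0)


# ------------------------------------------------------------- zero flow


def test_zero_flow_backend_equals_warp_passthrough(clip):
    cfg = GeneratorConfig(flow_backend="zero", **TOY)
    gen = RecurrentGenerator(cfg, seed=0)
    out_a = gen.super_resolve(clip[:3])

    passthrough = RecurrentGenerator(GeneratorConfig(flow_backend="zero", **TOY), seed=0)
    passthrough.warp_features = lambda feats, flow: feats  # identity transport
    out_b = passthrough.super_resolve(clip[:3])
    np.testing.assert_allclose(out_a, out_b, atol=1e-6)


# ----------------------------------------------------- feature extraction


def test_layer_features_shapes_and_pixel_tap(toy_gen, clip):
    x = Tensor(clip[:1][:, None])
    feats = toy_gen.extract_layer_features(x)
    np.testing.assert_array_equal(feats["l0"].data, x.data)
    sizes = [feats[k].shape[2] for k in ("l0", "l1", "l2", "l3", "l4")]
    assert sizes[0] >= sizes[1]
    assert sizes[1] == sizes[2] == sizes[3] == sizes[4]


def test_layer_features_share_generator_weights(toy_gen):
    assert toy_gen.extract_layer_features.__self__ is toy_gen
    x = Tensor(np.zeros((1, 1, 64, 64), np.float32))
    before = toy_gen.embed.weight
    toy_gen.extract_layer_features(x)
    assert toy_gen.embed.weight is before  # same Parameter object, no copies


def test_layer_features_rejects_unknown_ids(toy_gen):
    with pytest.raises(ValueError):
        toy_gen.extract_layer_features(np.zeros((1, 1, 64, 64), np.float32),
                                       layers=("l0", "l9"))
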
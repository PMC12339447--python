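"""Patching, masking, the masked loss, and the autoencoder contracts."""

import time

import numpy as np
import pytest

from retmae.mae import (MAEConfig, BackboneSpec, PatchGrid, build_mae,
                        forward_reconstruct, load_checkpoint, masked_mse_loss,
                        patchify, preset, sample_mask, sample_masks,
                        save_checkpoint, unpatchify)
from retmae.nn import Tensor

RNG = np.random.default_rng(0)


# --------------------------------------------------------------------- grid
@pytest.mark.parametrize("size,patch,expected", [
    ((224, 224), 16, 196),
    ((64, 64), 8, 64),
])
def test_patch_counts(size, patch, expected):
    assert PatchGrid(size, patch).n_patches == expected


def test_grid_rejects_non_divisible_sizes():
    with pytest.raises(ValueError, match="divisible"):
        PatchGrid((60, 64), 8)


def test_patchify_round_trip_is_exact():
    grid = PatchGrid((64, 64), 8)
    for _ in range(100):
        img = RNG.normal(size=(64, 64))
        assert np.array_equal(unpatchify(patchify(img, grid), grid), img)


def test_patch_order_is_row_major():
    grid = PatchGrid((4, 4), 2)
    img = np.arange(16).reshape(4, 4).astype(float)
    patches = patchify(img, grid)
    # first patch = top-left 2x2 block, second = top-right
    assert patches[0].tolist() == [0, 1, 4, 5]
    assert patches[1].tolist() == [2, 3, 6, 7]


# --------------------------------------------------------------------- mask
@pytest.mark.parametrize("P,ratio,expected", [
    (196, 0.7, 137),
    (64, 0.5, 32),
])
def test_mask_cardinality(P, ratio, expected):
    side = int(np.sqrt(P))
    grid = PatchGrid((side * 8, side * 8), 8)
    plan = sample_mask(grid, ratio, 0)
    assert plan.n_masked == expected


def test_mask_cardinality_over_many_draws():
    grid = PatchGrid((64, 64), 8)
    for ratio in (0.2, 0.5, 0.7, 0.8):
        expected = int(np.floor(ratio * grid.n_patches))
        for seed in range(250):
            assert sample_mask(grid, ratio, seed).n_masked == expected


def test_mask_determinism_and_seed_sensitivity():
    grid = PatchGrid((64, 64), 8)
    a = sample_mask(grid, 0.7, 1).mask
    b = sample_mask(grid, 0.7, 1).mask
    c = sample_mask(grid, 0.7, 2).mask
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_pixel_mask_is_patchwise_upsampling():
    grid = PatchGrid((16, 16), 8)
    plan = sample_mask(grid, 0.5, 3)
    for p_idx in range(grid.n_patches):
        r, c = divmod(p_idx, 2)
        block = plan.pixel_mask[r * 8:(r + 1) * 8, c * 8:(c + 1) * 8]
        assert (block == plan.mask[p_idx]).all()


def test_mask_ratio_bounds_rejected():
    grid = PatchGrid((16, 16), 8)   # P = 4
    with pytest.raises(ValueError):
        sample_mask(grid, 0.1, 0)   # floor(0.4) = 0 masked
    with pytest.raises(ValueError):
        sample_mask(grid, 1.2, 0)


# --------------------------------------------------------------------- loss
def test_loss_zero_at_perfect_reconstruction():
    x = RNG.uniform(size=(8, 8))
    mask = np.ones((8, 8), dtype=bool)
    loss = masked_mse_loss(x, Tensor(x.copy()), mask, 1.0)
    assert float(loss.data) == 0.0


def test_loss_full_mask_limit_is_plain_mse():
    x = np.zeros(2)
    x_hat = Tensor(np.ones(2))
    loss = masked_mse_loss(x, x_hat, np.ones(2, dtype=bool), 1.0)
    assert abs(float(loss.data) - 1.0) < 1e-15


def test_loss_hand_example():
    x = np.array([1.0, 0.0, 0.0, 0.0])
    x_hat = Tensor(np.array([0.0, 0.0, 0.0, 0.5]))
    m = np.array([1, 0, 0, 1], dtype=bool)
    loss = masked_mse_loss(x, x_hat, m, 0.5)
    assert abs(float(loss.data) - 0.625) < 1e-12


def test_loss_ignores_unmasked_pixels_exactly():
    x = RNG.uniform(size=(16, 16))
    grid = PatchGrid((16, 16), 8)
    plan = sample_mask(grid, 0.5, 7)
    x_hat = RNG.uniform(size=(16, 16))
    base = float(masked_mse_loss(x, Tensor(x_hat), plan.pixel_mask,
                                 plan.m_ratio).data)
    perturbed = x_hat + RNG.normal(size=x.shape) * ~plan.pixel_mask
    after = float(masked_mse_loss(x, Tensor(perturbed), plan.pixel_mask,
                                  plan.m_ratio).data)
    assert abs(base - after) < 1e-12


def test_loss_equals_masked_mean_when_ratio_exact():
    """With m_ratio equal to the realized masked fraction the loss is the
    mean squared error over masked pixels (independent direct average)."""
    x = RNG.uniform(size=(16, 16))
    x_hat = RNG.uniform(size=(16, 16))
    grid = PatchGrid((16, 16), 8)
    plan = sample_mask(grid, 0.5, 1)
    ratio_exact = plan.pixel_mask.sum() / plan.pixel_mask.size
    loss = float(masked_mse_loss(x, Tensor(x_hat), plan.pixel_mask,
                                 ratio_exact).data)
    oracle = float(((x_hat - x)[plan.pixel_mask] ** 2).mean())
    assert abs(loss - oracle) < 1e-12


def test_loss_rejects_nonpositive_ratio():
    with pytest.raises(ValueError):
        masked_mse_loss(np.zeros(2), Tensor(np.zeros(2)),
                        np.ones(2, dtype=bool), 0.0)


# ------------------------------------------------------------------- models
def test_paper_presets_match_published_dims():
    v2 = preset("swinv2-paper")
    assert v2.encoder.embed_dim == 96
    assert v2.encoder.depths == (2, 2, 6, 2)
    assert v2.encoder.heads == (3, 6, 12, 24)
    assert v2.decoder_embed == 768
    swin = preset("swin-paper")
    assert swin.encoder.depths == (2, 2, 18, 2)
    assert swin.encoder.heads == (6, 12, 24, 48)
    vit = preset("vit-paper")
    assert vit.encoder.embed_dim == 1024
    assert vit.encoder.depths == (6,) and vit.encoder.heads == (4,)
    assert vit.decoder_embed == 1024
    assert vit.decoder_depths == (4,) and vit.decoder_heads == (4,)


def test_unknown_family_and_preset_rejected():
    with pytest.raises(ValueError, match="family"):
        BackboneSpec("resmlp", 16, (1,), (1,))
    with pytest.raises(KeyError):
        preset("swinv3-tiny")


@pytest.mark.parametrize("name", ["vit-tiny", "swin-tiny", "swinv2-tiny"])
def test_forward_is_deterministic_and_shape_preserving(name):
    cfg = preset(name)
    model = build_mae(cfg, rng_seed=5)
    img = RNG.uniform(size=(64, 64))
    plan = sample_mask(cfg.patch_grid, cfg.mask_ratio, 9)
    out1 = forward_reconstruct(model, img, plan)
    out2 = forward_reconstruct(model, img, plan)
    assert out1.shape == (64, 64)
    assert np.array_equal(out1, out2)
    assert np.isfinite(out1).all()


def test_tiny_forward_fits_interactive_budget():
    cfg = preset("swinv2-tiny")
    model = build_mae(cfg)
    img = RNG.uniform(size=(1, 64, 64))
    plans = sample_masks(cfg.patch_grid, 0.7, 0, 1)
    model.forward(img, plans)                      # warm caches
    t0 = time.perf_counter()
    model.forward(img, plans)
    assert time.perf_counter() - t0 < 1.0


def test_forward_rejects_mismatched_shapes():
    cfg = preset("swinv2-tiny")
    model = build_mae(cfg)
    plan = sample_mask(cfg.patch_grid, 0.7, 0)
    with pytest.raises(ValueError, match="shape"):
        model.forward(RNG.uniform(size=(1, 32, 32)), [plan])


def test_weight_transport_reproduces_outputs(tmp_path):
    cfg = preset("swinv2-tiny")
    model = build_mae(cfg, rng_seed=2)
    img = RNG.uniform(size=(2, 64, 64))
    plans = sample_masks(cfg.patch_grid, 0.7, 4, 2)
    before = model.forward(img, plans).data
    path = save_checkpoint(model, tmp_path / "mae")
    clone = load_checkpoint(path)
    after = clone.forward(img, plans).data
    assert np.array_equal(before, after)


def test_short_training_reduces_masked_loss(domains):
    """A few optimization steps on a small set must lower the masked MSE."""
    from retmae.nn import AdamW
    from retmae.synth import LesionParams, generate_bscan
    cfg = preset("swinv2-tiny")
    model = build_mae(cfg, rng_seed=0)
    images = np.stack([generate_bscan(domains[0], LesionParams("NORMAL"),
                                      500 + i) for i in range(16)])
    plans = sample_masks(cfg.patch_grid, 0.7, 3, 16)
    initial = float(model.loss(images, plans).data)
    opt = AdamW(model, lr=1e-3)
    for _ in range(10):
        loss = model.loss(images, plans)
        model.zero_grad()
        loss.backward()
        opt.step()
    assert float(model.loss(images, plans).data) < initial
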
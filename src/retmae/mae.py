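"""Masked-autoencoder core: patch grids, random masking, the masked
reconstruction loss, and the ViT / Swin / SwinV2 autoencoder architectures.

The self-supervised task: hide a fraction ``m_ratio`` of the image's
``patch_size × patch_size`` patches, replace their embeddings with a shared
learned mask token (dense masking — windowed attention processes the full
token grid, so tokens are substituted rather than dropped), and train the
encoder/decoder to reconstruct the original pixels.  The loss is mean
squared error restricted to masked pixels:

    L = (1 / m_ratio) · (1 / N) · Σ_i (x̂_i − x_i)² · m_i

with N the total pixel count and m_i the pixel-level mask, so that when
``m_ratio`` equals the exact masked fraction the loss is the plain MSE over
masked pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (LayerNorm, Linear, Module, ModuleList, Parameter,
                 PatchExpanding, PatchMerging, SwinBlock, Tensor, ViTBlock,
                 trunc_normal)

__all__ = ["PatchGrid", "MaskPlan", "BackboneSpec", "MAEConfig",
           "patchify", "unpatchify", "sample_mask", "sample_masks",
           "masked_mse_loss", "build_mae", "forward_reconstruct",
           "preset", "PRESETS", "save_checkpoint", "load_checkpoint"]


# --------------------------------------------------------------------- grid
@dataclass(frozen=True)
class PatchGrid:
    """The division of an (H, W) image into square patches."""

    image_size: tuple[int, int]
    patch_size: int = 16

    def __post_init__(self):
        H, W = self.image_size
        if H % self.patch_size or W % self.patch_size:
            raise ValueError(
                f"image {self.image_size} not divisible by patch {self.patch_size}")
        if self.n_patches < 4:
            raise ValueError("grid must contain at least 4 patches")

    @property
    def grid_shape(self) -> tuple[int, int]:
        H, W = self.image_size
        return H // self.patch_size, W // self.patch_size

    @property
    def n_patches(self) -> int:
        gh, gw = self.image_size[0] // self.patch_size, \
            self.image_size[1] // self.patch_size
        return gh * gw


def patchify(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """(H, W) → (P, patch²) in row-major patch order; bit-exact inverse of
    :func:`unpatchify`."""
    H, W = grid.image_size
    if image.shape != (H, W):
        raise ValueError(f"image shape {image.shape} does not match grid")
    p = grid.patch_size
    x = image.reshape(H // p, p, W // p, p)
    return x.transpose(0, 2, 1, 3).reshape(grid.n_patches, p * p)


def unpatchify(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    H, W = grid.image_size
    p = grid.patch_size
    if patches.shape != (grid.n_patches, p * p):
        raise ValueError("patch array does not match grid")
    x = patches.reshape(H // p, W // p, p, p)
    return x.transpose(0, 2, 1, 3).reshape(H, W)


# --------------------------------------------------------------------- mask
@dataclass(frozen=True)
class MaskPlan:
    """A realized random mask: which patches are hidden, and its pixel map."""

    mask: np.ndarray            # bool, (P,), True = masked
    m_ratio: float
    pixel_mask: np.ndarray      # bool, (H, W)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def sample_mask(grid: PatchGrid, mask_ratio: float, rng_seed: int) -> MaskPlan:
    """Choose ``floor(mask_ratio · P)`` patches uniformly without replacement."""
    if not (0.0 < mask_ratio < 1.0):
        raise ValueError("mask_ratio must lie strictly between 0 and 1")
    P = grid.n_patches
    n_masked = int(np.floor(mask_ratio * P))
    if n_masked == 0 or n_masked == P:
        raise ValueError(
            f"mask_ratio {mask_ratio} masks {n_masked} of {P} patches")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(P, size=n_masked, replace=False)
    mask = np.zeros(P, dtype=bool)
    mask[chosen] = True
    gh, gw = grid.grid_shape
    p = grid.patch_size
    pixel = np.repeat(np.repeat(mask.reshape(gh, gw), p, axis=0), p, axis=1)
    return MaskPlan(mask=mask, m_ratio=float(mask_ratio), pixel_mask=pixel)


def sample_masks(grid: PatchGrid, mask_ratio: float, rng_seed: int,
                 n: int) -> list[MaskPlan]:
    """Stream ``n`` fresh masks from one seed (one per image per step)."""
    seeds = np.random.SeedSequence(entropy=int(rng_seed)).generate_state(n)
    return [sample_mask(grid, mask_ratio, int(s)) for s in seeds]


# --------------------------------------------------------------------- loss
def masked_mse_loss(x: Tensor | np.ndarray, x_hat: Tensor,
                    pixel_mask: np.ndarray, m_ratio: float) -> Tensor:
    """Masked reconstruction loss (see module docstring for the formula).

    ``x`` and ``pixel_mask`` are targets/constants; ``x_hat`` carries the
    gradient.  Unmasked pixels contribute exactly zero.
    """
    if m_ratio <= 0:
        raise ValueError("m_ratio must be positive")
    x_arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    mask = np.asarray(pixel_mask, dtype=np.float64)
    if x_arr.shape != x_hat.shape or mask.shape != x_hat.shape:
        raise ValueError("x, x_hat and pixel_mask must share one shape")
    N = x_arr.size
    diff = x_hat - Tensor(x_arr)
    return (diff * diff * Tensor(mask)).sum() * (1.0 / (m_ratio * N))


# ------------------------------------------------------------------ configs
@dataclass(frozen=True)
class BackboneSpec:
    """Declarative encoder description."""

    family: str                       # vit | swin | swinv2
    embed_dim: int
    depths: tuple[int, ...]
    heads: tuple[int, ...]
    window_size: int = 7              # swin families only
    embed_patch: int = 4              # 4 for swin families, 16 for vit

    def __post_init__(self):
        if self.family not in ("vit", "swin", "swinv2"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have equal length")
        if min(self.depths) <= 0 or min(self.heads) <= 0:
            raise ValueError("depths and heads must be positive")

    @property
    def final_dim(self) -> int:
        if self.family == "vit":
            return self.embed_dim
        return self.embed_dim * 2 ** (len(self.depths) - 1)


@dataclass(frozen=True)
class MAEConfig:
    """Full autoencoder description at paper or tiny scale."""

    encoder: BackboneSpec
    decoder_embed: int
    decoder_depths: tuple[int, ...]
    decoder_heads: tuple[int, ...]
    patch_grid: PatchGrid
    mask_ratio: float = 0.7
    scale: str = "paper"

    def __post_init__(self):
        if not (0.0 < self.mask_ratio < 1.0):
            raise ValueError("mask_ratio must lie in (0,1)")
        if self.scale not in ("paper", "tiny"):
            raise ValueError("scale must be 'paper' or 'tiny'")
        if self.patch_grid.patch_size % self.encoder.embed_patch:
            raise ValueError("mask patch must be a multiple of embed patch")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=list, indent=1, sort_keys=True)


def _paper_presets() -> dict[str, MAEConfig]:
    grid224 = PatchGrid((224, 224), 16)
    grid64 = PatchGrid((64, 64), 8)
    return {
        "vit-paper": MAEConfig(
            BackboneSpec("vit", 1024, (6,), (4,), embed_patch=16),
            decoder_embed=1024, decoder_depths=(4,), decoder_heads=(4,),
            patch_grid=grid224),
        "swin-paper": MAEConfig(
            BackboneSpec("swin", 96, (2, 2, 18, 2), (6, 12, 24, 48),
                         window_size=7, embed_patch=4),
            decoder_embed=768, decoder_depths=(18, 2, 2),
            decoder_heads=(24, 12, 6), patch_grid=grid224),
        "swinv2-paper": MAEConfig(
            BackboneSpec("swinv2", 96, (2, 2, 6, 2), (3, 6, 12, 24),
                         window_size=7, embed_patch=4),
            decoder_embed=768, decoder_depths=(6, 2, 2),
            decoder_heads=(12, 6, 3), patch_grid=grid224),
        "vit-tiny": MAEConfig(
            BackboneSpec("vit", 32, (2,), (2,), embed_patch=8),
            decoder_embed=32, decoder_depths=(1,), decoder_heads=(2,),
            patch_grid=grid64, scale="tiny"),
        "swin-tiny": MAEConfig(
            BackboneSpec("swin", 16, (1, 1, 1, 1), (1, 2, 4, 8),
                         window_size=4, embed_patch=4),
            decoder_embed=128, decoder_depths=(1, 1, 1),
            decoder_heads=(4, 2, 1), patch_grid=grid64, scale="tiny"),
        "swinv2-tiny": MAEConfig(
            BackboneSpec("swinv2", 16, (1, 1, 1, 1), (1, 2, 4, 8),
                         window_size=4, embed_patch=4),
            decoder_embed=128, decoder_depths=(1, 1, 1),
            decoder_heads=(4, 2, 1), patch_grid=grid64, scale="tiny"),
    }


PRESETS = _paper_presets()


def preset(name: str, mask_ratio: float | None = None) -> MAEConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if mask_ratio is not None:
        cfg = MAEConfig(cfg.encoder, cfg.decoder_embed, cfg.decoder_depths,
                        cfg.decoder_heads, cfg.patch_grid,
                        mask_ratio=mask_ratio, scale=cfg.scale)
    return cfg


# ------------------------------------------------------------------- models
def _token_mask(plans: list[MaskPlan], grid: PatchGrid,
                embed_patch: int) -> np.ndarray:
    """Upsample patch masks to the embed-token grid → (B, th, tw, 1)."""
    H, W = grid.image_size
    th, tw = H // embed_patch, W // embed_patch
    rep = grid.patch_size // embed_patch
    gh, gw = grid.grid_shape
    out = np.empty((len(plans), th, tw, 1))
    for b, plan in enumerate(plans):
        m = plan.mask.reshape(gh, gw)
        out[b, :, :, 0] = np.repeat(np.repeat(m, rep, axis=0), rep, axis=1)
    return out


class _ViTEncoder(Module):
    def __init__(self, rng, spec: BackboneSpec, grid: PatchGrid):
        p = spec.embed_patch
        H, W = grid.image_size
        self.tokens = (H // p) * (W // p)
        self.embed_grid = PatchGrid(grid.image_size, p)
        self.embed = Linear(rng, p * p, spec.embed_dim)
        self.pos = Parameter(trunc_normal(rng, (self.tokens, spec.embed_dim)))
        self.mask_token = Parameter(trunc_normal(rng, (spec.embed_dim,)))
        self.blocks = ModuleList([ViTBlock(rng, spec.embed_dim, spec.heads[0])
                                  for _ in range(spec.depths[0])])
        self.norm = LayerNorm(spec.embed_dim)

    def forward(self, images: np.ndarray, token_mask: np.ndarray | None) -> Tensor:
        B = images.shape[0]
        patches = np.stack([patchify(im, self.embed_grid) for im in images])
        x = self.embed(Tensor(patches))
        if token_mask is not None:
            m = Tensor(token_mask.reshape(B, self.tokens, 1))
            x = x * (1.0 - m) + self.mask_token * m
        x = x + self.pos
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)                      # (B, L, E)


class _SwinEncoder(Module):
    def __init__(self, rng, spec: BackboneSpec, grid: PatchGrid):
        v2 = spec.family == "swinv2"
        p = spec.embed_patch
        H, W = grid.image_size
        self.grid_hw = (H // p, W // p)
        self.embed_grid = PatchGrid(grid.image_size, p)
        self.embed = Linear(rng, p * p, spec.embed_dim)
        self.mask_token = Parameter(trunc_normal(rng, (spec.embed_dim,)))
        stages, mergers = [], []
        size = self.grid_hw
        dim = spec.embed_dim
        for i, (depth, heads) in enumerate(zip(spec.depths, spec.heads)):
            stages.append(ModuleList([
                SwinBlock(rng, dim, heads, size, spec.window_size,
                          shift=bool(d % 2), v2=v2) for d in range(depth)]))
            if i < len(spec.depths) - 1:
                mergers.append(PatchMerging(rng, dim))
                size = (size[0] // 2, size[1] // 2)
                dim *= 2
        self.stages = ModuleList(stages)
        self.mergers = ModuleList(mergers)
        self.norm = LayerNorm(dim)
        self.final_hw = size
        self.final_dim = dim

    def forward(self, images: np.ndarray, token_mask: np.ndarray | None) -> Tensor:
        B = images.shape[0]
        th, tw = self.grid_hw
        patches = np.stack([patchify(im, self.embed_grid) for im in images])
        x = self.embed(Tensor(patches)).reshape(B, th, tw, -1)
        if token_mask is not None:
            m = Tensor(token_mask)
            x = x * (1.0 - m) + self.mask_token * m
        for i, stage in enumerate(self.stages):
            for blk in stage:
                x = blk(x)
            if i < len(self.mergers):
                x = self.mergers[i](x)
        return self.norm(x)                      # (B, h, w, C_final)


class MAEModel(Module):
    """Encoder + reconstruction decoder; the opaque model handle."""

    def __init__(self, config: MAEConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        spec = config.encoder
        grid = config.patch_grid
        if spec.family == "vit":
            self.encoder = _ViTEncoder(rng, spec, grid)
            D = config.decoder_embed
            self.dec_embed = Linear(rng, spec.embed_dim, D)
            self.dec_pos = Parameter(trunc_normal(rng, (self.encoder.tokens, D)))
            self.dec_blocks = ModuleList([
                ViTBlock(rng, D, config.decoder_heads[0])
                for _ in range(config.decoder_depths[0])])
            self.dec_norm = LayerNorm(D)
            p = spec.embed_patch
            self.dec_out = Linear(rng, D, p * p)
        else:
            self.encoder = _SwinEncoder(rng, spec, grid)
            v2 = spec.family == "swinv2"
            D = config.decoder_embed
            self.dec_embed = Linear(rng, self.encoder.final_dim, D)
            ups, dec_stages = [], []
            size = self.encoder.final_hw
            dim = D
            for depth, heads in zip(config.decoder_depths, config.decoder_heads):
                ups.append(PatchExpanding(rng, dim))
                size = (size[0] * 2, size[1] * 2)
                dim //= 2
                dec_stages.append(ModuleList([
                    SwinBlock(rng, dim, heads, size, spec.window_size,
                              shift=bool(d % 2), v2=v2) for d in range(depth)]))
            self.dec_ups = ModuleList(ups)
            self.dec_stages = ModuleList(dec_stages)
            self.dec_norm = LayerNorm(dim)
            p = spec.embed_patch
            if size != self.encoder.grid_hw:
                raise ValueError("decoder stages do not restore the token grid")
            self.dec_out = Linear(rng, dim, p * p)

    # ------------------------------------------------------------- plumbing
    def encode(self, images: np.ndarray,
               plans: list[MaskPlan] | None = None) -> Tensor:
        """Images → pooled feature vectors (B, final_dim)."""
        token_mask = None
        if plans is not None:
            token_mask = _token_mask(plans, self.config.patch_grid,
                                     self.config.encoder.embed_patch)
        feats = self.encoder(images, token_mask)
        if feats.ndim == 4:      # swin grid → pool over space
            B = feats.shape[0]
            feats = feats.reshape(B, -1, feats.shape[-1])
        return feats.mean(axis=1)

    def forward(self, images: np.ndarray, plans: list[MaskPlan]) -> Tensor:
        """(B, H, W) images + per-image masks → (B, H, W) reconstruction."""
        H, W = self.config.patch_grid.image_size
        if images.ndim != 3 or images.shape[1:] != (H, W):
            raise ValueError(
                f"images shape {images.shape} does not match config grid")
        if len(plans) != images.shape[0]:
            raise ValueError("need one MaskPlan per image")
        B = images.shape[0]
        spec = self.config.encoder
        token_mask = _token_mask(plans, self.config.patch_grid, spec.embed_patch)
        feats = self.encoder(images, token_mask)
        p = spec.embed_patch
        th, tw = H // p, W // p
        if spec.family == "vit":
            x = self.dec_embed(feats) + self.dec_pos
            for blk in self.dec_blocks:
                x = blk(x)
            x = self.dec_out(self.dec_norm(x))           # (B, L, p²)
        else:
            x = self.dec_embed(feats)
            for up, stage in zip(self.dec_ups, self.dec_stages):
                x = up(x)
                for blk in stage:
                    x = blk(x)
            x = self.dec_out(self.dec_norm(x))           # (B, th, tw, p²)
            x = x.reshape(B, th * tw, p * p)
        # row-major tokens → image
        x = x.reshape(B, th, tw, p, p).transpose(0, 1, 3, 2, 4).reshape(B, H, W)
        return x

    def loss(self, images: np.ndarray, plans: list[MaskPlan]) -> Tensor:
        recon = self.forward(images, plans)
        pixel = np.stack([pl.pixel_mask for pl in plans])
        return masked_mse_loss(images, recon, pixel, plans[0].m_ratio)


def build_mae(config: MAEConfig, rng_seed: int = 0) -> MAEModel:
    """Construct an autoencoder; weight names are stable across runs."""
    return MAEModel(config, rng_seed=rng_seed)


def forward_reconstruct(model: MAEModel, image: np.ndarray,
                        plan: MaskPlan) -> np.ndarray:
    """Single-image convenience wrapper returning a plain array."""
    out = model.forward(image[None], [plan])
    return out.data[0]


# -------------------------------------------------------------- checkpoints
def save_checkpoint(model: MAEModel, path: str | Path,
                    provenance: dict | None = None) -> Path:
    """Named-tensor archive (.npz) with a JSON sidecar describing the config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"config": json.loads(model.config.to_json()),
               "provenance": provenance or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _config_from_dict(d: dict) -> MAEConfig:
    enc = d["encoder"]
    return MAEConfig(
        BackboneSpec(enc["family"], enc["embed_dim"], tuple(enc["depths"]),
                     tuple(enc["heads"]), enc["window_size"],
                     enc["embed_patch"]),
        decoder_embed=d["decoder_embed"],
        decoder_depths=tuple(d["decoder_depths"]),
        decoder_heads=tuple(d["decoder_heads"]),
        patch_grid=PatchGrid(tuple(d["patch_grid"]["image_size"]),
                             d["patch_grid"]["patch_size"]),
        mask_ratio=d["mask_ratio"], scale=d["scale"])


def load_checkpoint(path: str | Path) -> MAEModel:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    model = MAEModel(_config_from_dict(sidecar["config"]))
    with np.load(path) as archive:
        model.load_state_dict(dict(archive))
    return model
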
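"""Synthetic multi-source retinal OCT B-scan generator.

Real OCT B-scans show a stack of smooth, roughly horizontal reflective
bands (the retinal layers), multiplicative speckle noise, device-dependent
blur and intensity calibration, and — in disease — focal deformations:
drusen appear as dome-shaped bumps under the outer bands (the early-AMD
signature used here), neovascular lesions as larger irregular elevations,
and macular edema as dark intraretinal fluid pockets.

The generator reproduces exactly those elements: layered bands with gently
undulating boundaries, log-normal multiplicative speckle, Gaussian blur and
an affine gain/offset per simulated device.  Distinct ``DomainParams``
presets stand in for different acquisition sites, giving a controllable
domain gap; everything is deterministic given a seed.

Class conventions: ``NORMAL`` and ``AMD`` are the binary classification
targets; ``CNV_LIKE`` and ``DME_LIKE`` exist so that label-free
pre-training can see a wider morphology spectrum than the supervised stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASS_LABELS = ("NORMAL", "AMD", "CNV_LIKE", "DME_LIKE")

MANIFEST_COLUMNS = ["image_path", "source_id", "subject_id", "class_label", "split"]

#: hard cap on images per generated source, guarding accidental huge runs
MAX_IMAGES_PER_SOURCE = 100_000


@dataclass(frozen=True)
class DomainParams:
    """Acquisition-site parameters controlling appearance, not pathology."""

    source_id: str
    image_size: tuple[int, int] = (64, 64)
    n_layers: int = 5
    layer_contrast: tuple[float, ...] = (0.65, 0.35, 0.8, 0.45, 0.9)
    speckle_sigma: float = 0.15
    blur_sigma: float = 0.7
    intensity_gain: float = 1.0
    intensity_offset: float = 0.0
    background_level: float = 0.08

    def __post_init__(self):
        H, W = self.image_size
        if H <= 0 or W <= 0:
            raise ValueError("image_size must be positive")
        if len(self.layer_contrast) != self.n_layers:
            raise ValueError("layer_contrast must have n_layers entries")
        if any(not (0.0 <= c <= 1.0) for c in self.layer_contrast):
            raise ValueError("layer_contrast values must lie in [0,1]")
        for name in ("speckle_sigma", "blur_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0,1]")


@dataclass(frozen=True)
class LesionParams:
    """Pathology parameters; geometry is in pixels of the target image."""

    class_label: str = "NORMAL"
    n_bumps: int = 0
    bump_amplitude: float = 6.0
    bump_width: float = 5.0
    fluid_pocket: bool = False
    pocket_size: float = 8.0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.class_label == "NORMAL" and (self.n_bumps or self.fluid_pocket):
            raise ValueError("NORMAL lesions must have n_bumps=0 and no pocket")
        if self.n_bumps < 0:
            raise ValueError("n_bumps must be >= 0")
        if self.n_bumps and (self.bump_amplitude <= 0 or self.bump_width <= 0):
            raise ValueError("bump amplitude/width must be positive")
        if self.fluid_pocket and self.pocket_size <= 0:
            raise ValueError("pocket_size must be positive")


def default_lesion(class_label: str, rng: np.random.Generator,
                   image_height: int) -> LesionParams:
    """Draw realistic lesion geometry for a class, scaled to the image."""
    s = image_height / 64.0
    if class_label == "NORMAL":
        return LesionParams("NORMAL")
    if class_label == "AMD":
        return LesionParams("AMD",
                            n_bumps=int(rng.integers(1, 4)),
                            bump_amplitude=float(rng.uniform(4, 8)) * s,
                            bump_width=float(rng.uniform(3.5, 6.5)) * s)
    if class_label == "CNV_LIKE":
        return LesionParams("CNV_LIKE",
                            n_bumps=int(rng.integers(1, 3)),
                            bump_amplitude=float(rng.uniform(8, 14)) * s,
                            bump_width=float(rng.uniform(7, 11)) * s)
    return LesionParams("DME_LIKE", fluid_pocket=True,
                        pocket_size=float(rng.uniform(6, 12)) * s)


# -------------------------------------------------------------------- render
def _band_boundaries(domain: DomainParams, rng: np.random.Generator) -> np.ndarray:
    """(n_layers+1, W) row positions of smooth band boundaries."""
    H, W = domain.image_size
    top = 0.18 * H + rng.uniform(-0.03, 0.03) * H
    bottom = 0.82 * H + rng.uniform(-0.03, 0.03) * H
    base = np.linspace(top, bottom, domain.n_layers + 1)[:, None]
    x = np.linspace(0, 2 * np.pi, W)[None, :]
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.01, 0.035) * H
    undulation = amp * np.sin(x + phase) + 0.4 * amp * np.sin(2 * x + phase / 2)
    return base + undulation


def _render(domain: DomainParams, lesion: LesionParams, rng_seed: int,
            min_patch: int = 8):
    """Render one B-scan; returns (image float64 in [0,1], metadata dict).

    The base anatomy is drawn from a sub-stream that does not depend on the
    lesion, so a seed-matched NORMAL render shares its geometry and noise
    with the diseased render — the lesion is the only difference.
    """
    H, W = domain.image_size
    if H < 2 * min_patch or W < 2 * min_patch:
        raise ValueError(
            f"image_size {domain.image_size} smaller than 2x patch size {min_patch}")
    ss = np.random.SeedSequence(entropy=int(rng_seed))
    anatomy_rng, lesion_rng, noise_rng = (
        np.random.default_rng(c) for c in ss.spawn(3))

    bounds = _band_boundaries(domain, anatomy_rng)
    meta: dict = {"bump_boxes": []}

    # lesion geometry deforms the outer (last) boundary upward
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    outer = bounds[-2].copy()           # outer reflective band's upper edge
    if lesion.n_bumps:
        centers = lesion_rng.choice(
            np.arange(int(0.15 * W), int(0.85 * W)),
            size=lesion.n_bumps, replace=False)
        for c in np.sort(centers):
            bump = lesion.bump_amplitude * np.exp(
                -0.5 * ((np.arange(W) - c) / lesion.bump_width) ** 2)
            outer = outer - bump        # rows grow downward; bump lifts edge
            half = int(np.ceil(2 * lesion.bump_width))
            r0 = int(max(0, bounds[-2, c] - lesion.bump_amplitude - 2))
            r1 = int(min(H, bounds[-1, c] + 2))
            meta["bump_boxes"].append(
                (r0, r1, max(0, int(c) - half), min(W, int(c) + half + 1)))
    deformed = bounds.copy()
    deformed[-2] = outer

    img = np.full((H, W), domain.background_level)
    for i in range(domain.n_layers):
        band = (rows >= deformed[i][None, :]) & (rows < deformed[i + 1][None, :])
        img[band] = domain.layer_contrast[i]

    if lesion.fluid_pocket:
        cy = float(np.mean(bounds[1:3, W // 2]))
        cx = lesion_rng.uniform(0.3 * W, 0.7 * W)
        ry = lesion.pocket_size / 2.0
        rx = lesion.pocket_size
        pocket = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        img[pocket] = 0.05
        meta["pocket_center"] = (cy, cx)

    if domain.blur_sigma > 0:
        img = gaussian_filter(img, domain.blur_sigma)
    if domain.speckle_sigma > 0:
        speckle = np.exp(noise_rng.normal(
            -0.5 * domain.speckle_sigma ** 2, domain.speckle_sigma, size=(H, W)))
        img = img * speckle
    img = domain.intensity_gain * img + domain.intensity_offset
    return np.clip(img, 0.0, 1.0), meta


def generate_bscan(domain: DomainParams, lesion: LesionParams, rng_seed: int,
                   min_patch: int = 8) -> np.ndarray:
    """Render one grayscale B-scan, values in [0,1], deterministic per seed."""
    img, _ = _render(domain, lesion, rng_seed, min_patch=min_patch)
    return img


def generate_bscan_with_meta(domain: DomainParams, lesion: LesionParams,
                             rng_seed: int, min_patch: int = 8):
    """As :func:`generate_bscan` but also return lesion geometry metadata."""
    return _render(domain, lesion, rng_seed, min_patch=min_patch)


# ------------------------------------------------------------------- sources
def _class_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n subjects over the class mix."""
    labels = list(class_mix)
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    for lab in labels:
        if lab not in CLASS_LABELS:
            raise ValueError(f"unknown class {lab!r}")
    quotas = {lab: n * class_mix[lab] for lab in labels}
    counts = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(labels, key=lambda l: (quotas[l] - counts[l], l),
                          reverse=True)
    for lab in by_remainder[:short]:
        counts[lab] += 1
    return counts


def generate_source(domain: DomainParams, n_subjects: int,
                    scans_per_subject: int, class_mix: dict[str, float],
                    rng_seed: int):
    """Generate one simulated acquisition site.

    Every subject receives a single class label (all of a subject's scans
    share it, mirroring subject-grouped clinical datasets) and
    ``scans_per_subject`` independently rendered B-scans.

    Returns ``(images, manifest)`` where ``images`` maps image_id to a
    float array and ``manifest`` is a DataFrame with the standard columns
    (split left empty).
    """
    if n_subjects <= 0 or scans_per_subject <= 0:
        raise ValueError("counts must be positive")
    total = n_subjects * scans_per_subject
    if total > MAX_IMAGES_PER_SOURCE:
        raise ValueError(
            f"{total} scans exceed the per-source cap {MAX_IMAGES_PER_SOURCE}")
    counts = _class_counts(n_subjects, class_mix)
    subject_classes: list[str] = []
    for lab in sorted(counts):
        subject_classes.extend([lab] * counts[lab])
    # deterministic interleave so per-subject class order is seed-stable
    order_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(rng_seed), spawn_key=(0,)).generate_state(4))
    order = order_rng.permutation(n_subjects)
    subject_classes = [subject_classes[i] for i in order]

    images: dict[str, np.ndarray] = {}
    rows = []
    H, _ = domain.image_size
    for s_idx, lab in enumerate(subject_classes):
        subject_id = f"{domain.source_id}_s{s_idx:03d}"
        for k in range(scans_per_subject):
            scan_seed = np.random.SeedSequence(
                entropy=int(rng_seed), spawn_key=(1, s_idx, k))
            lesion_rng = np.random.default_rng(scan_seed.generate_state(4))
            lesion = default_lesion(lab, lesion_rng, H)
            render_seed = int(scan_seed.generate_state(1, dtype=np.uint32)[0])
            img = generate_bscan(domain, lesion, render_seed)
            image_id = f"{subject_id}_i{k:03d}"
            images[image_id] = img
            rows.append({
                "image_path": f"{domain.source_id}/{image_id}.png",
                "source_id": domain.source_id,
                "subject_id": subject_id,
                "class_label": lab,
                "split": "",
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return images, manifest


# --------------------------------------------------------- multi-source kits
def default_domains(image_size: tuple[int, int] = (64, 64)) -> list[DomainParams]:
    """Three acquisition-site presets with a deliberate domain gap.

    The sites differ in contrast calibration (gain/offset), speckle level
    and optical blur — the appearance axes along which clinical OCT
    datasets from different devices differ.
    """
    return [
        DomainParams("srcA", image_size=image_size, speckle_sigma=0.15,
                     blur_sigma=0.7, intensity_gain=1.0, intensity_offset=0.0),
        DomainParams("srcB", image_size=image_size, speckle_sigma=0.25,
                     blur_sigma=1.1, intensity_gain=0.8,
                     intensity_offset=0.10, background_level=0.12),
        DomainParams("srcC", image_size=image_size, speckle_sigma=0.10,
                     blur_sigma=0.5, intensity_gain=1.15,
                     intensity_offset=-0.05, background_level=0.05),
    ]


#: default class imbalance for supervised-stage sources (NORMAL ≫ AMD)
BINARY_MIX = {"NORMAL": 0.8, "AMD": 0.2}
#: pre-training sources additionally carry the non-binary lesion classes
PRETRAIN_MIX = {"NORMAL": 0.6, "AMD": 0.2, "CNV_LIKE": 0.1, "DME_LIKE": 0.1}


# ---------------------------------------------------------------------- I/O
def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def write_source(out_dir: str | Path, images: dict[str, np.ndarray],
                 manifest: pd.DataFrame) -> Path:
    """Write 8-bit grayscale PNGs plus the manifest CSV; returns CSV path."""
    out_dir = Path(out_dir)
    for image_id, img in images.items():
        row = manifest.loc[manifest.image_path.str.contains(image_id)].iloc[0]
        path = out_dir / row.image_path
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(to_uint8(img), mode="L").save(path)
    source = manifest.source_id.iloc[0]
    csv_path = out_dir / f"manifest_{source}.csv"
    manifest.to_csv(csv_path, index=False)
    return csv_path


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image back to floats in [0,1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0
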
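"""Synthetic fundus phantoms with paired disc/cup ground truth.

A phantom emulates the structural layout of a disc-centred fundus
photograph: a circular field of view with radial illumination fall-off over
a warm background, dark curved vessels converging near the disc, a bright
soft-edged elliptical optic disc, and a brighter interior cup whose relative
size is the cup-to-disc ratio (CDR, defined here as sqrt(cup area / disc
area), the quantity clinicians estimate).  Domain presets apply global
colour casts, contrast/brightness shifts, noise levels and disc-size
distributions so that train/test distribution shifts can be simulated
without any real data.

These phantoms are *not* photorealistic (no pathology, no vessel trees, no
camera optics); they exist so the full pipeline — detection, cropping,
training, evaluation, restoration — is exercisable and measurable on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class PhantomSpec:
    image_size: int = 512
    fov_radius_frac: float = 0.95
    disc_center: tuple[float, float] | None = None  # (row, col); None = centred
    disc_center_jitter: float = 30.0
    disc_radii: tuple[float, float] = (55.0, 48.0)  # (a, b) pixels
    cup_to_disc_ratio: float = 0.5
    background_color: tuple[float, float, float] = (0.66, 0.32, 0.10)
    disc_color: tuple[float, float, float] = (0.95, 0.78, 0.42)
    cup_color: tuple[float, float, float] = (1.00, 0.92, 0.62)
    boundary_softness: float = 2.0
    vessel_count: int = 4
    vessel_darkness: float = 0.35
    vessel_width: float = 3.0
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if not 0.0 < self.cup_to_disc_ratio < 1.0:
            raise ValueError("cup_to_disc_ratio must lie strictly in (0, 1)")
        a, b = self.disc_radii
        fov = self.fov_radius_frac * self.image_size / 2
        if max(a, b) >= fov:
            raise ValueError("disc ellipse must lie inside the field of view")
        if min(a, b) <= 2:
            raise ValueError("disc radii too small to rasterize")
        return self


@dataclass
class DomainPreset:
    name: str
    color_cast: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast: float = 1.0
    brightness: float = 0.0
    noise_sigma: float = 0.02
    disc_radius_range: tuple[float, float] = (40.0, 70.0)
    cdr_range: tuple[float, float] = (0.3, 0.7)


#: Four appearance domains, mutually distinct in colour cast, contrast,
#: brightness, noise and disc-size distribution.
DOMAIN_PRESETS = {
    "D1": DomainPreset("D1"),
    "D2": DomainPreset("D2", color_cast=(1.10, 0.85, 0.75), contrast=1.15,
                       noise_sigma=0.035, disc_radius_range=(55.0, 80.0)),
    "D3": DomainPreset("D3", color_cast=(0.85, 1.05, 1.25), contrast=0.85,
                       brightness=0.08, disc_radius_range=(35.0, 55.0),
                       cdr_range=(0.35, 0.75)),
    "D4": DomainPreset("D4", color_cast=(0.95, 1.15, 0.80), contrast=1.0,
                       brightness=-0.07, noise_sigma=0.05,
                       disc_radius_range=(45.0, 60.0), cdr_range=(0.25, 0.55)),
}


def _ellipse_dist(rows, cols, center, radii):
    """Normalized elliptical radius: 1 on the ellipse boundary."""
    return np.sqrt(((rows - center[0]) / radii[0]) ** 2
                   + ((cols - center[1]) / radii[1]) ** 2)


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.  Returns (image H×W×3 float in [0,1], mask H×W
    int with 0=background 1=disc-rim 2=cup, metadata dict).

    Deterministic for a given spec (all randomness from ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    half = n / 2.0
    fov_r = spec.fov_radius_frac * half
    r_center = np.hypot(rows - half, cols - half)
    fov = r_center <= fov_r

    if spec.disc_center is None:
        jit = rng.uniform(-spec.disc_center_jitter, spec.disc_center_jitter, size=2)
        center = (half + jit[0], half + jit[1])
    else:
        center = spec.disc_center
    a, b = spec.disc_radii
    margin = max(a, b) + 3
    center = (float(np.clip(center[0], margin, n - margin)),
              float(np.clip(center[1], margin, n - margin)))

    # background with radial illumination fall-off
    falloff = 1.0 - 0.35 * (r_center / fov_r) ** 2
    img = np.zeros((n, n, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = spec.background_color[c] * falloff
    img[~fov] = 0.0

    # vessels: quadratic Bézier strokes radiating from near the disc centre
    yy, xx = rows, cols
    for _ in range(spec.vessel_count):
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.5, 1.0) * fov_r
        p0 = np.array(center) + rng.normal(0, 5, 2)
        p2 = p0 + length * np.array([np.sin(theta), np.cos(theta)])
        bend = rng.normal(0, 0.25 * length, 2)
        p1 = 0.5 * (p0 + p2) + bend
        t = np.linspace(0, 1, 160)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        width = spec.vessel_width * rng.uniform(0.7, 1.3)
        dark = np.zeros((n, n))
        r0 = np.clip(pts[:, 0], 0, n - 1)
        c0 = np.clip(pts[:, 1], 0, n - 1)
        for pr, pc in zip(r0, c0):
            lo_r, hi_r = int(max(pr - 3 * width, 0)), int(min(pr + 3 * width + 1, n))
            lo_c, hi_c = int(max(pc - 3 * width, 0)), int(min(pc + 3 * width + 1, n))
            d2 = ((yy[lo_r:hi_r, lo_c:hi_c] - pr) ** 2
                  + (xx[lo_r:hi_r, lo_c:hi_c] - pc) ** 2)
            np.maximum(dark[lo_r:hi_r, lo_c:hi_c],
                       np.exp(-d2 / (2 * width ** 2)), out=dark[lo_r:hi_r, lo_c:hi_c])
        img *= (1.0 - spec.vessel_darkness * dark * fov)[..., None]

    # disc and cup (soft edges in the image; exact ellipses in the mask)
    cdr = spec.cup_to_disc_ratio
    cup_radii = (cdr * a, cdr * b)
    d_disc = _ellipse_dist(rows, cols, center, (a, b))
    d_cup = _ellipse_dist(rows, cols, center, cup_radii)
    soft_d = spec.boundary_softness / min(a, b)
    disc_w = np.clip((1.0 - d_disc) / max(soft_d, 1e-6), 0, 1)
    cup_w = np.clip((1.0 - d_cup) / max(soft_d, 1e-6), 0, 1)
    for c in range(3):
        img[..., c] = img[..., c] * (1 - disc_w) + spec.disc_color[c] * disc_w
        img[..., c] = img[..., c] * (1 - cup_w) + spec.cup_color[c] * cup_w

    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    mask = np.zeros((n, n), dtype=np.uint8)
    mask[d_disc <= 1.0] = 1
    mask[d_cup <= 1.0] = 2

    metadata = {
        "disc_center": [center[0], center[1]],
        "disc_radii": [a, b],
        "cup_radii": [cup_radii[0], cup_radii[1]],
        "cup_to_disc_ratio": cdr,
        "seed": spec.seed,
    }
    return img.astype(np.float32), mask, metadata


def measured_cdr(mask: np.ndarray) -> float:
    """sqrt(cup area / disc area) from a rendered label mask."""
    cup = np.count_nonzero(mask == 2)
    disc = np.count_nonzero(mask >= 1)
    return float(np.sqrt(cup / disc)) if disc else 0.0


def sample_spec(preset: DomainPreset, rng: np.random.Generator,
                image_size: int = 512, seed: int | None = None) -> PhantomSpec:
    """Draw one phantom spec from a domain preset's distributions.

    Preset disc-radius ranges are stated for a 512-pixel frame and scale
    linearly with ``image_size``.
    """
    scale = image_size / 512.0
    a = rng.uniform(*preset.disc_radius_range) * scale
    b = a * rng.uniform(0.8, 1.0)
    cast = preset.color_cast
    base = np.array([0.66, 0.32, 0.10]) * cast
    disc = np.clip(np.array([0.95, 0.78, 0.42]) * cast * preset.contrast
                   + preset.brightness, 0, 1)
    cup = np.clip(np.array([1.0, 0.92, 0.62]) * cast * preset.contrast
                  + preset.brightness, 0, 1)
    return PhantomSpec(
        image_size=image_size,
        disc_center_jitter=30.0 * scale,
        vessel_width=max(3.0 * scale, 1.0),
        disc_radii=(a, b),
        cup_to_disc_ratio=rng.uniform(*preset.cdr_range),
        background_color=tuple(np.clip(base * preset.contrast + preset.brightness, 0, 1)),
        disc_color=tuple(disc),
        cup_color=tuple(cup),
        vessel_count=int(rng.integers(3, 7)),
        noise_sigma=preset.noise_sigma,
        seed=int(rng.integers(0, 2 ** 31 - 1)) if seed is None else seed,
    )


def generate_domain_dataset(n: int, preset: DomainPreset | str, seed: int,
                            out_dir, image_size: int = 512,
                            crop_size: int = 320) -> Path:
    """Write n image/mask PNG pairs, per-image metadata JSON and a manifest.

    The manifest CSV (image_path, mask_path, split, crop_size) assigns every
    fifth phantom to validation (a 4:1 train/validation split).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(preset, str):
        preset = DOMAIN_PRESETS[preset]
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        spec = sample_spec(preset, rng, image_size=image_size)
        img, mask, meta = generate_phantom(spec)
        img_path = out_dir / "images" / f"{preset.name}_{i:04d}.png"
        mask_path = out_dir / "masks" / f"{preset.name}_{i:04d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray(mask).save(mask_path)
        meta["preset"] = preset.name
        with open(out_dir / "masks" / f"{preset.name}_{i:04d}.json", "w") as fh:
            json.dump(meta, fh)
        rows.append({
            "image_path": str(img_path.relative_to(out_dir)),
            "mask_path": str(mask_path.relative_to(out_dir)),
            "split": "val" if i % 5 == 4 else "train",
            "crop_size": crop_size,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def display_mask(mask: np.ndarray) -> np.ndarray:
    """Raw labels {0,1,2} → display values {0,128,255}."""
    return (np.asarray(mask) * 127.5).round().astype(np.uint8)
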
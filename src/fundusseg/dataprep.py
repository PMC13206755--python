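"""Disc-centred preprocessing and exact restoration to original coordinates.

Pipeline used by the published experiments: locate the optic-disc centre
from a coarse segmentation (area + circularity checks, then the minimum
enclosing circle of the surviving component), crop a fixed window centred on
it (800² canonically; clipped at borders and zero-padded), resize to the
network input size with pixel-area resampling, augment, and z-score
normalize per channel.  Predictions are carried back by bicubically
upsampling the class planes to the crop size, re-taking the argmax, and
pasting the unpadded window into a background canvas of the original size —
the ``CropRecord`` stores everything needed to make this restoration exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import MultiPoint
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .nn.resize import resize_area_np, resize_bicubic_np, resize_nearest_np


# ---------------------------------------------------------------------------
# crop geometry
# ---------------------------------------------------------------------------

@dataclass
class CropRecord:
    original_height: int
    original_width: int
    od_center: tuple[int, int]          # (row, col) in original coordinates
    crop_size: int = 800
    input_size: int = 256
    # filled by crop_and_resize:
    row0: int = 0                       # top-left of the (unclipped) window
    col0: int = 0
    pad_top: int = 0
    pad_bottom: int = 0
    pad_left: int = 0
    pad_right: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["od_center"] = list(self.od_center)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CropRecord":
        d = json.loads(s)
        d["od_center"] = tuple(d["od_center"])
        return cls(**d)


# ---------------------------------------------------------------------------
# OD centre detection from a coarse mask
# ---------------------------------------------------------------------------

def locate_od_center(coarse_mask: np.ndarray,
                     min_area_frac: float = 0.0005,
                     max_area_frac: float = 0.15,
                     min_circularity: float = 0.5) -> tuple[int, int]:
    """Centre (row, col) of the optic disc in a coarse binary segmentation.

    Connected components are filtered by relative area and circularity
    (4πA/P²); the largest survivor's minimum enclosing circle gives the
    centre.  Raises if nothing survives (callers may fall back to the image
    centre).
    """
    coarse_mask = np.asarray(coarse_mask).astype(bool)
    image_area = coarse_mask.size
    labeled = cc_label(coarse_mask, connectivity=2)
    survivors = []
    for region in regionprops(labeled):
        frac = region.area / image_area
        if not (min_area_frac <= frac <= max_area_frac):
            continue
        perim = region.perimeter
        circularity = 4 * np.pi * region.area / perim ** 2 if perim > 0 else 1.0
        if circularity < min_circularity:
            continue
        survivors.append(region)
    if not survivors:
        raise ValueError(
            "no disc-like component passed the area/circularity checks; "
            "fall back to the image centre"
        )
    best = max(survivors, key=lambda r: r.area)
    component = labeled == best.label
    boundary = component & ~ndi.binary_erosion(component, border_value=0)
    pts = np.argwhere(boundary)
    circle = shapely.minimum_bounding_circle(MultiPoint(pts[:, ::-1]))  # (x=col, y=row)
    cx, cy = circle.centroid.x, circle.centroid.y
    return int(round(cy)), int(round(cx))


# ---------------------------------------------------------------------------
# crop / resize / restore
# ---------------------------------------------------------------------------

def crop_and_resize(image: np.ndarray, mask: np.ndarray | None,
                    record: CropRecord):
    """Crop the window centred on the OD and resize to the input size.

    The image is resized with pixel-area resampling, the mask with nearest
    neighbour (labels preserved).  Returns (image, mask, updated record).
    """
    h, w = image.shape[:2]
    if not (0 <= record.od_center[0] < h and 0 <= record.od_center[1] < w):
        raise ValueError(f"OD centre {record.od_center} outside image {h}×{w}")
    cs = record.crop_size
    r0 = record.od_center[0] - cs // 2
    c0 = record.od_center[1] - cs // 2
    r1, c1 = r0 + cs, c0 + cs
    pad_top, pad_left = max(0, -r0), max(0, -c0)
    pad_bottom, pad_right = max(0, r1 - h), max(0, c1 - w)

    canvas = np.zeros((cs, cs) + image.shape[2:], dtype=np.float64)
    src = image[r0 + pad_top:r1 - pad_bottom, c0 + pad_left:c1 - pad_right]
    if np.issubdtype(src.dtype, np.integer):
        src = src / 255.0
    canvas[pad_top:cs - pad_bottom, pad_left:cs - pad_right] = src
    out_img = resize_area_np(canvas, record.input_size).astype(np.float32)

    out_mask = None
    if mask is not None:
        mcanvas = np.zeros((cs, cs), dtype=mask.dtype)
        mcanvas[pad_top:cs - pad_bottom, pad_left:cs - pad_right] = (
            mask[r0 + pad_top:r1 - pad_bottom, c0 + pad_left:c1 - pad_right]
        )
        out_mask = resize_nearest_np(mcanvas, record.input_size)

    new_record = dataclasses.replace(
        record, original_height=h, original_width=w, row0=r0, col0=c0,
        pad_top=pad_top, pad_bottom=pad_bottom, pad_left=pad_left,
        pad_right=pad_right,
    )
    return out_img, out_mask, new_record


def restore_to_original(pred: np.ndarray, record: CropRecord,
                        num_classes: int | None = None) -> np.ndarray:
    """Restore a prediction at input size to original-image coordinates.

    Accepts either class-probability planes (K, s, s) or an integer label
    mask (s, s) — labels are one-hot expanded so that interpolation happens
    on probability planes and the restored mask stays a valid label map.
    """
    pred = np.asarray(pred)
    if pred.ndim == 2:
        k = int(num_classes if num_classes is not None else pred.max() + 1)
        k = max(k, 2)
        planes = np.zeros((k,) + pred.shape, dtype=np.float32)
        for c in range(k):
            planes[c] = pred == c
    elif pred.ndim == 3:
        planes = pred.astype(np.float32)
    else:
        raise ValueError("pred must be (s,s) labels or (K,s,s) probabilities")
    if planes.shape[1] != record.input_size:
        raise ValueError(
            f"prediction side {planes.shape[1]} does not match record input "
            f"size {record.input_size}"
        )
    cs = record.crop_size
    up = resize_bicubic_np(planes, cs, cs)
    crop_labels = np.argmax(up, axis=0).astype(np.uint8)
    content = crop_labels[record.pad_top:cs - record.pad_bottom,
                          record.pad_left:cs - record.pad_right]
    out = np.zeros((record.original_height, record.original_width), dtype=np.uint8)
    out[record.row0 + record.pad_top:record.row0 + cs - record.pad_bottom,
        record.col0 + record.pad_left:record.col0 + cs - record.pad_right] = content
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Per-channel z-score: subtract the channel mean, divide by std + 1e-8."""
    image = np.asarray(image, dtype=np.float64)
    axes = (0, 1) if image.ndim == 3 else None
    mu = image.mean(axis=axes, keepdims=image.ndim == 3)
    sd = image.std(axis=axes, keepdims=image.ndim == 3)
    return ((image - mu) / (sd + 1e-8)).astype(np.float32)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationStrategy:
    """Named augmentation recipes.

    ``spatial`` applies rotation and flips; ``designed`` adds the five
    photometric transforms (the spatial set is a subset of the designed
    set).  Probabilities and ranges are configuration, not claims about the
    published training runs.
    """

    name: str
    rotation_prob: float = 0.0
    rotation_deg: float = 30.0
    vflip_prob: float = 0.0
    hflip_prob: float = 0.0
    blur_prob: float = 0.0
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    noise_prob: float = 0.0
    noise_sigma_max: float = 0.05
    brightness_prob: float = 0.0
    brightness_delta: float = 0.1
    contrast_prob: float = 0.0
    contrast_range: tuple[float, float] = (0.75, 1.25)
    gamma_prob: float = 0.0
    gamma_range: tuple[float, float] = (0.7, 1.5)

    @classmethod
    def named(cls, name: str) -> "AugmentationStrategy":
        if name == "none":
            return cls(name="none")
        if name == "spatial":
            return cls(name="spatial", rotation_prob=0.5, vflip_prob=0.5,
                       hflip_prob=0.5)
        if name == "designed":
            return cls(name="designed", rotation_prob=0.5, vflip_prob=0.5,
                       hflip_prob=0.5, blur_prob=0.2, noise_prob=0.15,
                       brightness_prob=0.15, contrast_prob=0.15,
                       gamma_prob=0.15)
        raise ValueError(f"unknown augmentation strategy: {name!r}")


def augment(image: np.ndarray, mask: np.ndarray,
            strategy: AugmentationStrategy, rng: np.random.Generator):
    """Apply one random draw of the strategy to an (image, mask) pair.

    Geometric transforms hit image (bicubic) and mask (nearest) identically;
    photometric transforms hit the image only.  Deterministic given ``rng``.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    s = strategy
    if s.name == "none":
        return image, mask
    if rng.random() < s.rotation_prob:
        angle = rng.uniform(-s.rotation_deg, s.rotation_deg)
        image = ndi.rotate(image, angle, axes=(1, 0), reshape=False, order=3,
                           mode="constant", cval=0.0)
        mask = ndi.rotate(mask, angle, axes=(1, 0), reshape=False, order=0,
                          mode="constant", cval=0)
        image = np.clip(image, 0.0, 1.0)
    if rng.random() < s.vflip_prob:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    if rng.random() < s.hflip_prob:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.random() < s.blur_prob:
        sigma = rng.uniform(*s.blur_sigma)
        image = ndi.gaussian_filter(image, sigma=(sigma, sigma, 0))
    if rng.random() < s.noise_prob:
        sigma = rng.uniform(0.0, s.noise_sigma_max)
        image = np.clip(image + rng.normal(0, sigma, image.shape), 0, 1).astype(
            np.float32
        )
    if rng.random() < s.brightness_prob:
        image = np.clip(image + rng.uniform(-s.brightness_delta, s.brightness_delta),
                        0, 1)
    if rng.random() < s.contrast_prob:
        c = rng.uniform(*s.contrast_range)
        image = np.clip((image - 0.5) * c + 0.5, 0, 1)
    if rng.random() < s.gamma_prob:
        g = rng.uniform(*s.gamma_range)
        image = np.clip(image, 0, 1) ** g
    return image.astype(np.float32), mask
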
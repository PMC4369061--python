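"""Green-mask segmentation of plant shoots from RGB views.

The plant ("plant green") occupies a compact arc of the hue circle, so the
core of the segmentation is a hue threshold in HSV space.  Thin offshoots
(tendrils, 1–2 px wide) are fragile under thresholding — a single-pixel
miss disconnects the whole offshoot — so the hue mask is fused with a Canny
edge map: edge components attached to the hue mask are kept, isolated
background edges are discarded.  A post-processing chain (median filter,
morphological closing/opening, small-component removal) cleans the result,
and a tray image can be split into per-plant masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage import color, feature, morphology

VIEWS = ("top", "front", "side")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HueInterval:
    """An arc on the hue circle, in degrees; may wrap through 0°."""

    low_deg: float = 80.0
    high_deg: float = 160.0

    def __post_init__(self) -> None:
        if not (0 <= self.low_deg < 360 and 0 <= self.high_deg < 360):
            raise ValueError("hue interval endpoints must lie in [0, 360)")

    def contains(self, hue_deg: np.ndarray) -> np.ndarray:
        h = np.asarray(hue_deg) % 360.0
        if self.low_deg <= self.high_deg:
            return (h >= self.low_deg) & (h <= self.high_deg)
        return (h >= self.low_deg) | (h <= self.high_deg)


@dataclass
class SegmentationParams:
    """All tunables of the green-mask pipeline.

    Canny thresholds are expressed on the [0, 1] intensity scale of the
    value channel.  Zero radii skip the corresponding post-processing step.
    """

    hue_interval: HueInterval = field(default_factory=HueInterval)
    use_otsu: bool = False
    canny_sigma: float = 1.0
    canny_low: float = 0.08
    canny_high: float = 0.2
    edge_bridge_radius: int = 3
    median_radius: int = 0
    morph_close_radius: int = 0
    morph_open_radius: int = 0
    min_component_px: int = 10

    def __post_init__(self) -> None:
        if self.canny_low > self.canny_high:
            raise ValueError("canny_low must not exceed canny_high")
        for name in (
            "edge_bridge_radius",
            "median_radius",
            "morph_close_radius",
            "morph_open_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")


class HSVImage(NamedTuple):
    """Per-pixel hue (degrees, [0,360)), saturation and value (both [0,1])."""

    hue_deg: np.ndarray
    saturation: np.ndarray
    value: np.ndarray


class OtsuResult(NamedTuple):
    threshold: int
    degenerate: bool


def rgb_to_hsv(img: np.ndarray) -> HSVImage:
    """Convert an 8-bit RGB image to HSV with hue in degrees.

    Achromatic pixels (S = 0) get hue 0 by convention.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    hsv = color.rgb2hsv(arr.astype(np.float64) / 255.0)
    return HSVImage(hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2])


def otsu_threshold(channel: np.ndarray) -> OtsuResult:
    """Otsu threshold of an 8-bit channel over the fixed 256-bin histogram.

    Returns the integer threshold ``t`` that minimizes the intra-class
    (within-class) variance of the split ``{<= t}`` / ``{> t}``; ties break
    toward the smaller threshold.  A constant image has no separating
    threshold; it is returned unchanged with ``degenerate=True`` so the
    caller can decide what to do.
    """
    vals = np.asarray(channel)
    if vals.size == 0:
        raise ValueError("empty channel")
    vals = vals.astype(np.int64).ravel()
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    if vals.min() == vals.max():
        return OtsuResult(int(vals[0]), True)

    hist = np.bincount(vals, minlength=256).astype(np.float64)
    n = hist.sum()
    omega = np.cumsum(hist)                      # class-0 mass for t = 0..255
    mu = np.cumsum(hist * np.arange(256))        # class-0 first moment
    mu_total = mu[-1]
    # Between-class variance; maximizing it minimizes intra-class variance.
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu * n) ** 2 / (omega * (n - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return OtsuResult(int(np.argmax(sigma_b)), False)


def hue_threshold(hsv: HSVImage, interval: HueInterval) -> np.ndarray:
    """Boolean mask of pixels whose hue lies on the foreground arc.

    Saturation and value carry no hue information and are ignored, except
    that achromatic pixels (S = 0) have undefined hue and are always
    background.
    """
    return interval.contains(hsv.hue_deg) & (hsv.saturation > 0)


def canny_edges(gray: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Classic Canny edge map (thin, ~1 px) of a [0, 1] intensity channel."""
    g = np.asarray(gray, dtype=np.float64)
    return feature.canny(
        g,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )


def fuse_masks(thresh: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Fuse the hue-threshold mask with the edge map.

    Edge components (8-connected) that touch the threshold mask — within
    two pixels, since the Canny contour of a thin offshoot runs one pixel
    off the structure it outlines — belong to the plant and are kept;
    isolated background edges are dropped.  Kept edge pixels that merely
    hug the threshold mask (within one pixel of it) duplicate its boundary
    and are not added — only edge pixels extending beyond that one-pixel
    shell, e.g. along a tendril the threshold lost, enter the fused mask.

    The result is always a superset of ``thresh`` and a subset of
    ``thresh | edges``.
    """
    thresh = np.asarray(thresh, dtype=bool)
    edges = np.asarray(edges, dtype=bool)
    if thresh.shape != edges.shape:
        raise ValueError("threshold and edge masks must share a shape")
    if not thresh.any() or not edges.any():
        return thresh.copy()

    labels, _ = ndimage.label(edges, structure=_STRUCT8)
    anchor = ndimage.binary_dilation(thresh, structure=_STRUCT8, iterations=2)
    shell = ndimage.binary_dilation(thresh, structure=_STRUCT8)
    anchored_ids = np.unique(labels[anchor & edges])
    anchored_ids = anchored_ids[anchored_ids > 0]
    if anchored_ids.size == 0:
        return thresh.copy()
    anchored = np.isin(labels, anchored_ids)
    return thresh | (anchored & ~shell)


def postprocess_mask(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Clean a binary mask: median → closing → opening → size filter.

    A zero radius (or ``min_component_px == 0``) skips that step, so the
    all-zero configuration is the identity map.
    """
    out = np.asarray(mask, dtype=bool)
    if params.median_radius > 0:
        fp = morphology.disk(params.median_radius)
        out = ndimage.median_filter(out, footprint=fp)
    if params.morph_close_radius > 0:
        out = morphology.closing(out, morphology.disk(params.morph_close_radius))
    if params.morph_open_radius > 0:
        out = morphology.opening(out, morphology.disk(params.morph_open_radius))
    if params.min_component_px > 0:
        out = morphology.remove_small_objects(
            out, max_size=params.min_component_px - 1, connectivity=2
        )
    return out


def split_tray(mask: np.ndarray, n_plants: int) -> list[np.ndarray]:
    """Split a tray mask into per-plant masks, left to right.

    Connected components are assigned to ``n_plants`` equal-width vertical
    strips by the column of their centroid.  If a strip receives no
    component an empty mask is returned for it, with a warning.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n_comp = ndimage.label(mask, structure=_STRUCT8)
    out = [np.zeros_like(mask) for _ in range(n_plants)]
    if n_comp:
        strip_w = mask.shape[1] / n_plants
        centroids = ndimage.center_of_mass(mask, labels, range(1, n_comp + 1))
        for comp_id, (_, cx) in enumerate(centroids, start=1):
            strip = min(int(cx / strip_w), n_plants - 1)
            out[strip] |= labels == comp_id
    empty = [i for i, m in enumerate(out) if not m.any()]
    if empty:
        warnings.warn(
            f"no plant found in strip(s) {empty}; returning empty mask(s)",
            stacklevel=2,
        )
    return out


def segment_view(
    img: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Full green-mask pipeline for one RGB view.

    HSV conversion → hue threshold (or Otsu split of the hue channel when
    ``use_otsu``) → Canny on the value channel → mask fusion → edge
    bridging → post-processing.

    Canny marks the two flanks of a thin offshoot rather than its centre
    line, so the pixels the fusion step adds are dilated by
    ``edge_bridge_radius`` to fill in the structure they outline, gated on
    the value channel: only pixels at least as bright as the midpoint
    between the plant and the background median brightness are admitted,
    so in-filling cannot leak onto dark soil between branches.  Bridging
    only ever grows edge-derived additions — on an image where the hue
    threshold already captures everything, fusion adds nothing and the
    mask passes through untouched.
    """
    params = params or SegmentationParams()
    hsv = rgb_to_hsv(img)
    if params.use_otsu:
        hue_byte = np.clip(np.round(hsv.hue_deg / 360.0 * 255.0), 0, 255).astype(
            np.uint8
        )
        t, degenerate = otsu_threshold(hue_byte)
        # Plant green sits above soil/pot hues, so foreground is the upper class.
        thresh = (
            np.zeros(hue_byte.shape, dtype=bool)
            if degenerate
            else (hue_byte > t) & (hsv.saturation > 0)
        )
    else:
        thresh = hue_threshold(hsv, params.hue_interval)
    edges = canny_edges(hsv.value, params)
    fused = fuse_masks(thresh, edges)
    additions = fused & ~thresh
    if params.edge_bridge_radius > 0 and additions.any() and thresh.any():
        grown = ndimage.binary_dilation(
            additions, structure=_STRUCT8, iterations=params.edge_bridge_radius
        )
        background = ~(thresh | edges)
        v_plant = float(np.median(hsv.value[thresh]))
        v_bg = float(np.median(hsv.value[background])) if background.any() else 0.0
        gate = hsv.value >= (v_plant + v_bg) / 2.0
        fused = thresh | ((additions | grown) & gate)
    return postprocess_mask(fused, params)


def mask_overlay(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RGB copy of ``img`` with the mask boundary drawn as a white line."""
    out = np.asarray(img, dtype=np.uint8).copy()
    boundary = ndimage.binary_dilation(mask, structure=_STRUCT8) & ~np.asarray(
        mask, dtype=bool
    )
    out[boundary] = 255
    return out


def recall_precision(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Pixel recall and precision of a predicted mask against ground truth."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = float(np.count_nonzero(predicted & truth))
    recall = tp / max(np.count_nonzero(truth), 1)
    precision = tp / max(np.count_nonzero(predicted), 1)
    return recall, precision


def params_from_mapping(cfg: dict[str, str | float | int]) -> SegmentationParams:
    """Build :class:`SegmentationParams` from flat config keys.

    Recognized keys (with or without a ``segmentation.`` prefix):
    ``hue_low``, ``hue_high``, ``use_otsu``, ``canny_sigma``, ``canny_low``,
    ``canny_high``, ``median_radius``, ``morph_close_radius``,
    ``morph_open_radius``, ``min_component_px``.
    """
    flat: dict[str, str] = {}
    for key, val in cfg.items():
        name = key.split(".", 1)[1] if key.startswith("segmentation.") else key
        flat[name] = str(val)
    kwargs: dict = {}
    if "hue_low" in flat or "hue_high" in flat:
        kwargs["hue_interval"] = HueInterval(
            float(flat.get("hue_low", 80.0)), float(flat.get("hue_high", 160.0))
        )
    if "use_otsu" in flat:
        kwargs["use_otsu"] = flat["use_otsu"].lower() in ("1", "true", "yes")
    for name, cast in (
        ("canny_sigma", float),
        ("canny_low", float),
        ("canny_high", float),
        ("edge_bridge_radius", int),
        ("median_radius", int),
        ("morph_close_radius", int),
        ("morph_open_radius", int),
        ("min_component_px", int),
    ):
        if name in flat:
            kwargs[name] = cast(flat[name])
    return SegmentationParams(**kwargs)


def views_in_use(names: Sequence[str]) -> list[str]:
    unknown = [v for v in names if v not in VIEWS]
    if unknown:
        raise ValueError(f"unknown view(s): {unknown}; expected subset of {VIEWS}")
    return list(names)
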
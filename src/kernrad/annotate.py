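"""Red-contour detection, 64x64 window placement, patch and mask extraction.

A radiologist's annotation is a closed pure-red curve drawn on an exported
copy of the image.  This module finds that curve, fixes a 64x64 analysis
window, cuts the patch from the *non-annotated* original (so the red line
cannot leak into the features) and builds the binary lesion mask by filling
the contour and erasing the contour-line pixels themselves.

Two window-placement modes are provided.  ``paper_scan`` slides a 64x64
window over the image in row-major order with step 1 and stops at the first
window touching a red pixel; ``centroid`` (default) centers the window on
the centroid of the red-pixel bounding box, which stays robust when the
contour is larger than a single window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from kernrad.errors import (
    AnnotationNotFoundError,
    BoundsError,
    ContourError,
    MaskError,
)

WINDOW = 64
_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class RedRule:
    """Thresholds defining an annotation pixel; tolerant to JPEG chroma bleed."""

    r_min: int = 200
    g_max: int = 80
    b_max: int = 80


@dataclass(frozen=True)
class WindowCoords:
    """Half-open 64x64 window [top, top+64) x [left, left+64), 0-based."""

    top: int
    left: int
    size: int = WINDOW


@dataclass
class Patch:
    pixels: np.ndarray  # (64, 64) uint8, from the non-annotated original
    window: WindowCoords
    source_id: str | None = None


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luma conversion (0.299 R + 0.587 G + 0.114 B), rounded to uint8."""
    rgb = np.asarray(rgb)
    if rgb.ndim == 2:
        return rgb.astype(np.uint8)
    y = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def red_mask(annotated: np.ndarray, rule: RedRule = RedRule()) -> np.ndarray:
    """Boolean mask of annotation pixels under the red rule."""
    img = np.asarray(annotated)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("annotated image must be an RGB raster")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return (r >= rule.r_min) & (g <= rule.g_max) & (b <= rule.b_max)


def _closed_contour(red: np.ndarray) -> np.ndarray:
    """Fill the contour after a 3x3 morphological closing; error if open.

    A contour counts as closed when the closed curve encloses a nonempty
    interior and forms a single 8-connected component; the 3x3 closing
    tolerates 1-px gaps introduced by lossy compression.
    """
    closed = ndimage.binary_closing(red, structure=_EIGHT)
    n_comp = ndimage.label(closed, structure=_EIGHT)[1]
    filled = ndimage.binary_fill_holes(closed)
    if n_comp != 1 or filled.sum() <= closed.sum():
        raise ContourError("red annotation is not a single closed contour")
    return filled


def locate_annotation(
    annotated: np.ndarray, mode: str = "centroid", rule: RedRule = RedRule()
) -> WindowCoords:
    """Place the 64x64 analysis window relative to the red contour.

    ``paper_scan`` reproduces a raster scan with step 1 from the top-left:
    the returned window is the first one, in row-major order, that contains
    at least one red pixel.  ``centroid`` centers the window on the red
    bounding-box centroid, clipped to the image bounds.
    """
    img = np.asarray(annotated)
    h, w = img.shape[:2]
    if h < WINDOW or w < WINDOW:
        raise BoundsError("image smaller than the 64x64 window")
    red = red_mask(img, rule)
    if not red.any():
        raise AnnotationNotFoundError("no red annotation pixels found")
    _closed_contour(red)

    rows, cols = np.nonzero(red)
    if mode == "paper_scan":
        # first-contact window in row-major order: the smallest top whose
        # row range [top, top+64) touches a red pixel, then the smallest
        # valid left touching one of those pixels
        top = min(max(0, rows.min() - (WINDOW - 1)), h - WINDOW)
        in_rows = cols[rows < top + WINDOW]
        left = min(max(0, in_rows.min() - (WINDOW - 1)), w - WINDOW)
        return WindowCoords(int(top), int(left))
    if mode == "centroid":
        cy = (rows.min() + rows.max()) / 2.0
        cx = (cols.min() + cols.max()) / 2.0
        top = int(np.clip(round(cy - WINDOW / 2), 0, h - WINDOW))
        left = int(np.clip(round(cx - WINDOW / 2), 0, w - WINDOW))
        return WindowCoords(top, left)
    raise ValueError(f"unknown mode {mode!r}")


def extract_patch(
    original: np.ndarray, w: WindowCoords, source_id: str | None = None
) -> Patch:
    """Cut the 64x64 patch from the non-annotated original image."""
    img = np.asarray(original)
    if img.ndim == 3:
        img = to_grayscale(img)
    h, wid = img.shape
    if w.top < 0 or w.left < 0 or w.top + w.size > h or w.left + w.size > wid:
        raise BoundsError(f"window {w} exceeds image bounds {img.shape}")
    pixels = img[w.top : w.top + w.size, w.left : w.left + w.size].copy()
    return Patch(pixels, w, source_id)


def build_mask(
    annotated: np.ndarray, w: WindowCoords, rule: RedRule = RedRule()
) -> np.ndarray:
    """Binary lesion mask inside the window: filled contour minus the line.

    The red curve is morphologically closed, hole-filled, and the contour
    pixels themselves erased ("erasing the small annotated area"), then the
    result is restricted to the window.  If window clipping splits the
    region, the largest connected component is kept.
    """
    img = np.asarray(annotated)
    red = red_mask(img, rule)
    if not red.any():
        raise AnnotationNotFoundError("no red annotation pixels found")
    filled = _closed_contour(red)
    closed = ndimage.binary_closing(red, structure=_EIGHT)
    interior = filled & ~closed
    sub = interior[w.top : w.top + w.size, w.left : w.left + w.size]
    if sub.shape != (w.size, w.size):
        raise BoundsError(f"window {w} exceeds image bounds {img.shape[:2]}")
    labels, n = ndimage.label(sub, structure=_EIGHT)
    if n == 0:
        raise MaskError("contour interior does not intersect the window")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        sub = labels == (1 + int(np.argmax(sizes)))
    return sub.astype(bool)


def segment_subject(
    annotated: np.ndarray,
    original: np.ndarray,
    mode: str = "centroid",
    rule: RedRule = RedRule(),
    source_id: str | None = None,
) -> tuple[Patch, np.ndarray]:
    """Full per-subject preprocessing: locate window, cut patch, build mask."""
    w = locate_annotation(annotated, mode=mode, rule=rule)
    return extract_patch(original, w, source_id), build_mask(annotated, w, rule)
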
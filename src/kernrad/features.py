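"""Registry of 670 named radiomics features per (patch, mask) pair.

The registry is organized in four groups:

* 14 shape/size features computed from the binary lesion mask alone;
* 18 first-order (histogram) features per image channel;
* 16 gray-level co-occurrence matrix (GLCM) descriptors per channel at
  4 angles (0, 45, 90, 135 degrees) and distance 1;
* 8 image channels: the original patch, the 4 single-level Haar wavelet
  sub-bands (LL/LH/HL/HH, upsampled back to 64x64) and 3
  Laplacian-of-Gaussian responses (sigma = 1, 2, 3 px).

Total: 14 + 8 x (18 + 4 x 16) = 670.  Intensity features are computed on
masked pixels only; gray levels are quantized to Q = 32 equal-width bins
over the masked min-max range.  Logarithms are base 2 with an epsilon
guard of 1e-12 so every feature is finite on any valid input.

Feature names follow the grammar ``shape_<desc>``, ``FO_<desc>_<channel>``
and ``GLCM_t_<angle>_d_1_<Desc>_<channel>``, e.g. ``FO_smoothness_orig``
and ``GLCM_t_45_d_1_Con_orig``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage import measure

from kernrad.errors import DegenerateGLCMError, MaskError

EPS = 1e-12
Q_DEFAULT = 32
ANGLES = (0, 45, 90, 135)
GLCM_DISTANCE = 1
#: full-scale intensity used to rescale values to [0, 1] for smoothness
FULL_SCALE = 255.0

CHANNELS = ("orig", "wav_LL", "wav_LH", "wav_HL", "wav_HH", "LoG_1", "LoG_2", "LoG_3")

SHAPE_NAMES = (
    "area",
    "perimeter",
    "compactness",
    "circularity",
    "eccentricity",
    "elongation",
    "major_axis",
    "minor_axis",
    "equiv_diameter",
    "solidity",
    "extent",
    "convexity",
    "boundary_roughness",
    "feret_max",
)

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "min",
    "max",
    "range",
    "variance",
    "sd",
    "mad",
    "rms",
    "energy",
    "entropy",
    "uniformity",
    "skewness",
    "kurtosis",
    "smoothness",
    "p10",
    "p90",
    "iqr",
)

GLCM_DESCRIPTORS = (
    "Auto",
    "ClProm",
    "ClShade",
    "Con",
    "Corr",
    "DifEnt",
    "DifVar",
    "Dissim",
    "Energy",
    "Ent",
    "Homog",
    "IMC1",
    "IMC2",
    "MaxP",
    "SumAvg",
    "SumEnt",
)

# (row, col) pixel offsets per angle; 0 deg points along +col
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def feature_names() -> list[str]:
    names = [f"shape_{d}" for d in SHAPE_NAMES]
    for ch in CHANNELS:
        names.extend(f"FO_{d}_{ch}" for d in FIRST_ORDER_NAMES)
        for theta in ANGLES:
            names.extend(
                f"GLCM_t_{theta}_d_{GLCM_DISTANCE}_{d}_{ch}"
                for d in GLCM_DESCRIPTORS
            )
    return names


_NAMES = feature_names()
N_FEATURES = len(_NAMES)


def feature_manifest() -> pd.DataFrame:
    """Table of (name, group, channel, parameters) for every feature."""
    rows = []
    for name in _NAMES:
        if name.startswith("shape_"):
            rows.append((name, "shape", "", ""))
        elif name.startswith("FO_"):
            ch = next(c for c in CHANNELS if name.endswith("_" + c))
            rows.append((name, "first_order", ch, ""))
        else:
            parts = name.split("_")
            theta, dist = parts[2], parts[4]
            ch = next(c for c in CHANNELS if name.endswith("_" + c))
            rows.append((name, "glcm", ch, f"theta={theta},d={dist},Q={Q_DEFAULT}"))
    return pd.DataFrame(rows, columns=["name", "group", "channel", "parameters"])


# ---------------------------------------------------------------------------
# quantization and GLCM


def quantize(patch: np.ndarray, mask: np.ndarray, q: int = Q_DEFAULT) -> np.ndarray:
    """Map masked intensities to levels {0..q-1} by equal-width binning.

    Bin edges span the masked min-max range; a constant region maps to
    level 0 everywhere.  Pixels outside the mask are set to level 0 and
    must be ignored by consumers.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MaskError("empty mask")
    x = np.asarray(patch, dtype=float)
    lo = x[mask].min()
    hi = x[mask].max()
    out = np.zeros(x.shape, dtype=np.int64)
    if hi > lo:
        levels = np.floor((x - lo) / (hi - lo) * q).astype(np.int64)
        out[mask] = np.clip(levels[mask], 0, q - 1)
    return out


def glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    angle: int,
    distance: int = GLCM_DISTANCE,
    q: int = Q_DEFAULT,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over in-mask pixel pairs.

    A pair is counted only when *both* pixels lie inside the mask; each
    pair contributes in both directions, and the matrix is normalized to
    sum to one.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    dr, dc = (o * distance for o in _OFFSETS[angle])
    qarr = np.asarray(quantized)
    mask = np.asarray(mask, bool)
    h, w = qarr.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = qarr[r0s:r0e, c0s:c0e]
    b = qarr[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    i = a[valid]
    j = b[valid]
    if i.size == 0:
        raise DegenerateGLCMError("no in-mask pixel pairs for this offset")
    p = np.zeros((q, q), dtype=float)
    np.add.at(p, (i, j), 1.0)
    np.add.at(p, (j, i), 1.0)
    return p / p.sum()


def glcm_descriptors(p: np.ndarray) -> dict[str, float]:
    """Sixteen Haralick-style descriptors of a normalized symmetric GLCM."""
    p = np.asarray(p, float)
    q = p.shape[0]
    i = np.arange(q, dtype=float)[:, None]
    j = np.arange(q, dtype=float)[None, :]
    px = p.sum(axis=1)
    mu = float((i * p).sum())  # = mu_x = mu_y by symmetry
    sigma2 = float(((i - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    contrast = float(((i - j) ** 2 * p).sum())
    dissim = float((np.abs(i - j) * p).sum())
    if sigma > EPS:
        correlation = float(((i - mu) * (j - mu) * p).sum() / (sigma * sigma))
    else:
        correlation = 1.0

    # marginal sums p_{x+y} (k = 0..2q-2) and p_{x-y} (k = 0..q-1)
    ksum = (np.arange(q)[:, None] + np.arange(q)[None, :]).ravel()
    kdiff = np.abs(np.arange(q)[:, None] - np.arange(q)[None, :]).ravel()
    p_sum = np.bincount(ksum, weights=p.ravel(), minlength=2 * q - 1)
    p_diff = np.bincount(kdiff, weights=p.ravel(), minlength=q)
    ks = np.arange(2 * q - 1, dtype=float)
    kd = np.arange(q, dtype=float)
    sum_avg = float((ks * p_sum).sum())
    sum_ent = float(-(p_sum * np.log2(p_sum + EPS)).sum())
    dif_ent = float(-(p_diff * np.log2(p_diff + EPS)).sum())
    da = float((kd * p_diff).sum())
    dif_var = float(((kd - da) ** 2 * p_diff).sum())

    hxy = float(-(p * np.log2(p + EPS)).sum())
    hx = float(-(px * np.log2(px + EPS)).sum())
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-(p * np.log2(pxpy + EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + EPS)).sum())
    imc1 = (hxy - hxy1) / hx if hx > EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "Auto": float((i * j * p).sum()),
        "ClProm": float(((i + j - 2 * mu) ** 4 * p).sum()),
        "ClShade": float(((i + j - 2 * mu) ** 3 * p).sum()),
        "Con": contrast,
        "Corr": correlation,
        "DifEnt": dif_ent,
        "DifVar": dif_var,
        "Dissim": dissim,
        "Energy": float((p**2).sum()),
        "Ent": hxy,
        "Homog": float((p / (1.0 + (i - j) ** 2)).sum()),
        "IMC1": imc1,
        "IMC2": imc2,
        "MaxP": float(p.max()),
        "SumAvg": sum_avg,
        "SumEnt": sum_ent,
    }


# ---------------------------------------------------------------------------
# first-order and shape


def first_order(
    channel: np.ndarray, mask: np.ndarray, q: int = Q_DEFAULT
) -> dict[str, float]:
    """Eighteen histogram features of the masked channel intensities.

    ``smoothness`` is R = 1 - 1/(1 + var) of the intensities divided by
    the 8-bit full scale (255), so a constant region scores 0 and rougher
    regions score closer to 1.  Histogram entropy/uniformity use ``q``
    equal-width bins over the masked range.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MaskError("empty mask")
    x = np.asarray(channel, float)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        hist, _ = np.histogram(x, bins=q, range=(lo, hi))
        prob = hist / n
    else:
        prob = np.zeros(q)
        prob[0] = 1.0
    entropy = float(-(prob * np.log2(prob + EPS)).sum())
    uniformity = float((prob**2).sum())
    if sd > EPS:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    var_scaled = float((x / FULL_SCALE).var())
    smoothness = 1.0 - 1.0 / (1.0 + var_scaled)
    p10, p25, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 75, 90]))
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "min": lo,
        "max": hi,
        "range": hi - lo,
        "variance": var,
        "sd": sd,
        "mad": float(np.abs(x - mean).mean()),
        "rms": float(np.sqrt((x**2).mean())),
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
        "skewness": skew,
        "kurtosis": kurt,
        "smoothness": smoothness,
        "p10": p10,
        "p90": p90,
        "iqr": p75 - p25,
    }


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Fourteen size/shape descriptors of the binary lesion mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise MaskError("empty mask")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n != 1:
        raise MaskError(f"mask must be a single connected component, got {n}")
    props = measure.regionprops(labels.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    if perimeter <= 0:  # single-pixel degenerate mask
        perimeter = 1.0
    convex_perimeter = float(measure.perimeter(props.image_convex))
    if convex_perimeter <= 0:
        convex_perimeter = perimeter
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "area": area,
        "perimeter": perimeter,
        "compactness": perimeter**2 / area,
        "circularity": 4.0 * np.pi * area / perimeter**2,
        "eccentricity": float(props.eccentricity),
        "elongation": 1.0 - minor / major if major > 0 else 0.0,
        "major_axis": major,
        "minor_axis": minor,
        "equiv_diameter": float(props.equivalent_diameter_area),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "convexity": min(convex_perimeter / perimeter, 1.0),
        "boundary_roughness": perimeter / convex_perimeter,
        "feret_max": float(props.feret_diameter_max),
    }


# ---------------------------------------------------------------------------
# transform channels and full extraction


def derive_channels(patch: np.ndarray) -> dict[str, np.ndarray]:
    """Eight aligned 64x64 channels: original, Haar sub-bands, LoG responses.

    The single-level Haar sub-bands (half resolution) are upsampled back to
    64x64 by 2x2 pixel replication so every channel aligns with the mask.
    LoG filters use reflective boundary handling.
    """
    x = np.asarray(patch, float)
    ll, (lh, hl, hh) = pywt.dwt2(x, "haar")
    up = lambda s: np.kron(s, np.ones((2, 2)))
    channels = {
        "orig": x,
        "wav_LL": up(ll),
        "wav_LH": up(lh),
        "wav_HL": up(hl),
        "wav_HH": up(hh),
    }
    for sigma in (1.0, 2.0, 3.0):
        channels[f"LoG_{int(sigma)}"] = _log_filter(x, sigma)
    return channels


def _log_kernel(sigma: float) -> np.ndarray:
    """Discrete LoG kernel forced to exact zero sum (annihilates constants)."""
    r = int(np.ceil(4.0 * sigma))
    impulse = np.zeros((2 * r + 1, 2 * r + 1))
    impulse[r, r] = 1.0
    k = ndimage.gaussian_laplace(impulse, sigma, mode="constant")
    return k - k.sum() / k.size


def _log_filter(x: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.convolve(x, _log_kernel(sigma), mode="reflect")


def extract_all(
    patch: np.ndarray, mask: np.ndarray, q: int = Q_DEFAULT
) -> pd.Series:
    """Compute the full 670-feature vector in manifest order."""
    patch = np.asarray(patch)
    mask = np.asarray(mask, bool)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    values: dict[str, float] = {}
    for name, v in shape_features(mask).items():
        values[f"shape_{name}"] = v
    for ch_name, channel in derive_channels(patch).items():
        for name, v in first_order(channel, mask, q).items():
            values[f"FO_{name}_{ch_name}"] = v
        quant = quantize(channel, mask, q)
        for theta in ANGLES:
            p = glcm(quant, mask, theta, GLCM_DISTANCE, q)
            for name, v in glcm_descriptors(p).items():
                values[f"GLCM_t_{theta}_d_{GLCM_DISTANCE}_{name}_{ch_name}"] = v
    return pd.Series([values[n] for n in _NAMES], index=_NAMES, dtype=float)


def extract_table(
    patches: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    index: Iterable | None = None,
    q: int = Q_DEFAULT,
) -> pd.DataFrame:
    """Feature matrix: one row per (patch, mask) pair, 670 columns."""
    rows = [extract_all(p, m, q) for p, m in zip(patches, masks)]
    return pd.DataFrame(rows, index=index)
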
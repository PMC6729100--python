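"""Synthetic annotated-lesion cohorts with grade-dependent texture.

The generator emulates the study material the pipeline was designed for:
single-slice, 8-bit, soft-tissue-windowed CT exports on which a radiologist
has encircled the solid part of a tumor with a closed red curve.  Each
subject yields an annotated RGB copy, the untouched grayscale original, a
binary ground-truth lesion mask and a row of clinical covariates.

Two histological grades are simulated.  Well-differentiated (``WD``)
lesions carry a long-correlation, low-amplitude Gaussian random-field
texture (smooth); moderately/poorly differentiated (``MD/PD``) lesions a
short-correlation, high-amplitude field plus hypodense necrosis-like blobs
(rough).  Class prevalence defaults to the 61.3% / 38.7% WD vs MD/PD mix
of a 206-patient head-and-neck squamous-cell-carcinoma cohort, and the
four clinical covariates (T, N, stage, enhancement pattern) are Bernoulli
draws whose logit is shifted by ``clinical_effect`` for MD/PD subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from kernrad.errors import ConfigurationError, GeometryError

WD = "WD"
MDPD = "MD/PD"
GRADES = (WD, MDPD)

#: dichotomous clinical covariates: (column, reference level, risk level)
CLINICAL_LEVELS = {
    "T": ("T1-2", "T3-4"),
    "N": ("N0", "N+"),
    "stage": ("I-II", "III-IV"),
    "enhancement": ("homogeneous", "heterogeneous"),
}

# baseline probability of the risk level for a WD subject; chosen to echo
# the marginal frequencies of a typical HNSCC cohort (T3-4 ~70%, N+ ~47%,
# stage III-IV ~78%, heterogeneous enhancement ~68%)
_CLINICAL_BASE_P = {"T": 0.60, "N": 0.35, "stage": 0.70, "enhancement": 0.60}


@dataclass
class PhantomConfig:
    """Knobs of the synthetic cohort.

    Texture parameters are per-grade mappings keyed by ``"WD"`` and
    ``"MD/PD"``.  ``texture_sd`` is the pixel-intensity standard deviation
    of the lesion's Gaussian random field (8-bit units) and
    ``texture_corr_length`` its correlation length in pixels; the MD/PD
    field must be rougher (larger SD) than the WD field by construction.
    ``clinical_effect`` is the log-odds shift of each risk-level clinical
    covariate for MD/PD relative to WD subjects (0 = uninformative).
    """

    n_subjects: int = 200
    prevalence_wd: float = 0.613
    image_size: tuple[int, int] = (192, 192)
    lesion_axes_range: tuple[float, float] = (10.0, 24.0)
    texture_corr_length: dict = field(
        default_factory=lambda: {WD: 3.0, MDPD: 1.5}
    )
    texture_sd: dict = field(default_factory=lambda: {WD: 6.0, MDPD: 18.0})
    necrosis_blob_rate: dict = field(default_factory=lambda: {WD: 0.0, MDPD: 3.0})
    annotation_color: tuple[int, int, int] = (255, 0, 0)
    clinical_effect: float = 1.0
    seed: int = 0
    lesion_mean: float = 150.0  # mean lesion intensity (8-bit)
    background_level: float = 70.0
    background_gradient: float = 35.0
    background_noise_sd: float = 2.0
    shape_perturb_amp: float = 0.06  # radial Fourier mode amplitude cap
    export_format: str = "png"  # "png" (lossless) or "jpeg" (quality 90)

    def validate(self) -> None:
        if not 0.0 < self.prevalence_wd < 1.0:
            raise ConfigurationError("prevalence_wd must lie in (0, 1)")
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        h, w = self.image_size
        if h < 128 or w < 128:
            raise ConfigurationError("image_size must be at least 128x128")
        r, g, b = self.annotation_color
        if g != 0 or b != 0 or r == 0:
            raise ConfigurationError(
                "annotation_color must be pure red (zero green/blue)"
            )
        if self.texture_sd[MDPD] <= self.texture_sd[WD]:
            raise ConfigurationError(
                "texture_sd['MD/PD'] must exceed texture_sd['WD']"
            )
        lo, hi = self.lesion_axes_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid lesion_axes_range")
        if self.export_format not in ("png", "jpeg"):
            raise ConfigurationError("export_format must be 'png' or 'jpeg'")


@dataclass
class LesionGeometry:
    """Star-shaped lesion: ellipse perturbed by low-order radial modes."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (a >= b), pixels
    orientation: float  # radians, CCW from +col axis
    perturb_amps: tuple[float, ...] = ()  # modes k = 2, 3, 4
    perturb_phases: tuple[float, ...] = ()


@dataclass
class AnnotatedImage:
    subject_id: str
    annotated: np.ndarray  # (H, W, 3) uint8, carries the red contour
    original: np.ndarray  # (H, W) uint8, no annotation
    lesion_mask: np.ndarray  # (H, W) bool ground truth


def _radial_perturbation(geom: LesionGeometry, phi: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phi)
    for k, (amp, phase) in enumerate(
        zip(geom.perturb_amps, geom.perturb_phases), start=2
    ):
        out += amp * np.cos(k * phi + phase)
    return out


def _lesion_interior(geom: LesionGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels with normalized elliptical radius <= 1 + p(phi)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rows - geom.center[0]
    dx = cols - geom.center[1]
    c, s = np.cos(geom.orientation), np.sin(geom.orientation)
    # rotate into the ellipse frame
    u = c * dx + s * dy
    v = -s * dx + c * dy
    a, b = geom.axes
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v / b, u / a)
    return rho <= 1.0 + _radial_perturbation(geom, phi)


def _gaussian_random_field(
    shape: tuple[int, int], corr_length: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary field: Gaussian-filtered white noise rescaled to SD `sd`."""
    if sd <= 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        noise = ndimage.gaussian_filter(noise, corr_length, mode="reflect")
    s = noise.std()
    if s == 0:  # pathological but possible for tiny images
        return np.zeros(shape)
    return noise * (sd / s)


def sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> LesionGeometry:
    """Draw a lesion geometry guaranteed to fit inside the image."""
    h, w = config.image_size
    lo, hi = config.lesion_axes_range
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, a)
    amps = tuple(rng.uniform(0, config.shape_perturb_amp, size=3))
    phases = tuple(rng.uniform(0, 2 * np.pi, size=3))
    margin = a * (1 + sum(amps)) + 3
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    return LesionGeometry((cy, cx), (a, b), rng.uniform(0, np.pi), amps, phases)


def render_subject(
    grade: str,
    geometry: LesionGeometry,
    config: PhantomConfig,
    rng: np.random.Generator,
    subject_id: str = "subject",
) -> AnnotatedImage:
    """Render one subject: background, textured lesion, red contour.

    The original copy is grayscale and carries no annotation; the annotated
    copy is an RGB clone with a 1-2 px closed pure-red contour traced along
    the lesion boundary.
    """
    config.validate()
    if grade not in GRADES:
        raise ConfigurationError(f"unknown grade {grade!r}")
    h, w = config.image_size
    cy, cx = geometry.center
    a = geometry.axes[0] * (1 + sum(geometry.perturb_amps))
    if not (a <= cy <= h - a and a <= cx <= w - a):
        raise GeometryError("lesion does not fit inside the image bounds")

    cols = np.arange(w, dtype=float)
    background = (
        config.background_level
        + config.background_gradient * cols[None, :] / max(w - 1, 1)
        + rng.normal(0, config.background_noise_sd, size=(h, w))
    )

    interior = _lesion_interior(geometry, (h, w))
    field = _gaussian_random_field(
        (h, w), config.texture_corr_length[grade], config.texture_sd[grade], rng
    )
    lesion = config.lesion_mean + field

    n_blobs = rng.poisson(config.necrosis_blob_rate[grade])
    if n_blobs > 0:
        inner = ndimage.binary_erosion(interior, iterations=3)
        idx = np.flatnonzero(inner if inner.any() else interior)
        rows_g, cols_g = np.mgrid[0:h, 0:w]
        for _ in range(n_blobs):
            flat = rng.choice(idx)
            by, bx = divmod(flat, w)
            radius = rng.uniform(3.0, 6.0)
            depth = rng.uniform(40.0, 70.0)
            d2 = (rows_g - by) ** 2 + (cols_g - bx) ** 2
            lesion = lesion - depth * np.exp(-d2 / (2 * (radius / 2.0) ** 2))

    # soft halo outside the lesion only: interior pixels stay pure lesion
    # texture so in-mask statistics are not diluted by background blending
    halo = ndimage.gaussian_filter(interior.astype(float), 1.0, mode="reflect")
    weight = np.where(interior, 1.0, halo)
    img = background * (1 - weight) + lesion * weight
    original = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # the annotation encircles the lesion: ring just outside the boundary
    contour = (
        ndimage.binary_dilation(interior, structure=np.ones((3, 3), bool))
        & ~interior
    )
    annotated = np.stack([original] * 3, axis=-1)
    annotated[contour] = np.asarray(config.annotation_color, dtype=np.uint8)

    return AnnotatedImage(subject_id, annotated, original, interior)


def _sample_clinical(
    grade: str, config: PhantomConfig, rng: np.random.Generator
) -> dict:
    out = {}
    shift = config.clinical_effect if grade == MDPD else 0.0
    for name, (ref, risk) in CLINICAL_LEVELS.items():
        base = _CLINICAL_BASE_P[name]
        logit = np.log(base / (1 - base)) + shift
        p = 1.0 / (1.0 + np.exp(-logit))
        out[name] = risk if rng.random() < p else ref
    return out


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Generate a full cohort of annotated phantoms plus the truth table.

    Deterministic for a fixed config (including ``config.seed``): every
    subject draws from its own child stream of the root seed sequence, so
    per-subject rendering is independent of cohort size ordering.
    """
    config.validate()
    columns = [
        "subject_id",
        "grade",
        "T",
        "N",
        "stage",
        "enhancement",
        "center_row",
        "center_col",
        "axis_major",
        "axis_minor",
        "orientation",
    ]
    if config.n_subjects == 0:
        return [], pd.DataFrame(columns=columns)

    root = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    grades = np.where(
        label_rng.random(config.n_subjects) < config.prevalence_wd, WD, MDPD
    )
    images: list[AnnotatedImage] = []
    rows = []
    child_seqs = root.spawn(config.n_subjects + 1)[1:]
    for i, (grade, seq) in enumerate(zip(grades, child_seqs)):
        rng = np.random.default_rng(seq)
        sid = f"S{i:04d}"
        geom = sample_geometry(config, rng)
        images.append(render_subject(grade, geom, config, rng, subject_id=sid))
        clin = _sample_clinical(grade, config, rng)
        rows.append(
            {
                "subject_id": sid,
                "grade": grade,
                **clin,
                "center_row": geom.center[0],
                "center_col": geom.center[1],
                "axis_major": geom.axes[0],
                "axis_minor": geom.axes[1],
                "orientation": geom.orientation,
            }
        )
    return images, pd.DataFrame(rows, columns=columns)


def save_cohort(
    images: Iterable[AnnotatedImage],
    truth: pd.DataFrame,
    out_dir: str | Path,
    export_format: str = "png",
) -> None:
    """Write ``images/<id>_annotated.*``, ``images/<id>_original.*``, truth.csv."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    ext = "png" if export_format == "png" else "jpg"
    kwargs = {} if export_format == "png" else {"quality": 90}
    for im in images:
        Image.fromarray(im.annotated).save(
            img_dir / f"{im.subject_id}_annotated.{ext}", **kwargs
        )
        Image.fromarray(im.original).save(
            img_dir / f"{im.subject_id}_original.{ext}", **kwargs
        )
    truth.to_csv(out_dir / "truth.csv", index=False)
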
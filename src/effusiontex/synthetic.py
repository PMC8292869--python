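"""Synthetic two-class cohorts of effusion-like images.

Real CT shows benign intraperitoneal collections as a mixed bag — free,
encapsulated, inflammatory and purulent fluid — with broad density
variation, while malignant ascites tends to be more locally homogeneous.
The generator emulates exactly that contrast and nothing more: an
elliptical fluid region on a brighter uniform background, whose interior is

* heterogeneous class: several Voronoi compartments with Gaussian-offset
  mean densities plus short-range correlated noise (rough, multi-density
  fluid), or
* homogeneous class: a single smooth long-range correlated random field.

Intensities are on an HU-like scale (fluid means near 0-30, background near
60) without claiming Hounsfield fidelity.  One master seed drives the run;
each sample uses a derived seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import GrayImage, ROIMask, write_image, write_mask

__all__ = [
    "ClassSpec",
    "CohortConfig",
    "DEFAULT_HETEROGENEOUS",
    "DEFAULT_HOMOGENEOUS",
    "BACKGROUND_LEVEL",
    "generate_effusion_image",
    "generate_cohort_arrays",
    "generate_cohort",
    "generate_fixture_patterns",
    "synthesize_ar_field",
    "AR_FIXTURE_THETA",
    "AR_FIXTURE_SIGMA",
    "AR_FIXTURE_SEED",
]

BACKGROUND_LEVEL = 60.0
MIN_ROI_DIAMETER = 30  # pixels, mirrors the 30 mm minimum transverse diameter


@dataclass(frozen=True)
class ClassSpec:
    """Statistical description of one effusion class.

    base_mean and noise_sd are HU-like intensities; correlation_length is the
    Gaussian smoothing scale (pixels) of the noise field; n_subregions > 1
    adds Voronoi compartments whose mean offsets have SD
    subregion_mean_spread.  A homogeneous class has n_subregions = 1.
    """

    label: str
    base_mean: float
    noise_sd: float
    correlation_length: float
    n_subregions: int = 1
    subregion_mean_spread: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be nonnegative")
        if self.n_subregions < 1:
            raise ValueError("n_subregions must be at least 1")
        if self.subregion_mean_spread < 0:
            raise ValueError("subregion_mean_spread must be nonnegative")


# Default study conditions: benign collections are the mixed, multi-density
# class; malignant ascites the smooth homogeneous one.
DEFAULT_HETEROGENEOUS = ClassSpec(
    label="benign", base_mean=15.0, noise_sd=6.0, correlation_length=0.5,
    n_subregions=5, subregion_mean_spread=8.0,
)
DEFAULT_HOMOGENEOUS = ClassSpec(
    label="malignant", base_mean=20.0, noise_sd=6.0, correlation_length=6.0,
    n_subregions=1, subregion_mean_spread=0.0,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: per-class sizes, raster geometry and the master seed."""

    n_per_class: tuple[int, int] = (29, 23)
    image_size: tuple[int, int] = (128, 128)
    roi_axes_range: tuple[float, float] = (18.0, 40.0)  # semi-axes, pixels
    seed: int = 0
    class_specs: tuple[ClassSpec, ClassSpec] = (DEFAULT_HETEROGENEOUS, DEFAULT_HOMOGENEOUS)

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ValueError("each class needs at least one sample")
        lo, hi = self.roi_axes_range
        if lo < MIN_ROI_DIAMETER / 2:
            raise ValueError(
                f"minimum ROI semi-axis {lo} violates the {MIN_ROI_DIAMETER}-pixel "
                "minimum transverse diameter"
            )
        if 2 * hi >= min(self.image_size):
            raise ValueError("largest ROI does not fit inside the image")
        if self.class_specs[0].label == self.class_specs[1].label:
            raise ValueError("class labels must differ")


def generate_effusion_image(
    spec: ClassSpec,
    size: tuple[int, int],
    roi_axes: tuple[float, float],
    seed: int,
) -> tuple[GrayImage, ROIMask]:
    """Render one effusion-like image and its ground-truth elliptical mask.

    The mask is an axis-aligned ellipse centered in the raster with semi-axes
    ``roi_axes`` (rows, cols).  In-mask intensity = base_mean + compartment
    offset + correlated noise; outside, a uniform background.  Identical
    arguments give bit-identical output.
    """
    h, w = size
    a, b = roi_axes
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if a <= 0 or b <= 0 or cy - a < 0 or cy + a > h - 1 or cx - b < 0 or cx + b > w - 1:
        raise ValueError(f"ROI semi-axes {roi_axes} do not fit inside image {size}")

    rr, cc = np.mgrid[0:h, 0:w]
    mask = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    interior = np.full((h, w), spec.base_mean, dtype=float)

    if spec.n_subregions > 1:
        idx = np.flatnonzero(mask.ravel())
        centers = idx[rng.integers(0, idx.size, size=spec.n_subregions)]
        c_rr, c_cc = np.divmod(centers, w)
        offsets = rng.normal(0.0, spec.subregion_mean_spread, size=spec.n_subregions)
        d2 = (rr[..., None] - c_rr) ** 2 + (cc[..., None] - c_cc) ** 2
        interior += offsets[np.argmin(d2, axis=-1)]

    if spec.noise_sd > 0:
        white = rng.standard_normal((h, w))
        if spec.correlation_length > 0:
            fieldn = gaussian_filter(white, sigma=spec.correlation_length, mode="reflect")
        else:
            fieldn = white
        sd = fieldn.std()
        if sd > 0:
            interior += fieldn / sd * spec.noise_sd

    img[mask] = interior[mask]
    return GrayImage(img), ROIMask(mask)


def _sample_plan(config: CohortConfig):
    """Deterministic per-sample (label, spec, axes, seed) plan for a cohort."""
    axes_rng = np.random.default_rng(config.seed)
    plan = []
    index = 0
    for spec, n in zip(config.class_specs, config.n_per_class):
        for _ in range(n):
            axes = tuple(axes_rng.uniform(*config.roi_axes_range, size=2))
            plan.append((spec.label, spec, axes, config.seed + 1 + index))
            index += 1
    return plan


def generate_cohort_arrays(
    config: CohortConfig,
) -> list[tuple[GrayImage, ROIMask, str]]:
    """Generate the cohort in memory: list of (image, mask, label)."""
    return [
        (*generate_effusion_image(spec, config.image_size, axes, seed), label)
        for label, spec, axes, seed in _sample_plan(config)
    ]


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write the cohort as PNG image/mask pairs plus a manifest CSV.

    Intensities are rounded to integers and stored as 16-bit grayscale PNG
    (negative noise excursions clipped at 0).  Returns the manifest with
    paths relative to ``out_dir``; the same frame is written to
    ``out_dir/manifest.csv``.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (image, mask, label) in enumerate(generate_cohort_arrays(config)):
        image_path = f"{label}_{i:03d}.png"
        mask_path = f"{label}_{i:03d}_mask.png"
        stored = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
        write_image(stored, os.path.join(out_dir, image_path))
        write_mask(mask, os.path.join(out_dir, mask_path))
        rows.append({"image_path": image_path, "mask_path": mask_path, "label": label})
    manifest = pd.DataFrame(rows, columns=["image_path", "mask_path", "label"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


# ---------------------------------------------------------------------------
# deterministic fixture patterns
# ---------------------------------------------------------------------------

AR_FIXTURE_THETA = (0.4, 0.3, -0.1, 0.05)
AR_FIXTURE_SIGMA = 1.0
AR_FIXTURE_SEED = 20240517


def synthesize_ar_field(
    theta: tuple[float, float, float, float],
    sigma: float,
    size: tuple[int, int],
    seed: int,
) -> np.ndarray:
    """Causal AR realization: f(x,y) = th1 f(x-1,y) + th2 f(x-1,y-1)
    + th3 f(x,y-1) + th4 f(x+1,y-1) + e, out-of-range neighbors zero."""
    h, w = size
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, sigma, size=(h, w))
    f = np.zeros((h, w))
    t1, t2, t3, t4 = theta
    for y in range(h):
        for x in range(w):
            v = e[y, x]
            if x > 0:
                v += t1 * f[y, x - 1]
            if y > 0:
                if x > 0:
                    v += t2 * f[y - 1, x - 1]
                v += t3 * f[y - 1, x]
                if x < w - 1:
                    v += t4 * f[y - 1, x + 1]
            f[y, x] = v
    return f


def generate_fixture_patterns() -> dict[str, np.ndarray]:
    """Small deterministic rasters with hand-checkable texture statistics."""
    constant = np.full((8, 8), 5.0)
    checker = np.indices((8, 8)).sum(axis=0) % 2 + 1.0
    ramp = np.tile(np.arange(1.0, 9.0), (8, 1))
    blocks = np.kron(np.indices((4, 4)).sum(axis=0) % 2 + 1.0, np.ones((2, 2)))
    ar = synthesize_ar_field(AR_FIXTURE_THETA, AR_FIXTURE_SIGMA, (128, 128), AR_FIXTURE_SEED)
    return {
        "constant": constant,
        "checkerboard": checker,
        "ramp": ramp,
        "blocks": blocks,
        "ar": ar,
    }
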
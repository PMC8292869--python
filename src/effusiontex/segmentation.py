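"""Semi-automatic delineation of a fluid collection from a seed point.

Seeded region growing with a gradient stop stands in for an interactive
level-set tool: starting from a user-placed seed near the center of the
collection, 4-connected pixels are admitted while their intensity stays
within ``tolerance`` running SDs of the growing region's mean and the local
gradient magnitude stays below ``gradient_ceiling``; a morphological closing
then seals pixel-scale leaks.  Masks can always be supplied externally,
bypassing this module entirely.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing
from skimage.morphology import disk

from .io import GrayImage, ROIMask

__all__ = ["SeedSpec", "SeedError", "RunawaySegmentationError", "segment_from_seed"]


class SeedError(ValueError):
    """Raised when growth from the seed admits nothing."""


class RunawaySegmentationError(RuntimeError):
    """Raised when the grown region floods most of the image border."""


@dataclass(frozen=True)
class SeedSpec:
    """Parameters of the seeded growth.

    intensity_tolerance is in multiples of the running in-region SD (floored
    at ``sigma_floor`` so growth can start from a single pixel);
    gradient_ceiling is in intensity units per pixel; closing_radius in
    pixels (0 disables closing).
    """

    seed_point: tuple[int, int]
    intensity_tolerance: float = 3.0
    gradient_ceiling: float = 10.0
    closing_radius: int = 2
    sigma_floor: float = 2.0

    def __post_init__(self) -> None:
        if self.intensity_tolerance <= 0:
            raise ValueError("intensity_tolerance must be positive")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be nonnegative")


def _gradient_magnitude(pixels: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(pixels)
    return np.sqrt(gx**2 + gy**2)


def segment_from_seed(image: GrayImage, spec: SeedSpec) -> ROIMask:
    """Grow a connected region from the seed and return its mask.

    Deterministic and idempotent for fixed inputs.  Raises
    :class:`RunawaySegmentationError` when the grown region reaches more than
    half of the image border (no enclosing boundary exists, e.g. on a uniform
    image), and :class:`SeedError` when nothing beyond the seed is admitted.
    """
    px = image.pixels
    h, w = px.shape
    r0, c0 = spec.seed_point
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise SeedError(f"seed {spec.seed_point} outside image {px.shape}")

    grad_ok = _gradient_magnitude(px) < spec.gradient_ceiling
    in_region = np.zeros((h, w), dtype=bool)
    in_region[r0, c0] = True
    total = px[r0, c0]
    total_sq = px[r0, c0] ** 2
    count = 1

    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or in_region[rr, cc] or not grad_ok[rr, cc]:
                continue
            mu = total / count
            var = max(total_sq / count - mu * mu, 0.0)
            sigma = max(np.sqrt(var), spec.sigma_floor)
            if abs(px[rr, cc] - mu) <= spec.intensity_tolerance * sigma:
                in_region[rr, cc] = True
                total += px[rr, cc]
                total_sq += px[rr, cc] ** 2
                count += 1
                queue.append((rr, cc))

    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    n_border = int(border.sum())
    if int((in_region & border).sum()) > 0.5 * n_border:
        raise RunawaySegmentationError(
            "region growth reached more than half of the image border"
        )
    if count == 1:
        raise SeedError("growth admitted no pixel beyond the seed")

    if spec.closing_radius > 0:
        closed = binary_closing(in_region, structure=disk(spec.closing_radius))
        # closing must not disconnect; keep the component containing the seed
        from scipy.ndimage import label as cc_label

        lab, _ = cc_label(closed)
        closed = lab == lab[r0, c0]
        in_region = closed
    return ROIMask(in_region)
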
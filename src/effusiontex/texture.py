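"""Six-family texture feature extraction over a quantized region of interest.

Families and naming follow the MaZda conventions:

* gray-level histogram: ``Mean, Variance, Skewness, Kurtosis, Perc.01%,
  Perc.10%, Perc.50%, Perc.90%, Perc.99%`` (population moments, uncorrected
  kurtosis m4/m2^2, nearest-rank percentiles);
* absolute gradient: ``GrMean, GrVariance, GrSkewness, GrKurtosis,
  GrNonZeros`` from central differences evaluated only where all four
  4-neighbors are in-mask;
* gray-level co-occurrence matrix: 11 Haralick-type features per offset,
  offsets ``(d,0), (0,d), (d,d), (d,-d)`` for d = 1..5, symmetrized and
  normalized, named ``S(dx,dy)<Feat>`` with dx = column offset (rightward)
  and dy = row offset (downward);
* run-length matrix: 5 Galloway features per direction (horizontal,
  vertical, 45 and 135 degrees), named ``<Feat><Dir>``;
* causal autoregressive model: ``Teta1..Teta4, Sigma`` — least-squares fit of
  f(x,y) = th1 f(x-1,y) + th2 f(x-1,y-1) + th3 f(x,y-1) + th4 f(x+1,y-1) + e
  on mean-centered levels;
* Haar wavelet energies: ``WavEn{LL,LH,HL,HH}_s-{1..4}`` — mean squared
  coefficient per subband over the ROI bounding box (out-of-mask pixels
  filled with the in-mask mean).

The default configuration yields 275 features in a fixed, documented order.
Pairs, runs and neighborhoods are counted only when every participating pixel
is in-mask (no padding).  Failures within a family degrade to NaN rather than
aborting the sample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .io import GrayImage, ROIMask, read_image, read_mask
from .normalization import DEFAULT_NG, QuantizedROI, quantize_roi

__all__ = [
    "OffsetSpec",
    "CoocMatrix",
    "RunLengthMatrix",
    "DEFAULT_OFFSETS",
    "RUN_DIRECTIONS",
    "histogram_features",
    "gradient_features",
    "cooccurrence_matrix",
    "cooccurrence_features",
    "runlength_matrix",
    "runlength_features",
    "ar_features",
    "wavelet_features",
    "feature_names",
    "extract_all",
    "extract_cohort",
    "feature_map",
]

HISTOGRAM_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc.01%", "Perc.10%", "Perc.50%", "Perc.90%", "Perc.99%",
)
GRADIENT_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
COOC_FEATURE_NAMES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
RL_FEATURE_NAMES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
RUN_DIRECTIONS = ("Horzl", "Vertl", "45dgr", "135dgr")
AR_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")
WAVELET_SCALES = (1, 2, 3, 4)


@dataclass(frozen=True)
class OffsetSpec:
    """A co-occurrence displacement: dx columns rightward, dy rows downward."""

    dx: int
    dy: int

    def __post_init__(self) -> None:
        if self.dx == 0 and self.dy == 0:
            raise ValueError("offset must be nonzero")
        if max(abs(self.dx), abs(self.dy)) > 5:
            raise ValueError("offset components are limited to |d| <= 5")

    @property
    def name(self) -> str:
        return f"S({self.dx},{self.dy})"


DEFAULT_OFFSETS = tuple(
    OffsetSpec(dx, dy)
    for d in range(1, 6)
    for dx, dy in ((d, 0), (0, d), (d, d), (d, -d))
)


@dataclass
class CoocMatrix:
    """Symmetrized, normalized gray-level co-occurrence matrix."""

    p: np.ndarray
    offset: OffsetSpec
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class RunLengthMatrix:
    """Counts of maximal same-level runs by gray level and length."""

    counts: np.ndarray  # Ng x Lmax, counts[g-1, l-1]
    direction: str
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance, skewness m3/m2^1.5 and kurtosis m4/m2^2."""
    mean = float(values.mean())
    centered = values - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return mean, 0.0, np.nan, np.nan
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def _nearest_rank(sorted_values: np.ndarray, fraction: float) -> float:
    """Nearest-rank percentile: the ceil(fraction * n)-th smallest value."""
    n = sorted_values.size
    rank = max(1, int(np.ceil(fraction * n)))
    return float(sorted_values[rank - 1])


def _entropy(p: np.ndarray) -> float:
    """Natural-log entropy with the 0*ln(0) = 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(q: QuantizedROI) -> dict[str, float]:
    """First-order statistics of the in-mask gray levels."""
    values = q.in_mask_levels.astype(float)
    if values.size == 0:
        return dict.fromkeys(HISTOGRAM_NAMES, np.nan)
    mean, var, skew, kurt = _moments(values)
    s = np.sort(values)
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Perc.01%": _nearest_rank(s, 0.01),
        "Perc.10%": _nearest_rank(s, 0.10),
        "Perc.50%": _nearest_rank(s, 0.50),
        "Perc.90%": _nearest_rank(s, 0.90),
        "Perc.99%": _nearest_rank(s, 0.99),
    }


# ---------------------------------------------------------------------------
# absolute gradient
# ---------------------------------------------------------------------------

def gradient_features(q: QuantizedROI) -> dict[str, float]:
    """Absolute-gradient statistics from in-mask central differences.

    g = sqrt(gx^2 + gy^2) with gx, gy half the difference of the two
    horizontal / vertical neighbors; evaluated only where all four
    4-neighbors are in-mask.
    """
    m = q.mask
    lv = q.levels.astype(float)
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:] & m[:-2, 1:-1] & m[2:, 1:-1]
    )
    if not interior.any():
        return dict.fromkeys(GRADIENT_NAMES, np.nan)
    gx = np.zeros_like(lv)
    gy = np.zeros_like(lv)
    gx[:, 1:-1] = (lv[:, 2:] - lv[:, :-2]) / 2.0
    gy[1:-1, :] = (lv[2:, :] - lv[:-2, :]) / 2.0
    g = np.sqrt(gx[interior] ** 2 + gy[interior] ** 2)
    mean, var, skew, kurt = _moments(g)
    return {
        "GrMean": mean,
        "GrVariance": var,
        "GrSkewness": skew,
        "GrKurtosis": kurt,
        "GrNonZeros": float(np.mean(g > 0)),
    }


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence_matrix(q: QuantizedROI, offset: OffsetSpec) -> CoocMatrix:
    """Count in-mask level pairs at the given displacement, symmetrized.

    A pair is counted only when both pixels lie inside the mask; each ordered
    pair contributes to (i, j) and (j, i), and the matrix is normalized to
    sum to one.
    """
    ng = q.ng
    lv = q.levels
    m = q.mask
    h, w = lv.shape
    dy, dx = offset.dy, offset.dx

    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    counts = np.zeros((ng, ng), dtype=float)
    n_pairs = 0
    if r1 > r0 and c1 > c0:
        a_mask = m[r0:r1, c0:c1]
        b_mask = m[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
        valid = a_mask & b_mask
        i = lv[r0:r1, c0:c1][valid] - 1
        j = lv[r0 + dy:r1 + dy, c0 + dx:c1 + dx][valid] - 1
        n_pairs = int(valid.sum())
        if n_pairs:
            flat = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
            counts = flat + flat.T
            counts /= counts.sum()
    return CoocMatrix(p=counts, offset=offset, n_pairs=n_pairs)


def cooccurrence_features(matrix: CoocMatrix) -> dict[str, float]:
    """The 11 co-occurrence features (bare names, no offset prefix)."""
    if matrix.empty:
        return dict.fromkeys(COOC_FEATURE_NAMES, np.nan)
    p = matrix.p
    ng = p.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    diff = np.subtract.outer(levels, levels)  # i - j
    px = p.sum(axis=1)  # row marginal; symmetric so px == py
    mu = float(levels @ px)
    sigma2 = float(((levels - mu) ** 2) @ px)

    ang_sc_mom = float((p**2).sum())
    contrast = float((diff**2 * p).sum())
    inv_df_mom = float((p / (1.0 + diff**2)).sum())
    sum_of_sqs = float((((levels - mu) ** 2)[:, None] * p).sum())
    if sigma2 > 0:
        correlat = (float(np.outer(levels, levels).ravel() @ p.ravel()) - mu * mu) / sigma2
    else:
        correlat = np.nan

    # sum and difference marginals
    i_idx, j_idx = np.meshgrid(np.arange(ng), np.arange(ng), indexing="ij")
    p_sum = np.bincount((i_idx + j_idx).ravel(), weights=p.ravel(), minlength=2 * ng - 1)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)  # i + j for levels 1..Ng
    sum_averg = float(k_sum @ p_sum)
    sum_varnc = float(((k_sum - sum_averg) ** 2) @ p_sum)
    sum_entrp = _entropy(p_sum)

    p_dif = np.bincount(np.abs(i_idx - j_idx).ravel(), weights=p.ravel(), minlength=ng)
    k_dif = np.arange(ng, dtype=float)
    dif_mean = float(k_dif @ p_dif)
    dif_varnc = float(((k_dif - dif_mean) ** 2) @ p_dif)
    dif_entrp = _entropy(p_dif)

    return {
        "AngScMom": ang_sc_mom,
        "Contrast": contrast,
        "Correlat": correlat,
        "SumOfSqs": sum_of_sqs,
        "InvDfMom": inv_df_mom,
        "SumAverg": sum_averg,
        "SumVarnc": sum_varnc,
        "SumEntrp": sum_entrp,
        "Entropy": _entropy(p),
        "DifVarnc": dif_varnc,
        "DifEntrp": dif_entrp,
    }


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------

def _direction_lines(lv: np.ndarray, m: np.ndarray, direction: str):
    """Yield (levels, mask) 1-D lines covering the raster in a direction."""
    h, w = lv.shape
    if direction == "Horzl":
        for r in range(h):
            yield lv[r], m[r]
    elif direction == "Vertl":
        for c in range(w):
            yield lv[:, c], m[:, c]
    elif direction == "135dgr":  # down-right diagonals
        for k in range(-(h - 1), w):
            yield lv.diagonal(k), m.diagonal(k)
    elif direction == "45dgr":  # up-right diagonals
        fl, fm = np.fliplr(lv), np.fliplr(m)
        for k in range(-(h - 1), w):
            yield fl.diagonal(k), fm.diagonal(k)
    else:
        raise ValueError(f"unknown run direction: {direction!r}")


def runlength_matrix(q: QuantizedROI, direction: str) -> RunLengthMatrix:
    """Maximal same-level run counts along one direction.

    Runs are broken by the mask boundary: only contiguous in-mask pixels of
    equal level form a run.
    """
    lv = q.levels
    m = q.mask
    n_pixels = int(m.sum())
    max_len = max(lv.shape)
    counts = np.zeros((q.ng, max_len), dtype=float)
    for line_lv, line_m in _direction_lines(lv, m, direction):
        if line_lv.size == 0 or not line_m.any():
            continue
        # encode gaps as level 0 so boundaries break runs
        x = np.where(line_m, line_lv, 0)
        change = np.flatnonzero(np.diff(x) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [x.size]))
        for s, e in zip(starts, ends):
            g = x[s]
            if g > 0:
                counts[g - 1, e - s - 1] += 1
    return RunLengthMatrix(counts=counts, direction=direction, n_pixels=n_pixels)


def runlength_features(r: RunLengthMatrix) -> dict[str, float]:
    """The 5 Galloway run-length features (bare names, no direction suffix)."""
    total = r.counts.sum()
    if total == 0:
        return dict.fromkeys(RL_FEATURE_NAMES, np.nan)
    lengths = np.arange(1, r.counts.shape[1] + 1, dtype=float)
    per_length = r.counts.sum(axis=0)
    per_level = r.counts.sum(axis=1)
    return {
        "ShrtREmp": float((per_length / lengths**2).sum() / total),
        "LngREmph": float((per_length * lengths**2).sum() / total),
        "GLevNonU": float((per_level**2).sum() / total),
        "RLNonUni": float((per_length**2).sum() / total),
        "Fraction": float(total / r.n_pixels),
    }


# ---------------------------------------------------------------------------
# autoregressive model
# ---------------------------------------------------------------------------

MIN_AR_EQUATIONS = 50


def ar_features(q: QuantizedROI) -> dict[str, float]:
    """Least-squares fit of the four-neighbor causal autoregressive model.

    With x = column and y = row, the predictors of f(x, y) are f(x-1, y),
    f(x-1, y-1), f(x, y-1) and f(x+1, y-1); equations are formed only where
    the pixel and all four causal neighbors are in-mask, and levels are
    mean-centered beforehand.  Sigma is the RMS residual.
    """
    m = q.mask
    lv = q.levels.astype(float)
    if m.any():
        lv = lv - lv[m].mean()
    h, w = lv.shape
    if h < 2 or w < 3:
        return dict.fromkeys(AR_NAMES, np.nan)

    # valid target pixels: rows 1.., cols 1..w-2 so all neighbors exist
    tgt = np.zeros_like(m)
    tgt[1:, 1:-1] = (
        m[1:, 1:-1]
        & m[1:, :-2]      # (x-1, y)
        & m[:-1, :-2]     # (x-1, y-1)
        & m[:-1, 1:-1]    # (x,   y-1)
        & m[:-1, 2:]      # (x+1, y-1)
    )
    n_eq = int(tgt.sum())
    if n_eq < MIN_AR_EQUATIONS:
        return dict.fromkeys(AR_NAMES, np.nan)

    rows, cols = np.nonzero(tgt)
    y = lv[rows, cols]
    design = np.column_stack(
        [
            lv[rows, cols - 1],
            lv[rows - 1, cols - 1],
            lv[rows - 1, cols],
            lv[rows - 1, cols + 1],
        ]
    )
    theta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 4:
        return dict.fromkeys(AR_NAMES, np.nan)
    resid = y - design @ theta
    sigma = float(np.sqrt(np.mean(resid**2)))
    return {"Teta1": float(theta[0]), "Teta2": float(theta[1]),
            "Teta3": float(theta[2]), "Teta4": float(theta[3]), "Sigma": sigma}


# ---------------------------------------------------------------------------
# Haar wavelet energies
# ---------------------------------------------------------------------------

def wavelet_features(q: QuantizedROI) -> dict[str, float]:
    """Mean squared Haar coefficients per subband over the ROI bounding box.

    Out-of-mask pixels inside the bounding box are replaced by the in-mask
    mean to minimize spurious edge energy.  At each scale the current
    approximation is cropped to even dimensions (orthonormal 2x2 Haar
    blocks), so subband energies sum exactly to the input energy; scales
    whose support falls below 2 pixels in either dimension are NaN.

    Subband convention: the first letter is the filter along columns (x),
    the second along rows (y) — HL is the column-difference subband.
    """
    names = [f"WavEn{b}_s-{s}" for s in WAVELET_SCALES for b in WAVELET_SUBBANDS]
    out = dict.fromkeys(names, np.nan)
    m = q.mask
    if not m.any():
        return out
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    box = q.levels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].astype(float)
    box_mask = m[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    fill = q.in_mask_levels.astype(float).mean()
    box = np.where(box_mask, box, fill)

    current = box
    for s in WAVELET_SCALES:
        h, w = current.shape
        h -= h % 2
        w -= w % 2
        if h < 2 or w < 2:
            break
        current = current[:h, :w]
        ca, (ch, cv, cd) = pywt.dwt2(current, "haar", mode="periodization")
        # pywt: ch = detail along rows (y), cv = detail along columns (x)
        out[f"WavEnLL_s-{s}"] = float(np.mean(ca**2))
        out[f"WavEnLH_s-{s}"] = float(np.mean(ch**2))
        out[f"WavEnHL_s-{s}"] = float(np.mean(cv**2))
        out[f"WavEnHH_s-{s}"] = float(np.mean(cd**2))
        current = ca
    return out


# ---------------------------------------------------------------------------
# full vector / cohort
# ---------------------------------------------------------------------------

def feature_names(offsets: tuple[OffsetSpec, ...] = DEFAULT_OFFSETS) -> list[str]:
    """The fixed, documented feature order (275 names by default)."""
    names: list[str] = list(HISTOGRAM_NAMES)
    names += GRADIENT_NAMES
    for off in offsets:
        names += [f"{off.name}{f}" for f in COOC_FEATURE_NAMES]
    for d in RUN_DIRECTIONS:
        names += [f"{f}{d}" for f in RL_FEATURE_NAMES]
    names += AR_NAMES
    names += [f"WavEn{b}_s-{s}" for s in WAVELET_SCALES for b in WAVELET_SUBBANDS]
    return names


def extract_all(
    q: QuantizedROI, offsets: tuple[OffsetSpec, ...] = DEFAULT_OFFSETS
) -> dict[str, float]:
    """Compute the full feature vector for one quantized ROI."""
    out: dict[str, float] = {}
    out.update(histogram_features(q))
    out.update(gradient_features(q))
    for off in offsets:
        feats = cooccurrence_features(cooccurrence_matrix(q, off))
        out.update({f"{off.name}{k}": v for k, v in feats.items()})
    for d in RUN_DIRECTIONS:
        feats = runlength_features(runlength_matrix(q, d))
        out.update({f"{k}{d}": v for k, v in feats.items()})
    out.update(ar_features(q))
    out.update(wavelet_features(q))
    return out


def extract_cohort(
    manifest: pd.DataFrame,
    *,
    ng: int = DEFAULT_NG,
    normalization: str = "mu3sigma",
    offsets: tuple[OffsetSpec, ...] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Extract the feature table for a cohort manifest.

    Returns a DataFrame with columns sample_id, label, then the features in
    the fixed order.  Per-sample family failures become NaN entries; the
    cohort is never aborted by a single sample.
    """
    records = []
    for idx, row in manifest.iterrows():
        image = read_image(row["image_path"])
        mask = read_mask(row["mask_path"], image)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = quantize_roi(image, mask, ng=ng, mode=normalization)
        rec = {"sample_id": f"s{idx:03d}", "label": row["label"]}
        rec.update(extract_all(q, offsets=offsets))
        records.append(rec)
    cols = ["sample_id", "label"] + feature_names(offsets)
    return pd.DataFrame.from_records(records)[cols]


# ---------------------------------------------------------------------------
# feature maps
# ---------------------------------------------------------------------------

_COOC_NAME_RE = re.compile(r"^S\((-?\d+),(-?\d+)\)(\w+)$")


def _single_feature(q: QuantizedROI, name: str) -> float:
    """Compute one named feature on a (small) quantized ROI."""
    if name in HISTOGRAM_NAMES:
        return histogram_features(q)[name]
    if name in GRADIENT_NAMES:
        return gradient_features(q)[name]
    m = _COOC_NAME_RE.match(name)
    if m:
        dx, dy, feat = int(m.group(1)), int(m.group(2)), m.group(3)
        if feat not in COOC_FEATURE_NAMES:
            raise KeyError(f"unknown co-occurrence feature: {name!r}")
        return cooccurrence_features(cooccurrence_matrix(q, OffsetSpec(dx, dy)))[feat]
    for d in RUN_DIRECTIONS:
        if name.endswith(d) and name[: -len(d)] in RL_FEATURE_NAMES:
            return runlength_features(runlength_matrix(q, d))[name[: -len(d)]]
    if name in AR_NAMES:
        return ar_features(q)[name]
    if name.startswith("WavEn"):
        feats = wavelet_features(q)
        if name not in feats:
            raise KeyError(f"unknown wavelet feature: {name!r}")
        return feats[name]
    raise KeyError(f"unknown feature name: {name!r}")


def feature_map(
    image: GrayImage,
    mask: ROIMask,
    feature_name: str,
    window_radius: int,
    *,
    ng: int = DEFAULT_NG,
) -> np.ndarray:
    """Per-pixel texture map: the named feature on each local patch.

    For every in-mask pixel the feature is computed on the surrounding
    (2r+1)^2 patch restricted to in-mask pixels, with patch-local mu +/- 3
    sigma quantization.  Out-of-mask pixels are NaN.  A window larger than
    the ROI bounding box yields an all-NaN map with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _single_feature(quantize_roi(image, mask, ng=ng), feature_name)  # validate name early
    h, w = image.shape
    out = np.full((h, w), np.nan)
    m = mask.pixels
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    side = 2 * window_radius + 1
    if side > (rows[-1] - rows[0] + 1) and side > (cols[-1] - cols[0] + 1):
        warnings.warn("feature-map window exceeds the ROI bounding box; map is all-NaN", stacklevel=2)
        return out
    for r, c in zip(*np.nonzero(m)):
        r0, r1 = max(0, r - window_radius), min(h, r + window_radius + 1)
        c0, c1 = max(0, c - window_radius), min(w, c + window_radius + 1)
        patch_mask = m[r0:r1, c0:c1]
        if patch_mask.sum() < 4 or min(patch_mask.shape) < 2:
            continue
        patch = GrayImage(image.pixels[r0:r1, c0:c1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                q = quantize_roi(patch, ROIMask(patch_mask), ng=ng)
                out[r, c] = _single_feature(q, feature_name)
            except ValueError:
                out[r, c] = np.nan
    return out
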
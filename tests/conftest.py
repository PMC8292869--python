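"""Shared fixtures: deterministic patterns, brute-force oracles, one cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from effusiontex.normalization import QuantizedROI
from effusiontex.synthetic import CohortConfig, generate_cohort_arrays, generate_fixture_patterns


def make_q(levels, ng=None, mask=None) -> QuantizedROI:
    """Build a QuantizedROI directly from an integer level array."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    if ng is None:
        ng = int(levels.max())
    return QuantizedROI(levels=np.where(mask, levels, 0), ng=ng, mask=mask)


@pytest.fixture(scope="session")
def patterns():
    return generate_fixture_patterns()


# ---------------------------------------------------------------------------
# independent brute-force oracles (pure-python loops, no shared code paths)
# ---------------------------------------------------------------------------

def brute_cooccurrence(levels, mask, dx, dy, ng):
    """Exhaustive symmetrized pair enumeration."""
    h, w = levels.shape
    p = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dy, c + dx
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                i, j = levels[r, c] - 1, levels[rr, cc] - 1
                p[i, j] += 1
                p[j, i] += 1
    s = p.sum()
    return p / s if s else p


def brute_cooc_features(p):
    """Direct double-loop evaluation of the 11 co-occurrence features."""
    ng = p.shape[0]
    out = {}
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["AngScMom"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["SumOfSqs"] = sigma2
    out["InvDfMom"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    if sigma2 > 0:
        out["Correlat"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)) - mu * mu
        ) / sigma2
    else:
        out["Correlat"] = np.nan
    psum = {}
    pdif = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdif[abs(i - j)] = pdif.get(abs(i - j), 0.0) + p[i, j]
    sa = sum(k * v for k, v in psum.items())
    out["SumAverg"] = sa
    out["SumVarnc"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    out["SumEntrp"] = -sum(v * np.log(v) for v in psum.values() if v > 0)
    dm = sum(k * v for k, v in pdif.items())
    out["DifVarnc"] = sum((k - dm) ** 2 * v for k, v in pdif.items())
    out["DifEntrp"] = -sum(v * np.log(v) for v in pdif.values() if v > 0)
    out["Entropy"] = -sum(
        p[i, j] * np.log(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    return out


def brute_runs(levels, mask, direction):
    """Explicit run scanner over the lines of one direction."""
    h, w = levels.shape
    if direction == "Horzl":
        lines = [[(r, c) for c in range(w)] for r in range(h)]
    elif direction == "Vertl":
        lines = [[(r, c) for r in range(h)] for c in range(w)]
    elif direction == "135dgr":
        lines = [
            [(r, c) for r in range(h) for c in range(w) if c - r == k]
            for k in range(-(h - 1), w)
        ]
    else:  # 45dgr: up-right
        lines = [
            [(r, c) for r in sorted(range(h), reverse=True) for c in range(w) if r + c == k]
            for k in range(h + w - 1)
        ]
    runs = []
    for line in lines:
        cur_level, cur_len = None, 0
        for r, c in line:
            g = levels[r, c] if mask[r, c] else None
            if g is not None and g == cur_level:
                cur_len += 1
            else:
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = g, (1 if g is not None else 0)
        if cur_level is not None:
            runs.append((cur_level, cur_len))
    return runs


def brute_rl_features(runs, n_pixels):
    total = len(runs)
    if total == 0:
        return None
    lengths = [l for _, l in runs]
    from collections import Counter

    by_level = Counter(g for g, _ in runs)
    by_length = Counter(lengths)
    return {
        "ShrtREmp": sum(1 / l**2 for l in lengths) / total,
        "LngREmph": sum(l**2 for l in lengths) / total,
        "GLevNonU": sum(v**2 for v in by_level.values()) / total,
        "RLNonUni": sum(v**2 for v in by_length.values()) / total,
        "Fraction": total / n_pixels,
    }


def brute_auc(values, is_positive):
    """Pair-counting AUC: P(pos > neg) + half ties."""
    pos = values[is_positive]
    neg = values[~is_positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def oracles():
    return {
        "cooc_matrix": brute_cooccurrence,
        "cooc_features": brute_cooc_features,
        "runs": brute_runs,
        "rl_features": brute_rl_features,
        "auc": brute_auc,
    }


# ---------------------------------------------------------------------------
# one shared default cohort (the study conditions: 29 benign + 23 malignant)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort_table():
    from effusiontex.normalization import quantize_roi
    from effusiontex.texture import extract_all, feature_names

    import pandas as pd

    samples = generate_cohort_arrays(CohortConfig(seed=11))
    rows = []
    for i, (img, mask, label) in enumerate(samples):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = quantize_roi(img, mask)
        rec = {"sample_id": f"s{i:03d}", "label": label}
        rec.update(extract_all(q))
        rows.append(rec)
    return pd.DataFrame.from_records(rows)[["sample_id", "label"] + feature_names()]
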
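"""End-to-end orchestration: cohort -> features -> selection -> k-NN -> stats.

A run consumes either an existing cohort manifest or a synthetic cohort
configuration, then reproduces the four analysis steps — mu +/- 3 sigma
quantization, six-family feature extraction, Fisher and POE+ACC selection of
ten features each, leave-one-out k-NN classification and the Mann-Whitney /
ROC screen — writing features.csv, selection.json, classifier_<method>.json,
stats.json and a plain-text log.  All randomness flows from the single
configured seed, so re-running a config reproduces every artifact exactly.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierConfig, knn_loocv
from .io import read_manifest, write_feature_table
from .normalization import DEFAULT_NG
from .selection import SelectionResult, poe_acc_select, rank_by_fisher
from .stats import univariate_screen
from .synthetic import ClassSpec, CohortConfig, generate_cohort
from .texture import extract_cohort

__all__ = ["RunConfig", "run", "load_config"]


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``manifest`` (path to an existing cohort CSV) or
    ``cohort`` (synthetic cohort spec) must be set.
    """

    out_dir: str
    manifest: str | None = None
    cohort: CohortConfig | None = None
    ng: int = DEFAULT_NG
    normalization: str = "mu3sigma"
    selection_methods: tuple[str, ...] = ("fisher", "poe_acc")
    n_select: int = 10
    k: int = 1
    positive_label: str = "malignant"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.cohort is None):
            raise ValueError("set exactly one of 'manifest' or 'cohort'")
        unknown = set(self.selection_methods) - {"fisher", "poe_acc"}
        if unknown:
            raise ValueError(f"unknown selection methods: {sorted(unknown)}")


def load_config(path: str | os.PathLike) -> RunConfig:
    """Read a RunConfig from TOML."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cohort = None
    if "cohort" in raw:
        c = raw["cohort"]
        specs = tuple(ClassSpec(**s) for s in c.pop("class_specs", []))
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in c.items()
        }
        if specs:
            kwargs["class_specs"] = specs
        cohort = CohortConfig(seed=raw.get("seed", 0), **kwargs)
    run_keys = {
        k: raw[k]
        for k in (
            "out_dir", "manifest", "ng", "normalization", "n_select",
            "k", "positive_label", "alpha", "seed",
        )
        if k in raw
    }
    if "selection_methods" in raw:
        run_keys["selection_methods"] = tuple(raw["selection_methods"])
    return RunConfig(cohort=cohort, **run_keys)


def _select(method: str, table: pd.DataFrame, n: int) -> SelectionResult:
    if method == "fisher":
        return rank_by_fisher(table, n)
    return poe_acc_select(table, n)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable run report."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines = [
        f"effusiontex {__version__} (python {sys.version.split()[0]}, numpy {np.__version__})",
        f"seed {config.seed}",
    ]

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("cohort")
        if config.cohort is not None:
            cohort_cfg = CohortConfig(
                n_per_class=config.cohort.n_per_class,
                image_size=config.cohort.image_size,
                roi_axes_range=config.cohort.roi_axes_range,
                seed=config.seed,
                class_specs=config.cohort.class_specs,
            )
            generate_cohort(cohort_cfg, os.path.join(config.out_dir, "images"))
            manifest = read_manifest(os.path.join(config.out_dir, "images", "manifest.csv"))
        else:
            manifest = read_manifest(config.manifest)
        log_lines.append(f"samples: {len(manifest)}")

        stage("extract")
        table = extract_cohort(manifest, ng=config.ng, normalization=config.normalization)
        features_path = os.path.join(config.out_dir, "features.csv")
        write_feature_table(table, features_path)

        stage("select")
        selections = [_select(m, table, config.n_select) for m in config.selection_methods]
        with open(os.path.join(config.out_dir, "selection.json"), "w") as fh:
            json.dump([s.to_dict() for s in selections], fh, indent=2, sort_keys=True)

        stage("classify")
        clf_cfg = ClassifierConfig(k=config.k, positive_label=config.positive_label)
        reports = {}
        for sel in selections:
            rep = knn_loocv(table, sel.feature_names, clf_cfg)
            reports[sel.method] = rep
            with open(os.path.join(config.out_dir, f"classifier_{sel.method}.json"), "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)

        stage("stats")
        screen = univariate_screen(
            table, selections, alpha=config.alpha, positive_label=config.positive_label
        )
        with open(os.path.join(config.out_dir, "stats.json"), "w") as fh:
            json.dump([r.to_dict() for r in screen], fh, indent=2, sort_keys=True)
    except Exception as exc:
        log_lines.append(f"FAILED: {exc}")
        with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {log_lines[-2].split(': ')[-1]!r} failed") from exc

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": int(len(manifest)),
        "n_features": int(table.shape[1] - 2),
        "selections": {s.method: s.feature_names for s in selections},
        "classifiers": {m: r.to_dict() for m, r in reports.items()},
        "univariate": [r.to_dict() for r in screen],
        "artifacts": {
            "features": "features.csv",
            "selection": "selection.json",
            "stats": "stats.json",
            "classifiers": {m: f"classifier_{m}.json" for m in reports},
        },
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log_lines.append("done")
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
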
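"""End-to-end pipeline: simulate/load -> extract -> compare -> classify -> report.

A run is described by a plain dictionary (usually loaded from YAML) with a
``simulate`` block or an ``input`` block, plus optional ``compare`` and
``classify`` blocks.  Everything downstream of the configuration and seed is
deterministic, and every number in the report is recomputable from the
intermediate files written to the output directory.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as wio
from .bands import compare_groups, significant_regions
from .classify import (
    ConfusionMatrix,
    fit_pca,
    loocv_classify,
    matrix_summaries,
    pairwise_metrics,
    project,
)
from .extract import SpectraDataset
from .simulate import (
    AcquisitionConfig,
    BackgroundModel,
    CellClassModel,
    DonorEffect,
    RamanPeak,
    default_cell_classes,
    default_donors,
    generate_dataset,
)

__all__ = ["RunReport", "run_pipeline", "load_config", "default_config", "build_simulation"]

logger = logging.getLogger("wmrs")


@dataclass
class RunReport:
    """Everything a run produced, with pointers to the stored intermediates."""

    parameters: dict[str, Any]
    n_cells: int
    class_counts: dict[str, int]
    explained_variance_ratios: list[float]
    confusion: ConfusionMatrix
    accuracy: float
    per_class_recall: dict[str, float]
    pairwise: list[dict[str, Any]] = field(default_factory=list)
    comparisons: list[dict[str, Any]] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "parameters": self.parameters,
            "n_cells": self.n_cells,
            "class_counts": self.class_counts,
            "explained_variance_ratios": self.explained_variance_ratios,
            "confusion": {
                "class_order": list(self.confusion.class_order),
                "counts": self.confusion.counts.tolist(),
            },
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "pairwise": self.pairwise,
            "comparisons": self.comparisons,
            "outputs": self.outputs,
        }


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_config(n_cells_per_class: int = 60, seed: int = 0) -> dict[str, Any]:
    """The bundled three-class simulation configuration."""
    return {
        "seed": seed,
        "simulate": {
            "classes": "default",
            "donors": "default",
            "n_cells_per_class": n_cells_per_class,
            "acquisition": {},
        },
        "compare": {"alpha": 1e-7, "min_run": 3},
        "classify": {"n_components": 7, "refit_per_fold": True},
    }


def _classes_from_config(spec: Any) -> list[CellClassModel]:
    if spec in (None, "default"):
        return default_cell_classes()
    classes = []
    for c in spec:
        bg = c.get("background")
        background = (
            BackgroundModel(
                kind=bg.get("kind", "gaussian"),
                coefficients=tuple(bg.get("coefficients", (1300.0, 450.0))),
                scale=float(bg.get("scale", 10.0)),
            )
            if bg
            else None
        )
        peaks = tuple(
            RamanPeak(
                center=float(p["center"]),
                width=float(p.get("width", 8.0)),
                amplitude=float(p.get("amplitude", 1.0)),
            )
            for p in c["peaks"]
        )
        classes.append(
            CellClassModel(
                name=str(c["name"]),
                peaks=peaks,
                background=background,
                amplitude_cv=float(c.get("amplitude_cv", 0.0)),
                noise_sigma=float(c.get("noise_sigma", 0.0)),
            )
        )
    return classes


def _donors_from_config(spec: Any) -> list[DonorEffect]:
    if spec in (None, "default"):
        return default_donors()
    return [
        DonorEffect(
            donor_id=str(d["donor_id"]),
            background_scale_mult=float(d.get("background_scale_mult", 1.0)),
            global_gain=float(d.get("global_gain", 1.0)),
        )
        for d in spec
    ]


def build_simulation(block: dict[str, Any], seed: int):
    """Build (stacks, acquisition) from a ``simulate`` config block."""
    acq = AcquisitionConfig(**(block.get("acquisition") or {}))
    classes = _classes_from_config(block.get("classes"))
    donors = _donors_from_config(block.get("donors"))
    stacks = generate_dataset(
        classes,
        int(block.get("n_cells_per_class", 60)),
        donors,
        acq=acq,
        seed=seed,
    )
    return stacks, acq


def run_pipeline(
    config: dict[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> RunReport:
    """Execute the full analysis described by ``config``.

    Stages: obtain modulation stacks (simulate or read), extract modulated
    spectra, pairwise band comparison for every class pair, PCA + LOOCV
    classification, pairwise sensitivity/specificity, and a JSON report.
    ``seed`` overrides ``config["seed"]``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    outputs: dict[str, str] = {}

    t0 = time.perf_counter()
    if "simulate" in config:
        stacks, _ = build_simulation(config["simulate"], seed)
        logger.info(
            "stage=simulate n_cells=%d elapsed=%.2fs", len(stacks), time.perf_counter() - t0
        )
    elif "input" in config:
        stacks = wio.read_dataset(config["input"]["spectra"], config["input"]["manifest"])
        logger.info(
            "stage=read n_cells=%d elapsed=%.2fs", len(stacks), time.perf_counter() - t0
        )
    else:
        raise ValueError("config must contain a 'simulate' or an 'input' block")

    t0 = time.perf_counter()
    try:
        dataset = SpectraDataset.from_stacks(stacks)
    except ValueError as exc:
        raise ValueError(f"stage=extract failed: {exc}") from exc
    mod_path = out / "modulated_spectra.csv"
    wio.write_modulated_spectra(dataset, mod_path)
    outputs["modulated_spectra"] = str(mod_path)
    logger.info("stage=extract n_cells=%d elapsed=%.2fs", len(dataset), time.perf_counter() - t0)

    class_order = list(dict.fromkeys(dataset.class_labels()))
    class_counts = {c: dataset.class_labels().count(c) for c in class_order}

    # --- band comparisons for every class pair -----------------------------
    comparisons: list[dict[str, Any]] = []
    cmp_cfg = config.get("compare", {}) or {}
    alpha = float(cmp_cfg.get("alpha", 1e-7))
    min_run = int(cmp_cfg.get("min_run", 3))
    if len(class_order) >= 2 and cmp_cfg.get("enabled", True):
        t0 = time.perf_counter()
        sig_frames = []
        for a, b in itertools.combinations(class_order, 2):
            sigmap = compare_groups(
                dataset.select_classes(a), dataset.select_classes(b), alpha=alpha
            )
            regions = significant_regions(sigmap, min_run=min_run)
            comparisons.append(
                {
                    "classes": [a, b],
                    "alpha": alpha,
                    "n_significant_bins": int(sigmap.mask.sum()),
                    "regions": [
                        {
                            "start": r.start,
                            "end": r.end,
                            "n_bins": r.n_bins,
                            "min_p": r.min_p,
                        }
                        for r in regions
                    ],
                }
            )
            sig_frames.append(
                pd.DataFrame(
                    {
                        "comparison": f"{a}_vs_{b}",
                        "axis_cm1": sigmap.axis,
                        "t": sigmap.t_values,
                        "p": sigmap.p_values,
                        "significant": sigmap.mask,
                    }
                )
            )
        sig_path = out / "significance.csv"
        pd.concat(sig_frames, ignore_index=True).to_csv(sig_path, index=False)
        outputs["significance"] = str(sig_path)
        logger.info(
            "stage=compare pairs=%d alpha=%g elapsed=%.2fs",
            len(comparisons), alpha, time.perf_counter() - t0,
        )

    # --- PCA + LOOCV classification ----------------------------------------
    cls_cfg = config.get("classify", {}) or {}
    n_components = int(cls_cfg.get("n_components", 7))
    refit = bool(cls_cfg.get("refit_per_fold", True))
    t0 = time.perf_counter()
    try:
        full_pca = fit_pca(dataset, n_components=n_components)
        predictions, cm = loocv_classify(
            dataset, n_components=n_components, refit_per_fold=refit
        )
    except ValueError as exc:
        raise ValueError(f"stage=classify failed: {exc}") from exc
    scores = project(full_pca, dataset.matrix())
    score_frame = pd.DataFrame(
        scores, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    score_frame.insert(0, "cell_id", dataset.cell_ids())
    score_frame.insert(1, "class_label", dataset.class_labels())
    score_frame.insert(2, "predicted_label", predictions)
    scores_path = out / "scores.csv"
    score_frame.to_csv(scores_path, index=False)
    outputs["scores"] = str(scores_path)

    cm_frame = pd.DataFrame(
        cm.counts,
        index=[f"actual_{c}" for c in cm.class_order],
        columns=[f"predicted_{c}" for c in cm.class_order],
    )
    cm_path = out / "confusion_matrix.csv"
    cm_frame.to_csv(cm_path)
    outputs["confusion_matrix"] = str(cm_path)

    total, accuracy, recalls = matrix_summaries(cm)
    logger.info(
        "stage=classify n_components=%d accuracy=%.3f elapsed=%.2fs",
        n_components, accuracy, time.perf_counter() - t0,
    )

    pairwise: list[dict[str, Any]] = []
    if len(class_order) >= 2:
        for a, b in itertools.combinations(class_order, 2):
            pm = pairwise_metrics(
                dataset.select_classes(a, b),
                n_components=n_components,
                positive_class=a,
                refit_per_fold=refit,
            )
            pairwise.append(
                {
                    "positive_class": pm.positive_class,
                    "negative_class": pm.negative_class,
                    "sensitivity": pm.sensitivity,
                    "specificity": pm.specificity,
                    "n_positive": pm.n_positive,
                    "n_negative": pm.n_negative,
                }
            )

    report = RunReport(
        parameters={
            "seed": seed,
            "alpha": alpha,
            "min_run": min_run,
            "n_components": n_components,
            "refit_per_fold": refit,
        },
        n_cells=total,
        class_counts=class_counts,
        explained_variance_ratios=[float(v) for v in full_pca.explained_variance_ratios],
        confusion=cm,
        accuracy=accuracy,
        per_class_recall=recalls,
        pairwise=pairwise,
        comparisons=comparisons,
        outputs=outputs,
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    report.outputs["report"] = str(report_path)
    return report
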
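"""File formats: CSV spectra + manifest, JSON bundles, JCAMP-DX single spectra.

The interchange format for modulation stacks is a pair of plain-text files:

* a *spectra* CSV whose header row holds the Raman-shift axis values and
  whose data rows each hold one step spectrum of one cell;
* a *manifest* CSV with one row per (cell, step):
  ``cell_id, class_label, donor_id, step_index, excitation_nm,
  spectrum_row_index``.

A single-file JSON *bundle* carrying the axis, the manifest fields and the
intensity matrix together is provided for round-tripping.  A minimal
JCAMP-DX reader covers single conventional spectra in the common
``(X++(Y..Y))`` and ``(XY..XY)`` layouts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import ModulatedSpectrum, SpectraDataset
from .simulate import ModulationStack

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_bundle",
    "read_bundle",
    "write_modulated_spectra",
    "read_modulated_spectra",
    "read_jcamp",
]

MANIFEST_COLUMNS = (
    "cell_id",
    "class_label",
    "donor_id",
    "step_index",
    "excitation_nm",
    "spectrum_row_index",
)


def write_dataset(
    stacks: Sequence[ModulationStack],
    spectra_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Write stacks as a spectra CSV plus a manifest CSV."""
    if not stacks:
        raise ValueError("no stacks to write")
    axis = stacks[0].axis
    rows = []
    manifest = []
    row_index = 0
    for stack in stacks:
        if not np.array_equal(stack.axis, axis):
            raise ValueError(f"cell {stack.cell_id!r} is not on the shared axis")
        for k in range(stack.n_steps):
            rows.append(stack.intensities[k])
            manifest.append(
                (
                    stack.cell_id,
                    stack.class_label,
                    stack.donor_id,
                    k,
                    stack.excitations[k],
                    row_index,
                )
            )
            row_index += 1
    spectra = pd.DataFrame(np.vstack(rows), columns=[repr(float(v)) for v in axis])
    spectra.to_csv(spectra_path, index=False)
    pd.DataFrame(manifest, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)


def read_dataset(
    spectra_path: str | Path, manifest_path: str | Path
) -> list[ModulationStack]:
    """Assemble and validate modulation stacks from a spectra/manifest pair."""
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError("no cells: the manifest is empty")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    spectra = pd.read_csv(spectra_path)
    axis = np.array([float(c) for c in spectra.columns])
    values = spectra.to_numpy(dtype=float)

    if manifest.duplicated(["cell_id", "step_index"]).any():
        dup = manifest[manifest.duplicated(["cell_id", "step_index"])].iloc[0]
        raise ValueError(
            f"duplicate step {int(dup.step_index)} for cell {dup.cell_id!r}"
        )
    idx = manifest["spectrum_row_index"].to_numpy()
    if idx.min() < 0 or idx.max() >= len(values) or len(np.unique(idx)) != len(idx):
        raise ValueError("spectrum_row_index values must be unique and in range")

    expected_steps = sorted(manifest["step_index"].unique())
    stacks: list[ModulationStack] = []
    for cell_id, grp in manifest.groupby("cell_id", sort=False):
        steps = sorted(grp["step_index"])
        if steps != expected_steps:
            raise ValueError(
                f"cell {cell_id!r} has steps {steps}, expected {expected_steps}"
            )
        if grp["class_label"].nunique() != 1 or grp["donor_id"].nunique() != 1:
            raise ValueError(f"cell {cell_id!r} has inconsistent labels across steps")
        grp = grp.sort_values("step_index")
        stacks.append(
            ModulationStack(
                cell_id=str(cell_id),
                class_label=str(grp["class_label"].iloc[0]),
                donor_id=str(grp["donor_id"].iloc[0]),
                axis=axis,
                intensities=values[grp["spectrum_row_index"].to_numpy()],
                excitations=grp["excitation_nm"].to_numpy(dtype=float),
            )
        )
    return stacks


def write_bundle(stacks: Sequence[ModulationStack], path: str | Path) -> None:
    """Write a single-file JSON container: axis + manifest + intensities."""
    if not stacks:
        raise ValueError("no stacks to write")
    axis = stacks[0].axis
    payload = {
        "axis_cm1": axis.tolist(),
        "cells": [
            {
                "cell_id": s.cell_id,
                "class_label": s.class_label,
                "donor_id": s.donor_id,
                "excitations_nm": s.excitations.tolist(),
                "intensities": s.intensities.tolist(),
            }
            for s in stacks
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_bundle(path: str | Path) -> list[ModulationStack]:
    payload = json.loads(Path(path).read_text())
    axis = np.asarray(payload["axis_cm1"], dtype=float)
    if not payload.get("cells"):
        raise ValueError("no cells: the bundle is empty")
    return [
        ModulationStack(
            cell_id=c["cell_id"],
            class_label=c["class_label"],
            donor_id=c["donor_id"],
            axis=axis,
            intensities=np.asarray(c["intensities"], dtype=float),
            excitations=np.asarray(c["excitations_nm"], dtype=float),
        )
        for c in payload["cells"]
    ]


def write_modulated_spectra(dataset: SpectraDataset, path: str | Path) -> None:
    """Write a dataset of modulated spectra as one wide CSV."""
    meta = pd.DataFrame(
        {
            "cell_id": dataset.cell_ids(),
            "class_label": dataset.class_labels(),
            "donor_id": dataset.donor_ids(),
            "explained_variance_ratio": [
                s.explained_variance_ratio for s in dataset.spectra
            ],
        }
    )
    values = pd.DataFrame(dataset.matrix(), columns=[repr(float(v)) for v in dataset.axis])
    pd.concat([meta, values], axis=1).to_csv(path, index=False)


def read_modulated_spectra(path: str | Path) -> SpectraDataset:
    frame = pd.read_csv(path)
    meta_cols = ["cell_id", "class_label", "donor_id", "explained_variance_ratio"]
    axis = np.array([float(c) for c in frame.columns if c not in meta_cols])
    spectra = [
        ModulatedSpectrum(
            cell_id=str(row["cell_id"]),
            class_label=str(row["class_label"]),
            donor_id=str(row["donor_id"]),
            axis=axis,
            values=row.drop(meta_cols).to_numpy(dtype=float),
            explained_variance_ratio=float(row["explained_variance_ratio"]),
        )
        for _, row in frame.iterrows()
    ]
    return SpectraDataset(spectra)


def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrum from a JCAMP-DX file.

    Supports the common uncompressed layouts ``##XYDATA=(X++(Y..Y))`` (one
    abscissa then a run of ordinates per line, with ``XFACTOR``/``YFACTOR``
    applied) and ``##XYPOINTS=(XY..XY)``.  Compressed ordinate forms
    (SQZ/DIF/DUP) are not supported.  Returns ``(x, y)`` arrays.
    """
    text = Path(path).read_text()
    headers: dict[str, str] = {}
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                continue
            if key == "XYPOINTS":
                mode = "xypoints"
                continue
            if key == "END":
                break
            headers[key] = value
            mode = None
            continue
        tokens = line.replace(",", " ").replace(";", " ").split()
        if mode == "xydata":
            vals = [float(t) for t in tokens]
            x0 = vals[0]
            xfac = float(headers.get("XFACTOR", 1.0))
            if "DELTAX" in headers:
                dx = float(headers["DELTAX"]) / xfac  # DELTAX is in final units
            else:
                dx = _deltax_from_headers(headers)
            for j, y in enumerate(vals[1:]):
                xs.append(x0 + j * dx)
                ys.append(y)
        elif mode == "xypoints":
            vals = [float(t) for t in tokens]
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    if not xs:
        raise ValueError(f"no spectral data found in {path}")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    x = np.asarray(xs) * xfactor
    y = np.asarray(ys) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return x, y


def _deltax_from_headers(headers: dict[str, str]) -> float:
    try:
        first = float(headers["FIRSTX"])
        last = float(headers["LASTX"])
        npoints = int(float(headers["NPOINTS"]))
    except KeyError as exc:
        raise ValueError("JCAMP file lacks DELTAX and FIRSTX/LASTX/NPOINTS") from exc
    if npoints < 2:
        raise ValueError("NPOINTS must be >= 2")
    # raw (pre-XFACTOR) spacing
    xfactor = float(headers.get("XFACTOR", 1.0))
    return (last - first) / (npoints - 1) / xfactor
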
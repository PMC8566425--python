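"""File formats for pipeline artifacts.

Scenes are RGB TIFF plus a compartment label TIFF (0=FSR, 1=PE, 2=ILS) and
a cells CSV; tables are CSV/TSV; configs are YAML.  Everything written here
can be read back to reproduce a stage from saved intermediates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mammilieu.masks import CompartmentMask, LABEL_NAMES
from mammilieu.detection import DetectedCell
from mammilieu.simulate.scene import GroundTruth

__all__ = [
    "write_scene",
    "read_scene_image",
    "read_label_mask",
    "cells_to_frame",
    "write_cells_csv",
    "write_yaml",
    "read_yaml",
]


def write_scene(out_dir, image_id: str, rgb: np.ndarray, truth: GroundTruth) -> dict[str, Path]:
    """Write one scene: RGB TIFF, label TIFF, truth-cells CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{image_id}.tiff",
        "labels": out / f"{image_id}_labels.tiff",
        "cells": out / f"{image_id}_cells.csv",
    }
    tifffile.imwrite(paths["image"], rgb)
    tifffile.imwrite(paths["labels"], truth.compartment_mask.labels)
    rows = [
        {
            "id": c.id,
            "x_px": c.centroid_px[1],
            "y_px": c.centroid_px[0],
            "diameter_um": c.diameter_um,
            "class": c.true_class,
            "compartment": c.true_compartment,
        }
        for c in truth.cells + truth.speckles + truth.debris
    ]
    pd.DataFrame(rows).to_csv(paths["cells"], index=False)
    return paths


def read_scene_image(path) -> np.ndarray:
    return tifffile.imread(path)


def read_label_mask(path, pixel_size_um: float = 0.465) -> CompartmentMask:
    return CompartmentMask(labels=tifffile.imread(path), pixel_size_um=pixel_size_um)


def cells_to_frame(cells: list[DetectedCell], image_id: str = "") -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "image_id": image_id,
            "cell_id": c.id,
            "x_px": c.centroid_px[1],
            "y_px": c.centroid_px[0],
            "diameter_um": c.equivalent_diameter_um,
            "class": c.cell_class,
            "compartment": c.compartment,
        }
        for marker, flag in c.positivity.items():
            row[f"{marker}_pos"] = flag
            row[f"{marker}_mean_intensity"] = c.mean_intensity.get(marker, np.nan)
        rows.append(row)
    if not rows:  # keep the schema even for cell-free images
        return pd.DataFrame(
            columns=["image_id", "cell_id", "x_px", "y_px", "diameter_um", "class", "compartment"]
        )
    return pd.DataFrame(rows)


def write_cells_csv(cells: list[DetectedCell], path, image_id: str = "") -> None:
    cells_to_frame(cells, image_id).to_csv(path, index=False)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
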
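"""Reading field-of-view images and writing segmentation outputs.

A *field* is one transmitted-illumination (bright-field) image plus zero,
one or two nuclear-fluorescence channels (e.g. CFP/YFP) registered to the
same frame.  All channels are promoted to float64 on load -- the focus
complement ``j = 2*mu_B - i`` can leave the input range, so integer bit
depth only matters on output.

Coordinate convention used throughout the package: 0-based pixel grid,
row-major arrays, ``x`` = column, ``y`` = row, polygon vertices at pixel
centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import tifffile

from .validate import CellRecord, FEATURE_NAMES


class ShapeMismatchError(ValueError):
    """Channels of one field do not share a common height x width."""


@dataclass
class FieldImages:
    """Registered channels of one field of view.

    ``trans`` is the bright-field channel; ``fluor`` holds 0..2 nuclear
    fluorescence channels of identical shape.
    """

    trans: np.ndarray
    fluor: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=np.float64)
        if self.trans.ndim != 2:
            raise ValueError(f"trans must be 2D, got shape {self.trans.shape}")
        if not np.all(np.isfinite(self.trans)):
            raise ValueError("trans contains non-finite values")
        self.fluor = [np.asarray(f, dtype=np.float64) for f in self.fluor]
        for i, f in enumerate(self.fluor):
            if f.shape != self.trans.shape:
                raise ShapeMismatchError(
                    f"fluorescence channel {i} has shape {f.shape}, "
                    f"trans has shape {self.trans.shape}"
                )

    @property
    def shape(self) -> tuple:
        return self.trans.shape


def _read_plane(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, "
                         f"got shape {arr.shape}")
    return arr.astype(np.float64)


def read_field(trans_path: str | Path,
               fluor_paths: Sequence[str | Path] = ()) -> FieldImages:
    """Load one field of view from single-plane grayscale TIFFs.

    Parameters
    ----------
    trans_path : path
        Transmitted-illumination channel.
    fluor_paths : sequence of paths
        Zero to two nuclear-fluorescence channels registered to the same
        frame.

    Raises
    ------
    ShapeMismatchError
        If any fluorescence channel's shape differs from the trans channel.
    """
    trans = _read_plane(trans_path)
    fluor = [_read_plane(p) for p in fluor_paths]
    return FieldImages(trans=trans, fluor=fluor)


def write_results(records: Sequence[CellRecord], label_mask: np.ndarray,
                  out_dir: str | Path) -> dict:
    """Write the segmentation of one field to ``out_dir``.

    Outputs ``labels.tif`` (16-bit instance label mask, 0 = background,
    k = cell k), ``cells.json`` (one record per contour: id, vertices,
    verdict, features) and ``features.csv`` (per-cell feature table).

    Returns a dict of the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    label_mask = np.asarray(label_mask)
    if label_mask.min() < 0 or label_mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask values must fit in uint16")
    mask_path = out / "labels.tif"
    tifffile.imwrite(str(mask_path), label_mask.astype(np.uint16))

    cells = []
    rows = []
    for i, rec in enumerate(records, start=1):
        verts = np.asarray(rec.contour.vertices, dtype=float)
        cells.append({
            "id": i,
            "vertices": [[float(x), float(y)] for x, y in verts],
            "verdict": rec.verdict,
            "features": {k: float(v)
                         for k, v in zip(FEATURE_NAMES, rec.features)},
        })
        rows.append({"id": i, "verdict": rec.verdict,
                     **{k: float(v)
                        for k, v in zip(FEATURE_NAMES, rec.features)}})

    json_path = out / "cells.json"
    with open(json_path, "w") as fh:
        json.dump({"cells": cells}, fh, indent=1)

    csv_path = out / "features.csv"
    columns = ["id", "verdict", *FEATURE_NAMES]
    pd.DataFrame(rows, columns=columns).to_csv(csv_path, index=False)

    return {"labels": mask_path, "cells": json_path, "features": csv_path}


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read back an instance label mask written by :func:`write_results`."""
    return tifffile.imread(str(path)).astype(np.int_)
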
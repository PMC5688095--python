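"""Reading and writing samples, feature tables and truth sidecars.

A sample on disk is a directory holding

- ``cells.tif``      multi-page TIFF, pages ordered cell-major (cell 0
  channel 0, cell 0 channel 1, ..., cell 1 channel 0, ...);
- ``manifest.json``  channel names and roles in acquisition order;
- ``truth.csv``      optional ground-truth table from the simulator.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import CellImage

__all__ = ["write_sample", "read_sample", "write_manifest", "read_manifest"]


def write_manifest(path, channel_names: Sequence[str], roles: Sequence[str],
                   n_cells: int) -> None:
    doc = {
        "channels": [
            {"name": n, "role": r} for n, r in zip(channel_names, roles)
        ],
        "n_cells": int(n_cells),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_manifest(path) -> dict:
    doc = json.loads(Path(path).read_text())
    doc["channel_names"] = tuple(c["name"] for c in doc["channels"])
    doc["roles"] = tuple(c["role"] for c in doc["channels"])
    return doc


def write_sample(directory, cells: Sequence[CellImage],
                 truth: Optional[pd.DataFrame] = None) -> Path:
    """Write a sample directory (TIFF stack, manifest, optional truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not cells:
        raise ValueError("cannot write an empty sample")
    names, roles = cells[0].channel_names, cells[0].roles
    stack = np.concatenate([c.pixels for c in cells], axis=0).astype(np.float32)
    tifffile.imwrite(directory / "cells.tif", stack)
    write_manifest(directory / "manifest.json", names, roles, len(cells))
    if truth is not None:
        truth.to_csv(directory / "truth.csv")
    return directory


def read_sample(directory):
    """Read a sample directory back into ``(cells, manifest, truth_or_None)``."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.json")
    stack = tifffile.imread(directory / "cells.tif").astype(float)
    k = len(manifest["channel_names"])
    n = manifest["n_cells"]
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != n * k:
        raise ValueError(
            f"TIFF has {stack.shape[0]} pages, expected {n} cells x {k} channels"
        )
    cells = [
        CellImage(stack[i * k : (i + 1) * k], manifest["channel_names"],
                  manifest["roles"])
        for i in range(n)
    ]
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path, index_col=0) if truth_path.exists() else None
    return cells, manifest, truth
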
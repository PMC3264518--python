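"""Reading and writing tiles, truth sidecars and result tables.

On disk a plant is a directory with ``total/`` and ``filled/`` tile
subfolders of 8-bit grayscale PNG or TIFF frames named ``tile_NN.png``,
plus an optional ``truth.json`` sidecar written by the simulator.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .segmentation import DEFAULT_MM_PER_PX, GrayTile

TILE_EXTENSIONS = (".png", ".tif", ".tiff")


def write_tile(path: str | Path, tile: GrayTile) -> None:
    Image.fromarray(tile.pixels, mode="L").save(path)


def read_tile(
    path: str | Path, tile_index: int = 0, mm_per_px: float = DEFAULT_MM_PER_PX
) -> GrayTile:
    with Image.open(path) as img:
        pixels = np.asarray(img.convert("L"), dtype=np.uint8)
    return GrayTile(pixels, tile_index=tile_index, mm_per_px=mm_per_px)


def write_series(directory: str | Path, tiles: list[GrayTile]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tile in tiles:
        write_tile(directory / f"tile_{tile.tile_index:02d}.png", tile)


def read_series(
    directory: str | Path, mm_per_px: float = DEFAULT_MM_PER_PX
) -> list[GrayTile]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"tile series directory not found: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in TILE_EXTENSIONS
    )
    if not paths:
        raise FileNotFoundError(f"no tiles in {directory}")
    return [read_tile(p, i, mm_per_px) for i, p in enumerate(paths)]


def write_truth(path: str | Path, truth_dict: dict) -> None:
    Path(path).write_text(json.dumps(truth_dict, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def append_records_csv(path: str | Path, rows: list[dict]) -> None:
    """Append plant records to a CSV results file keyed by barcode."""
    path = Path(path)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, mode="a", header=not path.exists(), index=False)
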
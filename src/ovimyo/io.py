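"""File I/O: images (TIFF/PNG), TSV tables, GMT gene sets."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .morphometry import FiberRegion, ImageGrid

__all__ = [
    "read_image",
    "write_image",
    "read_gmt",
    "write_gmt",
    "regions_to_table",
    "write_region_table",
    "write_json",
]


def read_image(path, um_per_px: Optional[float] = None) -> ImageGrid:
    """Read a TIFF or PNG image (8/16-bit, grayscale or RGB)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    bit_depth = 16 if np.asarray(pixels).dtype.itemsize > 1 else 8
    return ImageGrid(pixels, bit_depth=bit_depth, um_per_px=um_per_px)


def write_image(path, image: ImageGrid) -> None:
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    pixels = np.asarray(image.pixels).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets: one set per line, name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(path, gene_sets: Mapping[str, Sequence[str]]) -> None:
    lines = [
        "\t".join([name, "", *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def regions_to_table(regions: Sequence[FiberRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area_px": r.pixel_count,
                "area_um2": r.area_um2,
                "perimeter_px": r.perimeter_px,
                "circularity": r.circularity,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "status": r.status,
                "reason": r.reason or "",
            }
            for r in regions
        ]
    )


def write_region_table(path, regions: Sequence[FiberRegion]) -> None:
    regions_to_table(regions).to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
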
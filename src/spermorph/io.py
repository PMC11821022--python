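"""File formats: maps as indexed PNG, images as TIFF, tables as CSV/JSON.

Instance-ID maps are 16-bit PNGs; part-label maps are 8-bit PNGs restricted
to the palette {0 background, 1 head, 2 midpiece, 3 tail}.  Round-trips are
lossless; palette violations are rejected on read and write.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import MORPH_COLUMNS, MorphParams, SpermGeometry

MAX_PART_LABEL = 3


class FormatError(ValueError):
    pass


# -- maps -------------------------------------------------------------------

def write_instance_map(path: str | Path, instance_map: np.ndarray) -> None:
    arr = np.asarray(instance_map)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise FormatError("instance ids must fit in uint16")
    iio.imwrite(Path(path), arr.astype(np.uint16))


def read_instance_map(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int32)


def write_part_map(path: str | Path, part_map: np.ndarray) -> None:
    arr = np.asarray(part_map)
    if arr.min() < 0 or arr.max() > MAX_PART_LABEL:
        raise FormatError(f"part labels must lie in 0..{MAX_PART_LABEL}")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_part_map(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.max() > MAX_PART_LABEL:
        raise FormatError(
            f"{path}: part label {int(arr.max())} outside the palette 0..{MAX_PART_LABEL}")
    return arr.astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


# -- geometry & measurements ------------------------------------------------

def geometry_record(geom: SpermGeometry) -> dict:
    return {
        "instance_id": geom.instance_id,
        "head_center": list(geom.head_center),
        "head_semi_major_px": geom.head_semi_major_px,
        "head_semi_minor_px": geom.head_semi_minor_px,
        "head_orientation_rad": geom.head_orientation_rad,
        "midpiece_points": geom.midpiece_points.tolist(),
        "midpiece_width_px": geom.midpiece_width_px,
        "tail_points": geom.tail_points.tolist(),
        "tail_width_px": geom.tail_width_px,
        "params": geom.params.as_dict(),
    }


def write_geometries(path: str | Path, geometries: Iterable[SpermGeometry]) -> None:
    Path(path).write_text(
        json.dumps([geometry_record(g) for g in geometries], indent=1))


def read_geometries(path: str | Path) -> list[SpermGeometry]:
    out = []
    for rec in json.loads(Path(path).read_text()):
        params = MorphParams(**rec.pop("params"))
        rec["head_center"] = tuple(rec["head_center"])
        rec["midpiece_points"] = np.asarray(rec["midpiece_points"])
        rec["tail_points"] = np.asarray(rec["tail_points"])
        out.append(SpermGeometry(params=params, **rec))
    return out


def write_morphometry_csv(path: str | Path,
                          rows: dict[int, MorphParams]) -> pd.DataFrame:
    """One row per instance, columns ``id`` + the nine measurement columns."""
    df = pd.DataFrame(
        [{"id": k, **dict(zip(MORPH_COLUMNS, v.as_row()))} for k, v in sorted(rows.items())],
        columns=["id", *MORPH_COLUMNS])
    df.to_csv(path, index=False)
    return df


def read_morphometry_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(["id", *MORPH_COLUMNS]) - set(df.columns)
    if missing:
        raise FormatError(f"morphometry CSV missing columns {sorted(missing)}")
    return df


# -- signals ----------------------------------------------------------------

def write_signal_csv(path: str | Path, values: np.ndarray,
                     is_outlier: np.ndarray | None = None,
                     true_max: float | None = None) -> None:
    n = len(values)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "value": np.asarray(values, dtype=float),
        "is_outlier": np.zeros(n, dtype=bool) if is_outlier is None else np.asarray(is_outlier),
        "true_max": np.full(n, np.nan if true_max is None else true_max),
    })
    df.to_csv(path, index=False)


def read_signal_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise FormatError("signal CSV needs at least a 'value' column")
    return df
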
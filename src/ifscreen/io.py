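"""File I/O for plate directories, tables and results.

A plate directory contains ``plate_map.csv`` plus single-channel grayscale
TIFFs under ``images/`` named ``{well}_{site}_{channel}.tif`` with channels
``nuclear`` and ``marker``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import tifffile

from .assay import validate_plate_map
from .imaging import CELL_TABLE_COLUMNS, FieldImage, WellCount

WELL_TABLE_COLUMNS = ["well", "n_total", "n_positive", "n_negative", "n_sites"]
CHANNELS = ("nuclear", "marker")


def field_path(plate_dir: str | Path, well: str, site: int, channel: str) -> Path:
    return Path(plate_dir) / "images" / f"{well}_{site}_{channel}.tif"


def load_field(plate_dir: str | Path, well: str, site: int = 0) -> FieldImage:
    """Read both channels of one field; a missing file names the well/site."""
    arrays = {}
    for channel in CHANNELS:
        path = field_path(plate_dir, well, site, channel)
        if not path.exists():
            raise FileNotFoundError(
                f"missing {channel} image for well {well} site {site}: {path}"
            )
        arrays[channel] = tifffile.imread(path)
    bit_depth = 8 if arrays["nuclear"].dtype.itemsize == 1 else 16
    return FieldImage(
        well=well, site=site, channel_nuclear=arrays["nuclear"],
        channel_marker=arrays["marker"], bit_depth=bit_depth,
    )


def list_sites(plate_dir: str | Path, well: str) -> list[int]:
    """Site indices present for a well, from the nuclear-channel files."""
    img_dir = Path(plate_dir) / "images"
    sites = sorted(
        int(p.stem.split("_")[-2])
        for p in img_dir.glob(f"{well}_*_nuclear.tif")
    )
    return sites


def read_plate_map(plate_dir: str | Path) -> pd.DataFrame:
    path = Path(plate_dir) / "plate_map.csv"
    if not path.exists():
        raise FileNotFoundError(f"no plate_map.csv in {plate_dir}")
    return validate_plate_map(pd.read_csv(path))


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False, columns=[c for c in CELL_TABLE_COLUMNS
                                             if c in cells.columns])


def write_well_table(counts: list[WellCount], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "well": c.well, "n_total": c.n_total, "n_positive": c.n_positive,
                "n_negative": c.n_negative, "n_sites": c.n_sites,
            }
            for c in counts
        ],
        columns=WELL_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df


def read_well_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    return df


def screen_table(plate_map: pd.DataFrame, wells: pd.DataFrame) -> pd.DataFrame:
    """Join the plate map with per-well counts (1:1 on well id)."""
    merged = plate_map.merge(wells, on="well", how="left", validate="1:1")
    if merged["n_total"].isna().any():
        missing = merged.loc[merged["n_total"].isna(), "well"].tolist()
        raise ValueError(f"wells in plate map without counts: {missing[:10]}")
    return merged


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
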
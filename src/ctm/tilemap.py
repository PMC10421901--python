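"""Tile-map data model and long-table I/O.

A whole-slide image is represented as a rectangular grid of tiles.  Each
tile carries one of six texture labels (five tissue textures plus slide
background) and, optionally, a continuous lymphocyte score in [0, 1]
produced by an upstream classifier.  Maps are exchanged as long-format
delimited tables (TSV by default) with one row per tile.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left
corner, row-major.  Tiles inside the declared bounding box that are absent
from an input file are filled with the ``empty`` (background) label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical label order.  The first five entries form the tissue-texture
#: list ``T``; ``empty`` (slide background) is the only non-tissue label.
LABELS: tuple[str, ...] = ("blood", "cancer", "normal", "stroma", "other", "empty")
TISSUE_TEXTURES: tuple[str, ...] = LABELS[:5]
CODE: dict[str, int] = {name: i for i, name in enumerate(LABELS)}
CANCER = CODE["cancer"]
STROMA = CODE["stroma"]
EMPTY = CODE["empty"]

TILEMAP_COLUMNS = ("sample_id", "row", "col", "texture", "lymphocyte_score")
COHORT_REQUIRED = ("sample_id", "centre_id", "microns_per_px")


@dataclass(frozen=True)
class TileGeometry:
    """Physical geometry of a tile: edge length in pixels and resolution.

    The physical tile edge is ``tile_size_px * microns_per_px`` microns;
    the defaults (256 px at 0.25 µm/px) give a 64 µm tile edge.
    """

    tile_size_px: int = 256
    microns_per_px: float = 0.25

    def __post_init__(self) -> None:
        if self.tile_size_px <= 0:
            raise ValueError("tile_size_px must be positive")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def edge_microns(self) -> float:
        return self.tile_size_px * self.microns_per_px


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("grid must be a 2-D array with at least one tile")
    return grid


@dataclass(eq=False)
class TileMap:
    """Per-sample grid of texture labels (stored as small integer codes)."""

    sample_id: str
    grid: np.ndarray
    centre_id: str = ""
    geometry: TileGeometry = field(default_factory=TileGeometry)

    def __post_init__(self) -> None:
        self.grid = _validate_grid(self.grid).astype(np.int8)
        if self.grid.min() < 0 or self.grid.max() >= len(LABELS):
            raise ValueError("grid contains codes outside the label alphabet")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def labels(self) -> np.ndarray:
        """Grid as an array of label strings."""
        return np.asarray(LABELS, dtype=object)[self.grid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TileMap):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.geometry == other.geometry
            and np.array_equal(self.grid, other.grid)
        )

    @classmethod
    def from_labels(
        cls,
        sample_id: str,
        labels: Iterable[Iterable[str]],
        centre_id: str = "",
        geometry: TileGeometry | None = None,
    ) -> "TileMap":
        arr = np.asarray([[CODE[l] for l in row] for row in labels], dtype=np.int8)
        return cls(sample_id, arr, centre_id, geometry or TileGeometry())


@dataclass(eq=False)
class LymphocyteMap:
    """Grid of continuous lymphocyte scores co-registered with a TileMap.

    Missing scores (typically on background tiles) are stored as NaN and
    ignored by every density computation.
    """

    sample_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = _validate_grid(self.grid).astype(float)
        present = self.grid[~np.isnan(self.grid)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("lymphocyte scores must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LymphocyteMap):
            return NotImplemented
        return self.sample_id == other.sample_id and np.array_equal(
            self.grid, other.grid, equal_nan=True
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_tilemap(
    path: str | Path,
    sample_id: str | None = None,
    n_rows: int | None = None,
    n_cols: int | None = None,
    centre_id: str = "",
    geometry: TileGeometry | None = None,
    sep: str | None = None,
) -> tuple[TileMap, LymphocyteMap]:
    """Read a long-format tile table and reconstruct co-registered grids.

    Parameters
    ----------
    path:
        Delimited file with header columns ``sample_id, row, col, texture``
        and optionally ``lymphocyte_score``.
    sample_id:
        Select one sample from a multi-sample file; mandatory when the file
        holds more than one sample.
    n_rows, n_cols:
        Declared bounding box.  Defaults to the observed extent.  Positions
        inside the box that are not listed become ``empty`` tiles with a
        missing lymphocyte score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in ("sample_id", "row", "col", "texture") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
        if df.empty:
            raise ValueError(f"{path}: no rows for sample_id {sample_id!r}")
    else:
        ids = df["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                f"{path}: file holds {len(ids)} samples; pass sample_id to select one"
            )
        sample_id = str(ids[0])

    bad = ~df["texture"].isin(LABELS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header row, one for 1-based line numbering
        raise ValueError(
            f"{path}: unknown texture label {df['texture'].iloc[i]!r} "
            f"on line {df.index[i] + 2}"
        )

    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    if rows.min(initial=0) < 0 or cols.min(initial=0) < 0:
        raise ValueError(f"{path}: negative tile coordinates")
    dup = df.duplicated(subset=["row", "col"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate tile position ({rows[i]}, {cols[i]})"
        )

    R = int(rows.max()) + 1 if n_rows is None else int(n_rows)
    C = int(cols.max()) + 1 if n_cols is None else int(n_cols)
    if R <= int(rows.max()) or C <= int(cols.max()):
        raise ValueError(f"{path}: declared bounding box smaller than listed tiles")

    grid = np.full((R, C), EMPTY, dtype=np.int8)
    grid[rows, cols] = [CODE[t] for t in df["texture"]]

    lgrid = np.full((R, C), np.nan)
    if "lymphocyte_score" in df.columns:
        scores = pd.to_numeric(df["lymphocyte_score"], errors="coerce").to_numpy()
        finite = scores[~np.isnan(scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{path}: lymphocyte_score outside [0, 1]")
        lgrid[rows, cols] = scores

    tmap = TileMap(sample_id, grid, centre_id, geometry or TileGeometry())
    return tmap, LymphocyteMap(sample_id, lgrid)


def write_tilemap(
    tmap: TileMap,
    lmap: LymphocyteMap | None,
    path: str | Path,
    sep: str | None = None,
) -> Path:
    """Write co-registered maps as a long table (one row per tile).

    Every tile is written, including background, so that
    ``read_tilemap(write_tilemap(m)) == m`` holds regardless of which
    corner tiles happen to be empty.
    """
    path = Path(path)
    if lmap is not None and lmap.shape != tmap.shape:
        raise ValueError(
            f"shape mismatch: texture map {tmap.shape} vs lymphocyte map {lmap.shape}"
        )
    R, C = tmap.shape
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    df = pd.DataFrame(
        {
            "sample_id": tmap.sample_id,
            "row": rr.ravel(),
            "col": cc.ravel(),
            "texture": tmap.labels.ravel(),
            "lymphocyte_score": (lmap.grid.ravel() if lmap is not None else np.nan),
        }
    )
    df.to_csv(path, sep=_sep_for(path, sep), index=False, float_format="%.8g")
    return path


def read_cohort(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a cohort metadata table.

    Required columns: ``sample_id``, ``centre_id``, ``microns_per_px``.
    Free covariate columns and survival columns (``os_months``,
    ``os_event``) are passed through untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in cohort table")
    if df["centre_id"].isna().any() or (df["centre_id"].astype(str) == "").any():
        raise ValueError(f"{path}: empty centre_id in cohort table")
    return df


def validate_cohort(
    cohort: pd.DataFrame, maps: Iterable[TileMap]
) -> dict[str, object]:
    """Cross-check a cohort table against a collection of tile maps.

    Report-only: returns sample ids present in the table but lacking a map
    (``missing_map``), maps whose sample id is absent from the table
    (``orphan_map``), and the per-sample resolution.
    """
    map_ids = {m.sample_id for m in maps}
    table_ids = set(cohort["sample_id"].astype(str))
    return {
        "missing_map": sorted(table_ids - map_ids),
        "orphan_map": sorted(map_ids - table_ids),
        "resolution": dict(
            zip(cohort["sample_id"].astype(str), cohort["microns_per_px"])
        ),
    }


# distinct, colour-blind-friendly-ish palette for quick visual QC
_PALETTE: Mapping[str, tuple[int, int, int]] = {
    "blood": (214, 39, 40),
    "cancer": (148, 103, 189),
    "normal": (44, 160, 44),
    "stroma": (255, 187, 120),
    "other": (127, 127, 127),
    "empty": (255, 255, 255),
}


def export_png(tmap: TileMap, path: str | Path) -> Path:
    """Export the label grid as an indexed PNG with a JSON legend sidecar."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray(tmap.grid.astype(np.uint8), mode="P")
    palette: list[int] = []
    for name in LABELS:
        palette.extend(_PALETTE[name])
    img.putpalette(palette)
    img.save(path)
    legend = {name: CODE[name] for name in LABELS}
    Path(str(path) + ".legend.json").write_text(json.dumps(legend, indent=2))
    return path
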
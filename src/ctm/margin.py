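"""Tumour-margin extraction by morphological dilation.

The tumour margin is the band of non-cancer *tissue* tiles within a fixed
Chebyshev distance (two tiles by default) of any cancer tile — i.e. the
square dilation of the cancer mask minus the cancer mask itself,
intersected with tissue.  The cancer tiles form the tumour core, background
tiles stay background, and all remaining tissue is non-margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tilemap import CANCER, EMPTY, TileGeometry, TileMap

REGIONS: tuple[str, ...] = ("core", "margin", "non_margin", "background")
REGION_CODE: dict[str, int] = {name: i for i, name in enumerate(REGIONS)}


@dataclass(eq=False)
class RegionPartition:
    """Per-tile region labels {core, margin, non_margin, background}."""

    sample_id: str
    grid: np.ndarray
    depth_tiles: int = 2

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("partition grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def mask(self, region: str) -> np.ndarray:
        return self.grid == REGION_CODE[region]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(REGIONS, dtype=object)[self.grid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionPartition):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.depth_tiles == other.depth_tiles
            and np.array_equal(self.grid, other.grid)
        )


def extract_margin(tmap: TileMap, depth_tiles: int = 2) -> RegionPartition:
    """Partition a sample into core / margin / non-margin / background.

    A tile is margin iff it is non-cancer, non-empty, and its Chebyshev
    distance to the nearest cancer tile is at most ``depth_tiles`` (a
    square maximum filter of side ``2*depth_tiles + 1`` applied to the
    cancer mask).  A map without cancer tiles yields an empty core and
    margin: every tissue tile is non-margin.
    """
    if depth_tiles < 1:
        raise ValueError("depth_tiles must be >= 1")
    cancer = tmap.grid == CANCER
    tissue = tmap.grid != EMPTY
    dilated = ndimage.maximum_filter(
        cancer, size=2 * depth_tiles + 1, mode="constant", cval=False
    )
    grid = np.full(tmap.shape, REGION_CODE["non_margin"], dtype=np.int8)
    grid[~tissue] = REGION_CODE["background"]
    grid[dilated & ~cancer & tissue] = REGION_CODE["margin"]
    grid[cancer] = REGION_CODE["core"]
    return RegionPartition(tmap.sample_id, grid, depth_tiles)


def margin_width_px(
    geometry: TileGeometry, depth_tiles: int = 2
) -> tuple[int, float]:
    """Physical margin width: ``(pixels, microns)``.

    With the default geometry (256 px tiles at 0.25 µm/px) and a two-tile
    depth the margin band is 512 px, i.e. 128 µm, wide.
    """
    px = depth_tiles * geometry.tile_size_px
    return px, px * geometry.microns_per_px


def margin_eligibility(profile, min_normal: float = 0.01) -> bool:
    """Margin analyses are restricted to samples with at least ``min_normal``
    normal-tissue proportion (inclusive bound), to avoid sampling bias from
    tumour-core-only sections."""
    props = getattr(profile, "proportions", None) or {}
    return props.get("normal", 0.0) >= min_normal
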
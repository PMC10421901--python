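"""Sliding-window majority-vote smoothing of texture maps.

Raw tile classification yields tessellated maps: coherent regions are
disrupted by sporadic single-tile labels.  A window (3×3 tiles by default)
is slid over the map at a fixed stride (2 by default) and every tile in
each visited window is reassigned to the window's most common label.

Tie hierarchy: a tie involving cancer resolves to cancer; a tie involving
stroma but not cancer resolves to stroma (the two textures most often mixed
within single tiles); any remaining tie is broken uniformly at random among
the tied labels using a seeded generator, so results are reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tilemap import CANCER, CODE, LABELS, STROMA, TileMap


@dataclass(frozen=True)
class PoolingConfig:
    """Window/stride/seed for majority-vote pooling.

    ``mode`` selects between in-place smoothing (output keeps the input
    shape; overlapping windows are overwritten in raster order, later
    window wins) and ``downsample`` (one output tile per visited window).
    """

    window: int = 3
    stride: int = 2
    seed: int = 0
    mode: str = "inplace"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if not 1 <= self.stride <= self.window:
            raise ValueError("stride must satisfy 1 <= stride <= window")
        if self.mode not in ("inplace", "downsample"):
            raise ValueError("mode must be 'inplace' or 'downsample'")


def map_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-map generator seeded from (global seed, sample id).

    Cohort runs are therefore reproducible sample-by-sample, independent of
    the order in which samples are processed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    )


def _pool_counts(counts: np.ndarray, rng: np.random.Generator) -> int:
    """Resolve one window's label counts to a single label code."""
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    if CANCER in tied:
        return CANCER
    if STROMA in tied:
        return STROMA
    return int(tied[rng.integers(len(tied))])


def pool_window(
    counts: Mapping[str, int], rng: np.random.Generator | None = None
) -> str:
    """Modal label of one window under the tie hierarchy.

    ``counts`` maps label names to occurrence counts (absent labels count
    zero).  ``rng`` is only consulted for ties not involving cancer or
    stroma; tied labels are ordered canonically before the draw so a fixed
    generator state gives a fixed answer.
    """
    vec = np.zeros(len(LABELS), dtype=np.int64)
    for name, n in counts.items():
        if name not in CODE:
            raise ValueError(f"unknown texture label {name!r}")
        if n < 0:
            raise ValueError("counts must be non-negative")
        vec[CODE[name]] = n
    if vec.sum() == 0:
        raise ValueError("empty window: total count is zero")
    if rng is None:
        rng = np.random.default_rng(0)
    return LABELS[_pool_counts(vec, rng)]


def window_offsets(extent: int, window: int, stride: int) -> list[int]:
    """Top-left offsets along one axis: stride steps plus a final offset
    clamped so the last window touches the map edge."""
    offs = list(range(0, extent - window + 1, stride))
    last = extent - window
    if offs[-1] != last:
        offs.append(last)
    return offs


def pool_map(tmap: TileMap, cfg: PoolingConfig = PoolingConfig()) -> TileMap:
    """Majority-vote pooling of a full map.

    Windows are visited in raster order at the configured stride; counts
    are always taken from the *pre-pooling* grid (a single pass over one
    input), and in ``inplace`` mode every tile of a visited window is
    reassigned, later windows overwriting earlier ones where they overlap.
    Maps smaller than the window are returned unchanged with a warning.
    """
    src = tmap.grid
    R, C = src.shape
    w, s = cfg.window, cfg.stride
    if R < w or C < w:
        warnings.warn(
            f"map {tmap.sample_id!r} ({R}x{C}) smaller than pooling window; "
            "returned unchanged",
            stacklevel=2,
        )
        return TileMap(tmap.sample_id, src.copy(), tmap.centre_id, tmap.geometry)

    rng = map_rng(cfg.seed, tmap.sample_id)
    row_offs = window_offsets(R, w, s)
    col_offs = window_offsets(C, w, s)

    if cfg.mode == "downsample":
        out = np.empty((len(row_offs), len(col_offs)), dtype=np.int8)
        for i, r in enumerate(row_offs):
            for j, c in enumerate(col_offs):
                counts = np.bincount(
                    src[r : r + w, c : c + w].ravel().astype(np.int64),
                    minlength=len(LABELS),
                )
                out[i, j] = _pool_counts(counts, rng)
    else:
        out = src.copy()
        for r in row_offs:
            for c in col_offs:
                counts = np.bincount(
                    src[r : r + w, c : c + w].ravel().astype(np.int64),
                    minlength=len(LABELS),
                )
                out[r : r + w, c : c + w] = _pool_counts(counts, rng)

    return TileMap(tmap.sample_id, out, tmap.centre_id, tmap.geometry)
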
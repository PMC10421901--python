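"""Texture-aware lymphocyte quantification and centre harmonisation.

Raw per-tile lymphocyte scores are summarised per texture (the density
``d_t``: the mean score over tiles of texture ``t``).  Densities are then
rescaled to *relative lymphocyte proportions* ``ρ_t`` so that the five
tissue textures sum to 100% — ρ expresses how strongly lymphocytes are
enriched in each texture relative to the others, and is invariant to any
sample- or centre-level multiplicative intensity bias (e.g. stain
differences).  The harmonised infiltration of a sample is the area-weighted
mean

    α = Σ_t ρ_t · A_t / Σ_t A_t        (t over tissue textures)

with ``A_t`` the texture's area (tiles or px²; α is scale-free in the area
unit).  Residual staining differences are absorbed by binarising samples to
High/Low at their clinical centre's median, restricted to centres with more
than 20 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .margin import RegionPartition
from .tilemap import CODE, TISSUE_TEXTURES, LymphocyteMap, TileMap


@dataclass
class HarmonisationConfig:
    """Knobs for ρ/α computation and centre binarisation.

    ``min_centre_n=21`` keeps only centres with more than 20 samples;
    smaller batches make the centre median too unstable to binarise
    against.  ``rho_source`` selects between per-sample ρ (each sample's
    own densities renormalised) and cohort-level ρ (texture densities
    median-averaged over the cohort, then rescaled to 100%).
    """

    rho_source: str = "per_sample"
    min_texture_tiles: int = 1
    min_centre_n: int = 21
    excluded_centres: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.rho_source not in ("per_sample", "cohort_median"):
            raise ValueError("rho_source must be 'per_sample' or 'cohort_median'")
        if self.min_centre_n < 1:
            raise ValueError("min_centre_n must be >= 1")


@dataclass
class LymphoProfile:
    """Per-sample lymphocyte summary: densities, ρ, α, High/Low class."""

    sample_id: str
    density: dict[str, float] = field(default_factory=dict)
    rho: dict[str, float] = field(default_factory=dict)
    alpha: float = float("nan")
    infiltration_class: str = "NA"
    total_density: float = float("nan")


def density_per_texture(
    tmap: TileMap,
    lmap: LymphocyteMap,
    partition: RegionPartition | None = None,
    region: str | None = None,
    min_texture_tiles: int = 1,
) -> dict[str, float]:
    """Mean lymphocyte score per tissue texture (NaN when undefined).

    Tiles with missing scores are ignored.  A texture needs at least
    ``min_texture_tiles`` scored tiles for its density to be defined; when
    ``region`` is given the computation is restricted to that region of the
    partition.
    """
    if lmap.shape != tmap.shape:
        raise ValueError(
            f"shape mismatch: texture map {tmap.shape} vs lymphocyte map {lmap.shape}"
        )
    sel = np.ones(tmap.shape, dtype=bool)
    if region is not None:
        if partition is None:
            raise ValueError("region given without a partition")
        if partition.shape != tmap.shape:
            raise ValueError("partition shape does not match the map")
        sel = partition.mask(region)
    present = ~np.isnan(lmap.grid)
    out: dict[str, float] = {}
    for t in TISSUE_TEXTURES:
        m = (tmap.grid == CODE[t]) & sel & present
        n = int(m.sum())
        out[t] = float(lmap.grid[m].mean()) if n >= max(min_texture_tiles, 1) else float("nan")
    return out


def total_density(
    tmap: TileMap,
    lmap: LymphocyteMap,
    partition: RegionPartition | None = None,
    region: str | None = None,
) -> float:
    """Mean lymphocyte score over all scored tissue tiles (optionally of a
    region) — the raw, un-harmonised infiltration of a sample."""
    sel = np.ones(tmap.shape, dtype=bool)
    if region is not None:
        sel = partition.mask(region)
    m = (tmap.grid != CODE["empty"]) & sel & ~np.isnan(lmap.grid)
    return float(lmap.grid[m].mean()) if m.any() else float("nan")


def relative_proportions(density: Mapping[str, float]) -> dict[str, float]:
    """Rescale texture densities so defined textures sum to 100%.

    Undefined (NaN) densities get ρ = 0 and are excluded from the
    renormalisation.  If every defined density is zero the mass is spread
    uniformly over the defined textures (flagged with a warning).
    """
    defined = {t: d for t, d in density.items() if not np.isnan(d)}
    if not defined:
        raise ValueError("no defined texture density: cannot compute rho")
    total = sum(defined.values())
    if total == 0:
        warnings.warn("all defined densities are zero; uniform rho", stacklevel=2)
        return {
            t: (100.0 / len(defined) if t in defined else 0.0) for t in density
        }
    return {t: (100.0 * defined[t] / total if t in defined else 0.0) for t in density}


def ctm_alpha(
    rho: Mapping[str, float],
    areas: Mapping[str, float],
    include: Iterable[str] | None = None,
) -> float:
    """Area-weighted mean of ρ over tissue textures (the α statistic).

    ``include`` restricts the sum to the textures whose density was
    defined; textures absent from a sample contribute zero area and vanish
    naturally.  Background never enters.  Raises on zero total area.
    """
    keys = [
        t
        for t in (include if include is not None else rho)
        if t in TISSUE_TEXTURES and t in rho and areas.get(t, 0) > 0
    ]
    total = float(sum(areas[t] for t in keys))
    if total <= 0:
        raise ValueError("zero total tissue area: alpha undefined")
    return float(sum(rho[t] * areas[t] for t in keys) / total)


def lympho_profile(
    tmap: TileMap,
    lmap: LymphocyteMap,
    areas: Mapping[str, float] | None = None,
    cfg: HarmonisationConfig = HarmonisationConfig(),
    cohort_rho: Mapping[str, float] | None = None,
) -> LymphoProfile:
    """Densities, ρ and α for one sample.

    ``areas`` defaults to the map's own tile counts.  With
    ``rho_source="cohort_median"`` the shared ``cohort_rho`` vector (see
    :func:`cohort_median_rho`) replaces the per-sample one.
    """
    dens = density_per_texture(tmap, lmap, min_texture_tiles=cfg.min_texture_tiles)
    if areas is None:
        counts = np.bincount(tmap.grid.ravel().astype(np.int64), minlength=6)
        areas = {t: int(counts[CODE[t]]) for t in TISSUE_TEXTURES}
    defined = [t for t, d in dens.items() if not np.isnan(d)]
    if cfg.rho_source == "cohort_median":
        if cohort_rho is None:
            raise ValueError("rho_source='cohort_median' requires cohort_rho")
        rho = dict(cohort_rho)
        include = [t for t in rho if not np.isnan(rho[t])]
    else:
        rho = relative_proportions(dens)
        include = defined
    prof = LymphoProfile(sample_id=tmap.sample_id, density=dens, rho=rho)
    prof.total_density = total_density(tmap, lmap)
    if any(areas.get(t, 0) > 0 for t in include):
        prof.alpha = ctm_alpha(rho, areas, include=include)
    return prof


def cohort_median_rho(densities: Iterable[Mapping[str, float]]) -> dict[str, float]:
    """Cohort-level ρ: per-texture median density over samples, rescaled so
    the textures sum to 100%."""
    df = pd.DataFrame(list(densities))
    med = df.median(skipna=True)
    return relative_proportions(med.to_dict())


def centre_binarise(
    values: pd.Series,
    cohort: pd.DataFrame,
    cfg: HarmonisationConfig = HarmonisationConfig(),
) -> pd.Series:
    """High/Low infiltration per sample against the centre median.

    Within each centre holding at least ``min_centre_n`` samples, a sample
    is High iff its value strictly exceeds the centre median (ties go to
    Low, so at most half a centre is High).  Samples from smaller centres,
    excluded centres, or with missing values get "NA".
    """
    centres = cohort.set_index(cohort["sample_id"].astype(str))["centre_id"].astype(str)
    out = pd.Series("NA", index=values.index, dtype=object)
    grouped = values.groupby(values.index.map(centres))
    for centre, vals in grouped:
        if centre in cfg.excluded_centres:
            continue
        ok = vals.dropna()
        if len(ok) < cfg.min_centre_n:
            continue
        med = ok.median()
        out.loc[ok.index] = np.where(ok > med, "High", "Low")
    return out


def harmonisation_report(
    raw: pd.Series,
    alpha: pd.Series,
    cohort: pd.DataFrame,
) -> dict[str, object]:
    """Between-centre dispersion of raw density versus harmonised α.

    Because raw density and α live on different scales, dispersion is
    reported as the *relative* between-centre variance — the variance of
    centre means divided by the squared grand mean (a squared coefficient
    of variation) — alongside the scale-free Kruskal–Wallis statistic
    across centres.  ``variance_ratio_alpha_raw`` < 1 means harmonisation
    reduced between-centre differences.
    """
    centres = cohort.set_index(cohort["sample_id"].astype(str))["centre_id"].astype(str)

    def _one(values: pd.Series) -> dict[str, float]:
        v = values.dropna()
        by_centre = v.groupby(v.index.map(centres))
        means = by_centre.mean()
        grand = v.mean()
        rel_var = float(means.var(ddof=1) / grand**2) if len(means) > 1 else float("nan")
        groups = [g.to_numpy() for _, g in by_centre if len(g) > 0]
        if len(groups) > 1 and all(len(g) for g in groups):
            kw = sps.kruskal(*groups)
            stat, p = float(kw.statistic), float(kw.pvalue)
        else:
            stat, p = float("nan"), float("nan")
        return {
            "relative_between_centre_variance": rel_var,
            "kruskal_statistic": stat,
            "kruskal_p": p,
            "n_centres": int(len(means)),
        }

    raw_rep = _one(raw)
    alpha_rep = _one(alpha)
    degenerate = raw_rep["n_centres"] < 2
    if degenerate:
        warnings.warn("fewer than two centres: dispersion report degenerate",
                      stacklevel=2)
    ratio = (
        alpha_rep["relative_between_centre_variance"]
        / raw_rep["relative_between_centre_variance"]
        if not degenerate and raw_rep["relative_between_centre_variance"] > 0
        else float("nan")
    )
    return {
        "raw": raw_rep,
        "alpha": alpha_rep,
        "variance_ratio_alpha_raw": ratio,
        "degenerate": bool(degenerate),
    }
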
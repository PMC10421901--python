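"""Margin versus non-margin enrichment scores.

For each sample the texture composition and lymphocyte densities are
computed separately inside the tumour margin and the non-margin tissue;
per-texture enrichment is the ratio of margin to non-margin proportions
(and likewise for lymphocyte densities).  Ratios with a zero denominator
are NA — no pseudocounts by default, since they would silently manufacture
enrichment on sparse regions; ``pseudo=True`` adds one tile to both
region areas per texture for users who need finite ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lympho import density_per_texture, total_density
from .margin import REGION_CODE, RegionPartition
from .tilemap import CODE, TISSUE_TEXTURES, LymphocyteMap, TileMap


@dataclass
class MarginProfile:
    """Per-sample margin/non-margin composition, densities and ratios."""

    sample_id: str
    proportions_margin: dict[str, float] = field(default_factory=dict)
    proportions_non_margin: dict[str, float] = field(default_factory=dict)
    density_margin: dict[str, float] = field(default_factory=dict)
    density_non_margin: dict[str, float] = field(default_factory=dict)
    ratio_texture: dict[str, float] = field(default_factory=dict)
    ratio_lympho: dict[str, float] = field(default_factory=dict)
    ratio_lympho_total: float = float("nan")
    flagged: bool = False


def _region_composition(
    tmap: TileMap, partition: RegionPartition, region: str, pseudo: bool
) -> tuple[dict[str, float], float]:
    mask = partition.mask(region)
    counts = {
        t: float(((tmap.grid == CODE[t]) & mask).sum()) for t in TISSUE_TEXTURES
    }
    if pseudo:
        counts = {t: c + 1.0 for t, c in counts.items()}
    total = sum(counts.values())
    props = {t: (counts[t] / total if total > 0 else float("nan")) for t in counts}
    return props, total


def margin_profile(
    tmap: TileMap,
    lmap: LymphocyteMap,
    partition: RegionPartition,
    pseudo: bool = False,
) -> MarginProfile:
    """Margin:non-margin texture and lymphocyte enrichment for one sample.

    Both region compositions use the tissue denominator within the region.
    An empty margin or empty non-margin region yields all-NA ratios and a
    ``flagged`` profile.
    """
    if partition.shape != tmap.shape or lmap.shape != tmap.shape:
        raise ValueError("map, lymphocyte map and partition shapes must match")
    pm, n_margin = _region_composition(tmap, partition, "margin", pseudo)
    pn, n_non = _region_composition(tmap, partition, "non_margin", pseudo)
    prof = MarginProfile(
        sample_id=tmap.sample_id,
        proportions_margin=pm,
        proportions_non_margin=pn,
        density_margin=density_per_texture(tmap, lmap, partition, "margin"),
        density_non_margin=density_per_texture(tmap, lmap, partition, "non_margin"),
    )
    if n_margin == 0 or n_non == 0:
        warnings.warn(
            f"sample {tmap.sample_id!r}: empty margin or non-margin region; "
            "ratios undefined",
            stacklevel=2,
        )
        prof.flagged = True
        prof.ratio_texture = {t: float("nan") for t in TISSUE_TEXTURES}
        prof.ratio_lympho = {t: float("nan") for t in TISSUE_TEXTURES}
        return prof
    for t in TISSUE_TEXTURES:
        prof.ratio_texture[t] = (
            pm[t] / pn[t] if pn[t] > 0 else float("nan")
        )
        dm, dn = prof.density_margin[t], prof.density_non_margin[t]
        prof.ratio_lympho[t] = (
            dm / dn if not np.isnan(dm) and not np.isnan(dn) and dn > 0 else float("nan")
        )
    tm = total_density(tmap, lmap, partition, "margin")
    tn = total_density(tmap, lmap, partition, "non_margin")
    prof.ratio_lympho_total = tm / tn if tn and not np.isnan(tn) and tn > 0 else float("nan")
    return prof


def margin_profiles_frame(profiles: list[MarginProfile]) -> pd.DataFrame:
    """Flatten margin profiles into a tidy table."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "flagged": p.flagged,
            "ratio_lympho_total": p.ratio_lympho_total,
        }
        for t in TISSUE_TEXTURES:
            row[f"margin_prop_{t}"] = p.proportions_margin.get(t, np.nan)
            row[f"non_margin_prop_{t}"] = p.proportions_non_margin.get(t, np.nan)
            row[f"ratio_texture_{t}"] = p.ratio_texture.get(t, np.nan)
            row[f"ratio_lympho_{t}"] = p.ratio_lympho.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_classes(ratios: pd.Series, quantile: float = 0.5) -> pd.Series:
    """Binary High/Low split of an enrichment ratio at a cohort quantile.

    The threshold is the linear-interpolation quantile of the non-NA
    values; a sample is High iff its ratio strictly exceeds it.  NA ratios
    propagate to "NA".  Requires at least two non-NA samples.
    """
    ok = ratios.dropna()
    if len(ok) < 2:
        return pd.Series("NA", index=ratios.index, dtype=object)
    thr = float(ok.quantile(quantile))
    out = pd.Series("NA", index=ratios.index, dtype=object)
    out.loc[ok.index] = np.where(ok > thr, "High", "Low")
    return out
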
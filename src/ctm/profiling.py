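"""Texture composition, cohort quality control, and N+/N− stratification.

Composition is reported over the tissue-texture list ``T`` by default
(background excluded from the denominator); ``denominator="all_tiles"``
divides by the full tile count instead.

QC mirrors routine cohort curation for tile-classified slide archives:
samples scanned outside the accepted resolution band are dropped first,
then samples whose cancer proportion falls below a floor (5% by default,
strict ``<``), then manually flagged centres.  Stratification splits the
cohort at 1% normal tissue into N+ (peritumoural tissue included) versus
N− (tumour-core-only) sampling conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tilemap import CODE, LABELS, TISSUE_TEXTURES, TileMap

QC_PASS = "pass"
QC_LOW_CANCER = "excluded_low_cancer"
QC_RESOLUTION = "excluded_resolution"
QC_MANUAL = "excluded_manual"


@dataclass
class SampleProfile:
    """Per-sample texture areas, proportions, QC status and N-class."""

    sample_id: str
    centre_id: str = ""
    area_tiles: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float] | None = None
    denominator: str = "tissue"
    qc_status: str = QC_PASS
    n_class: str | None = None

    @property
    def tissue_area(self) -> int:
        return sum(self.area_tiles.get(t, 0) for t in TISSUE_TEXTURES)

    @property
    def undefined(self) -> bool:
        """True when the map holds no tissue, so proportions are undefined."""
        return self.proportions is None


@dataclass
class QCPolicy:
    """Quantitative exclusion rules.

    ``allowed_resolution`` is an inclusive µm/px band; the default accepts
    the common ~0.25 µm/px scans and rejects ~0.50 µm/px scans.
    ``excluded_centres`` lists centres removed by manual review (used for
    lymphocyte analyses where a centre's staining is unreliable).
    """

    min_cancer: float = 0.05
    allowed_resolution: tuple[float, float] = (0.1, 0.35)
    excluded_centres: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.min_cancer <= 1:
            raise ValueError("min_cancer must lie in [0, 1]")


def texture_composition(
    tmap: TileMap, denominator: str = "tissue"
) -> SampleProfile:
    """Tile counts and proportions per texture for one sample.

    With ``denominator="tissue"`` the proportions over ``T`` sum to one and
    background is ignored; with ``"all_tiles"`` each proportion is the
    texture's share of the whole grid.  A map with zero tissue area gets
    ``proportions=None`` (flagged undefined).
    """
    if denominator not in ("tissue", "all_tiles"):
        raise ValueError("denominator must be 'tissue' or 'all_tiles'")
    counts = np.bincount(tmap.grid.ravel().astype(np.int64), minlength=len(LABELS))
    area = {name: int(counts[CODE[name]]) for name in LABELS}
    tissue_total = sum(area[t] for t in TISSUE_TEXTURES)
    if denominator == "tissue":
        props = (
            {t: area[t] / tissue_total for t in TISSUE_TEXTURES}
            if tissue_total > 0
            else None
        )
    else:
        props = {t: area[t] / tmap.grid.size for t in TISSUE_TEXTURES}
        if tissue_total == 0:
            props = None
    return SampleProfile(
        sample_id=tmap.sample_id,
        centre_id=tmap.centre_id,
        area_tiles=area,
        proportions=props,
        denominator=denominator,
    )


def apply_qc(
    profiles: Iterable[SampleProfile],
    cohort: pd.DataFrame,
    policy: QCPolicy = QCPolicy(),
) -> tuple[list[SampleProfile], pd.DataFrame]:
    """Partition profiles into kept and excluded-with-reason.

    Exclusion order: resolution → low_cancer → manual; each sample is
    reported once with its first matching reason.  A sample with no
    resolution in the cohort table is retained with a warning.
    """
    res = dict(zip(cohort["sample_id"].astype(str), cohort["microns_per_px"]))
    centres = dict(zip(cohort["sample_id"].astype(str), cohort["centre_id"].astype(str)))
    lo, hi = policy.allowed_resolution
    kept: list[SampleProfile] = []
    rows: list[dict[str, str]] = []
    for p in profiles:
        centre = p.centre_id or centres.get(p.sample_id, "")
        p.centre_id = centre
        r = res.get(p.sample_id, np.nan)
        if p.sample_id not in res or (isinstance(r, float) and np.isnan(r)):
            warnings.warn(
                f"sample {p.sample_id!r}: missing resolution; retained",
                stacklevel=2,
            )
            r = np.nan
        if not np.isnan(r) and not (lo <= r <= hi):
            p.qc_status = QC_RESOLUTION
        elif p.proportions is None or p.proportions.get("cancer", 0.0) < policy.min_cancer:
            p.qc_status = QC_LOW_CANCER
        elif centre in policy.excluded_centres:
            p.qc_status = QC_MANUAL
        else:
            p.qc_status = QC_PASS
            kept.append(p)
            continue
        rows.append(
            {"sample_id": p.sample_id, "status": p.qc_status,
             "reason": p.qc_status.removeprefix("excluded_")}
        )
    excluded = pd.DataFrame(rows, columns=["sample_id", "status", "reason"])
    return kept, excluded


def stratify_n(profile: SampleProfile, threshold: float = 0.01) -> str:
    """Assign N+ (normal proportion ≥ threshold) or N− (< threshold)."""
    if profile.proportions is None:
        raise ValueError(f"sample {profile.sample_id!r}: proportions undefined")
    profile.n_class = (
        "N_plus" if profile.proportions.get("normal", 0.0) >= threshold else "N_minus"
    )
    return profile.n_class


def profiles_frame(profiles: Iterable[SampleProfile]) -> pd.DataFrame:
    """Flatten profiles into a tidy table (one row per sample)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "centre_id": p.centre_id,
            "qc_status": p.qc_status,
            "n_class": p.n_class,
            "tissue_area_tiles": p.tissue_area,
        }
        for t in LABELS:
            row[f"area_{t}"] = p.area_tiles.get(t, 0)
        for t in TISSUE_TEXTURES:
            row[f"prop_{t}"] = (
                p.proportions.get(t, 0.0) if p.proportions is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def centre_composition_summary(
    profiles: Iterable[SampleProfile], cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-centre median texture proportions and max/min fold-variation.

    Returns ``(medians, fold)`` where ``medians`` is indexed by centre with
    one column per tissue texture, and ``fold[t]`` is the ratio of the
    largest to the smallest centre median for texture ``t`` (a direct
    measure of between-centre sampling bias).
    """
    df = profiles_frame(profiles)
    centres = cohort.set_index(cohort["sample_id"].astype(str))["centre_id"]
    df["centre_id"] = df["centre_id"].where(
        df["centre_id"] != "", df["sample_id"].map(centres)
    )
    cols = [f"prop_{t}" for t in TISSUE_TEXTURES]
    medians = df.groupby("centre_id")[cols].median()
    medians.columns = list(TISSUE_TEXTURES)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = medians.max() / medians.min()
    return medians, fold


def fold_variation(centre_medians: Sequence[float] | Mapping[str, float]) -> float:
    """Max/min ratio of a set of per-centre medians (fold-variation)."""
    vals = np.asarray(
        list(centre_medians.values())
        if isinstance(centre_medians, Mapping)
        else list(centre_medians),
        dtype=float,
    )
    if vals.size == 0 or np.nanmin(vals) <= 0:
        return float("nan") if vals.size == 0 else float("inf")
    return float(np.nanmax(vals) / np.nanmin(vals))
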
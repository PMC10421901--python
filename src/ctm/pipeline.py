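"""End-to-end pipeline: pool → profile/QC → stratify → margin → lymphocyte
harmonisation → margin enrichment → association statistics.

Every stage writes a plain TSV into the output directory, and a JSON
manifest records the configuration hash, seed, library versions and
per-stage sample counts, so a rerun with identical inputs and seed
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import margin_profile, margin_profiles_frame
from .lympho import (
    HarmonisationConfig,
    centre_binarise,
    cohort_median_rho,
    lympho_profile,
)
from .margin import extract_margin, margin_eligibility
from .pooling import PoolingConfig, pool_map
from .profiling import (
    QCPolicy,
    apply_qc,
    profiles_frame,
    stratify_n,
    texture_composition,
)
from .stats import adjust_family, associate, association_table, survival_logrank
from .tilemap import TISSUE_TEXTURES, read_cohort, read_tilemap


@dataclass
class PipelineConfig:
    """Paths, per-stage parameters and the global seed."""

    maps_dir: str
    cohort_path: str
    out_dir: str
    pooling: PoolingConfig = field(default_factory=PoolingConfig)
    margin_depth: int = 2
    qc: QCPolicy = field(default_factory=QCPolicy)
    harmonisation: HarmonisationConfig = field(default_factory=HarmonisationConfig)
    n_threshold: float = 0.01
    min_normal_for_margin: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (
            ("pooling", PoolingConfig),
            ("qc", QCPolicy),
            ("harmonisation", HarmonisationConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub_raw = raw[key]
                for k, v in sub_raw.items():
                    if isinstance(v, list):
                        sub_raw[k] = tuple(v)
                raw[key] = sub(**sub_raw)
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Execute every stage on a directory of tile-map TSVs.

    Returns the result bundle (stage tables plus manifest) and writes one
    TSV per stage under ``cfg.out_dir``.  Any stage failure aborts with
    the stage name and, where known, the offending sample.
    """
    maps_dir = Path(cfg.maps_dir)
    cohort_path = Path(cfg.cohort_path)
    if not maps_dir.is_dir():
        raise FileNotFoundError(f"maps directory not found: {maps_dir}")
    if not cohort_path.is_file():
        raise FileNotFoundError(f"cohort table not found: {cohort_path}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, object] = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "ctm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    stages: dict = manifest["stages"]  # type: ignore[assignment]

    cohort = read_cohort(cohort_path)
    centres = dict(zip(cohort["sample_id"].astype(str), cohort["centre_id"].astype(str)))

    # --- ingest ---------------------------------------------------------
    maps = {}
    for path in sorted(maps_dir.glob("*.tsv")):
        try:
            tmap, lmap = read_tilemap(path)
        except ValueError as exc:
            raise RuntimeError(f"stage ingest failed on {path.name}: {exc}") from exc
        tmap.centre_id = centres.get(tmap.sample_id, "")
        maps[tmap.sample_id] = (tmap, lmap)
    if not maps:
        raise RuntimeError(f"stage ingest: no tile maps found in {maps_dir}")
    stages["ingest"] = {"n_samples": len(maps)}

    # --- pool -----------------------------------------------------------
    pcfg = dataclasses.replace(cfg.pooling, seed=cfg.seed)
    pooled = {}
    for sid, (tmap, lmap) in maps.items():
        pooled[sid] = (pool_map(tmap, pcfg), lmap)
    stages["pool"] = {"n_samples": len(pooled)}

    # --- profile + QC + stratify ---------------------------------------
    profiles = [texture_composition(t) for t, _ in pooled.values()]
    kept, excluded = apply_qc(profiles, cohort, cfg.qc)
    for p in kept:
        stratify_n(p, cfg.n_threshold)
    prof_df = profiles_frame(profiles)
    prof_df.to_csv(out / "profiles.tsv", sep="\t", index=False)
    excluded.to_csv(out / "qc.tsv", sep="\t", index=False)
    stages["qc"] = {
        "n_kept": len(kept),
        "n_excluded": int(len(excluded)),
        "by_reason": excluded["reason"].value_counts().to_dict()
        if len(excluded)
        else {},
    }

    kept_ids = [p.sample_id for p in kept]
    prof_by_id = {p.sample_id: p for p in kept}

    # --- margin partition ----------------------------------------------
    partitions = {}
    part_rows = []
    for sid in kept_ids:
        tmap, _ = pooled[sid]
        part = extract_margin(tmap, cfg.margin_depth)
        partitions[sid] = part
        R, C = part.shape
        rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        part_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "row": rr.ravel(),
                    "col": cc.ravel(),
                    "region": part.labels.ravel(),
                }
            )
        )
    if part_rows:
        pd.concat(part_rows).to_csv(out / "partitions.tsv", sep="\t", index=False)
    stages["margin"] = {"n_samples": len(partitions)}

    # --- lymphocyte harmonisation --------------------------------------
    hcfg = cfg.harmonisation
    cohort_rho = None
    if hcfg.rho_source == "cohort_median":
        from .lympho import density_per_texture

        cohort_rho = cohort_median_rho(
            density_per_texture(*pooled[sid], min_texture_tiles=hcfg.min_texture_tiles)
            for sid in kept_ids
        )
    lprofiles = {
        sid: lympho_profile(*pooled[sid], cfg=hcfg, cohort_rho=cohort_rho)
        for sid in kept_ids
    }
    alpha = pd.Series({sid: lp.alpha for sid, lp in lprofiles.items()})
    raw = pd.Series({sid: lp.total_density for sid, lp in lprofiles.items()})
    infiltration = centre_binarise(alpha, cohort, hcfg)
    ldf = pd.DataFrame(
        {
            "sample_id": kept_ids,
            "centre_id": [prof_by_id[s].centre_id for s in kept_ids],
            "alpha": [lprofiles[s].alpha for s in kept_ids],
            "total_density": [lprofiles[s].total_density for s in kept_ids],
            "infiltration_class": [infiltration[s] for s in kept_ids],
        }
    )
    for t in TISSUE_TEXTURES:
        ldf[f"density_{t}"] = [lprofiles[s].density[t] for s in kept_ids]
        ldf[f"rho_{t}"] = [lprofiles[s].rho.get(t, np.nan) for s in kept_ids]
    ldf.to_csv(out / "lympho.tsv", sep="\t", index=False)
    stages["lympho"] = {
        "n_samples": len(ldf),
        "n_binarised": int((ldf["infiltration_class"] != "NA").sum()),
    }

    # --- margin enrichment ---------------------------------------------
    eligible = [
        sid
        for sid in kept_ids
        if margin_eligibility(prof_by_id[sid], cfg.min_normal_for_margin)
    ]
    mprofiles = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid in eligible:
            tmap, lmap = pooled[sid]
            mprofiles.append(margin_profile(tmap, lmap, partitions[sid]))
    mdf = margin_profiles_frame(mprofiles)
    mdf.to_csv(out / "margins.tsv", sep="\t", index=False)
    stages["margin_profile"] = {"n_eligible": len(eligible)}

    # --- association statistics ----------------------------------------
    results = []
    nclass = pd.Series({s: prof_by_id[s].n_class for s in kept_ids})
    if nclass.nunique() > 1:
        family = []
        for t in TISSUE_TEXTURES:
            vals = prof_df.set_index("sample_id").loc[kept_ids, f"prop_{t}"]
            family.append(associate(vals, nclass, feature=f"prop_{t}", group_var="n_class"))
        family.append(associate(alpha, nclass, feature="alpha", group_var="n_class"))
        results.extend(adjust_family(family))
    has_survival = {"os_months", "os_event"} <= set(cohort.columns)
    surv_groups = infiltration[infiltration != "NA"]
    if has_survival and surv_groups.nunique() > 1:
        sub = cohort.set_index(cohort["sample_id"].astype(str)).loc[surv_groups.index]
        res, _curves = survival_logrank(
            sub["os_months"], sub["os_event"], surv_groups
        )
        res.feature = "os_5yr~infiltration_class"
        results.append(res)
    sdf = association_table(results)
    sdf.to_csv(out / "stats.tsv", sep="\t", index=False)
    stages["stats"] = {"n_tests": len(sdf)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "profiles": prof_df,
        "qc": excluded,
        "lympho": ldf,
        "margins": mdf,
        "stats": sdf,
        "manifest": manifest,
    }
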
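# ctm — computational texture mapping for H&E tile maps

`ctm` is a toolkit for the *post-classification* stage of computational
histopathology. Given per-tile texture labels and lymphocyte scores from
any upstream classifier (one label from {cancer, normal, stroma, blood,
empty, other} and one score in [0, 1] per tile of a whole-slide image), it

- smooths tessellated texture maps by sliding-window majority vote with a
  cancer/stroma-prioritising tie hierarchy (3×3 window, stride 2),
- extracts the **tumour margin** — the band of non-cancer tissue tiles
  within two tiles (Chebyshev distance) of any cancer tile, via square
  morphological dilation — and the complementary non-margin tissue,
- profiles per-sample texture composition, applies cohort QC (<5% cancer
  exclusion, resolution band, manual centre lists) and stratifies samples
  into **N+** (≥1% normal renal tissue, peritumoural sampling) versus
  **N−** (<1%, tumour-core-only sampling),
- harmonises lymphocyte infiltration across clinical centres with
  texture-aware normalisation, and computes margin:non-margin texture and
  lymphocyte enrichment ratios,
- wraps the conventional association tests (Wilcoxon rank-sum,
  Kruskal–Wallis, χ², Benjamini–Hochberg, 5-year Kaplan–Meier log-rank).

The target users are computational-pathology groups working with
multi-centre archives (e.g. TCGA), where centres differ systematically in
how much peritumoural tissue they sample and how slides are stained — both
of which confound naive lymphocyte quantification.

## The harmonisation statistic

For a sample with texture areas `A_t` (tiles or px²) and per-texture
lymphocyte densities `d_t` (mean tile score over tiles of texture `t`),
the *relative lymphocyte proportion* rescales densities over the tissue
textures `T = [blood, cancer, normal, stroma, other]`:

    ρ_t = 100 · d_t / Σ_{u∈T} d_u      (%)   so that Σ_t ρ_t = 100

ρ is invariant to any multiplicative stain-intensity bias. The harmonised
infiltration is the area-weighted mean

    α = Σ_{t∈T} ρ_t · A_t / Σ_{t∈T} A_t      (%)

Residual staining differences are absorbed by binarising each sample to
High/Low at its clinical centre's median α, restricted to centres with
more than 20 samples.

## Worked example

No real slides are needed: the built-in generator emulates a multi-centre
cohort with centre-specific sampling conventions and stain bias but a
shared texture–lymphocyte enrichment profile.

```python
import pandas as pd
import ctm

cfg = ctm.SyntheticCohortConfig(
    seed=1,
    centres=[
        ctm.CentreConfig("A", n_samples=10, p_nplus=0.9, stain_bias=0.7),
        ctm.CentreConfig("B", n_samples=10, p_nplus=0.0, stain_bias=1.4),
    ],
    grid_shape=(40, 40),
)
maps, cohort, truth = ctm.generate_cohort(cfg)

raw, alpha = {}, {}
for sid, (tmap, lmap) in maps.items():
    lp = ctm.lympho_profile(tmap, lmap)
    raw[sid], alpha[sid] = lp.total_density, lp.alpha

report = ctm.harmonisation_report(pd.Series(raw), pd.Series(alpha), cohort)
print(round(report["raw"]["relative_between_centre_variance"], 4))
print(round(report["alpha"]["relative_between_centre_variance"], 4))
print(round(report["variance_ratio_alpha_raw"], 4))
```

prints

```
0.0389
0.0002
0.0045
```

Centre A stains weakly and samples peritumoural tissue; centre B stains
strongly and samples tumour cores only. The raw mean lymphocyte density
consequently differs between centres (relative between-centre variance
0.039), while the texture-harmonised α removes the stain bias and shrinks
the between-centre variance by more than two orders of magnitude (ratio
0.0045 ≪ 1) — the sampling-bias signal is gone, not the biology: the
ground-truth enrichment profile is identical in both centres by
construction.

The same workflow runs from the shell:

```bash
ctm simulate --out demo --seed 1
ctm run --config pipeline.yaml     # pool → QC → margin → lympho → stats
```

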
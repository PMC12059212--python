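# nestprospect

Floater prospecting and settlement analysis for nest-box colonies monitored
with RFID (PIT-tag) readers.

In many cavity-nesting birds, sexually mature males that fail to obtain a
nest site ("floaters") spend the breeding season visiting the active nests
of conspecifics. Why? They might be scouting public information (copy
successful neighbours), probing the fighting ability of owners, or simply
staking out a foothold so they are first in line when a cavity falls vacant.
`nestprospect` turns raw detection events from a colony of nest boxes into
the analyses that separate these hypotheses:

1. **Stage-resolved visitation models** — how many distinct male floaters
   visit a box per recorded hour across the nesting cycle (pre-laying,
   laying, incubation, four nestling-age bins), as a Poisson GLMM with a
   log-hours offset and a nest random intercept, plus a hurdle model
   (logit zero part + zero-truncated Poisson count part) for the nestling
   period.
2. **Prospecting home ranges** — per floater-year 95% minimum convex
   polygons (MCP) over the distinct boxes visited, their centroids, and a
   circle of the colony-median MCP area projected on each centroid.
3. **Permutation tests of settlement** — is the mean distance between a
   floater's prospecting centroid and its eventual nest smaller than when
   settlement boxes are re-drawn uniformly from the colony, and do more
   floaters settle inside their own prospected circle than chance allows?
   p = (1 + #extreme) / (B + 1) with B = 10,000 draws.
4. **Autocorrelation of reproductive success** — pooled lag-k Pearson
   correlation of per-box annual fledged counts, and a Moran's I
   correlogram over 100-m distance classes with permutation significance,

       I = (n/W) Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²

5. **Settlement-choice models** — one binomial GLMM per candidate-box
   predictor (previous-year fledging output, owner age / ornament / body
   condition / provisioning rate, owner disappearance), with floater
   identity and year as crossed random intercepts; reported as β, SE,
   odds ratio with 95% CI, and type-III Wald χ².

Because the statistical engine matters here, the mixed models are fitted by
an exact-likelihood engine written for this package: adaptive Gauss–Hermite
quadrature (15 nodes) for one random intercept and a joint Laplace
approximation for two crossed intercepts, with the zero-truncated Poisson
pmf p(y|λ, y>0) = λ^y e^{−λ} / (y! (1 − e^{−λ})) for the hurdle count part.
Fits agree with `lme4::glmer` to four decimals on shared fixtures.

A **synthetic colony generator** (`nestprospect.simulate`) produces the full
input bundle — boxes, breeding records, detections, recording bouts,
morphometrics — with planted effects (settlement log-odds
−d/`distance_decay` + `vacancy_logOR`·1[owner died], AR(1) box quality,
stage-dependent visitation), so every stage of the chain can be validated
against known ground truth.

## Worked example

Run the whole chain on a small simulated colony (60 boxes on 20 ha, two
years, 25 floaters per year, settlement decay 60 m and vacancy log-odds
log 2):

```python
from nestprospect.simulate import SimConfig
from nestprospect.pipeline import run_pipeline

cfg = SimConfig(n_boxes=60, area_ha=20, n_years=2, n_floaters_per_year=25,
                prospect_kernel_sd=80.0, distance_decay=60.0, seed=1)
res = run_pipeline(cfg, "demo_out", B=5000)
```

which prints/stores (seed 1):

```
median MCP ha: 2.99
mean centroid-to-nest distance: 120.7 m (null 198.0 m), p = 0.0002
settled within own circle: 9/25, p = 0.0202
lag-1 fledging autocorrelation: 0.143 (n pairs 60)
owner-not-returned OR: 3.00 (1.29-6.97), p = 0.0106, n_obs = 271
```

Reading this: floaters prospected a median 3.0-ha polygon and settled on
average 121 m from their prospecting centroid — well below the ~198 m
expected if nests were re-assigned at random (permutation p = 2·10⁻⁴, the
smallest value B = 5000 permutations can produce); 9 of 25 settled inside
their own prospected circle (p = 0.02). The vacancy odds ratio (3.00, wide
CI) points the right way for the planted OR 2 but 25 floaters give a noisy
estimate — at 3×500 floaters it concentrates on ~2.0 (see the acceptance
script). The stage model for the same run puts every nestling stage about
one log-unit above pre-laying (e.g. `stage[nestling_15_18]`
β = 1.08 ± 0.15), the familiar floaters-flock-to-chicks pattern.

The same stages are available as a CLI:

```bash
nestprospect simulate colony_dir --config-file cfg.yaml --seed 1
nestprospect process colony_dir --out visit_counts.csv
nestprospect homerange colony_dir --out homeranges.csv
nestprospect permtest colony_dir --out permtests.csv --B 10000
nestprospect autocorr colony_dir --out correlograms.csv
nestprospect settlement colony_dir --out settlement_models.csv
nestprospect all out_dir --seed 1        # everything + manifest + figures
```

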
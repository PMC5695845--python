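# metapart

Variance partitioning for tropical-forest metacommunities: from a tree
census and per-plot topographic covariates to a table that splits each
community attribute into pure-topography, shared, pure-space and unexplained
components — separately for the whole community, for common species, and for
an information-equalized set of rare species.

The package targets the study design of Amazonian forest-inventory
metacommunities: 46 plots of 25 m × 100 m (11.5 ha), all stems with
DBH ≥ 10 cm identified and measured, five geomorphometric covariates per
plot (elevation, slope, profile curvature, plan curvature, HAND).  Because
such census data are rarely deposited, the package ships a synthetic
metacommunity generator with known structure (species sorting, mass effect,
neutral, null), so every stage — and the partition's ability to recover the
generating process — is testable end to end.

## The analysis

1. **Census** — stems with DBH ≥ 10 cm are kept; per-stem aboveground
   biomass is `B = 0.044 · (DBH² · H)^0.9719` (DBH cm, H m, B kg); stems
   aggregate to plots × species matrices on abundance and biomass bases.
2. **Common/rare split** — species are ranked by total; the split sits at
   the knee of the rank–log(total) curve (or an explicit cutoff).  Rare
   species are removed from the abundant end of the rare set until the
   retained rarest tail matches the common matrix's information content
   `∑ pᵢ(1 − pᵢ)` (binomial variance of the incidence matrix).
3. **Responses** — six attributes per species group: standardized richness
   (OLS residuals of richness on abundance), total abundance, total
   biomass, and composition on incidence / abundance / biomass bases, the
   abundance composition Hellinger-transformed (`y'ᵢⱼ = √(yᵢⱼ / yᵢ₊)`).
4. **Spatial predictors** — PCNM: principal coordinates of the
   truncated plot-distance matrix (threshold = longest minimum-spanning-tree
   edge; beyond-threshold distances replaced by 4t).  Axes are kept if
   their eigenvalue is positive and Moran's I on the truncation graph is
   positive and permutation-significant.
5. **Forward selection** — per response and per predictor set (topography,
   space): double-stopping permutation forward selection (global test gate,
   per-step Freedman–Lane pseudo-F at α, global adjusted-R² ceiling).
6. **Partition** — with `ab = adjR²(Y~E)`, `bc = adjR²(Y~S)`,
   `abc = adjR²(Y~E∪S)` (Ezekiel adjustment
   `1 − (1−R²)(n−1)/(n−m−1)`):
   `a = abc − bc`, `b = ab + bc − abc`, `c = abc − ab`, `d = 1 − abc`,
   with Freedman–Lane permutation tests for the pure fractions a and c and
   unconditioned tests for the marginal models.

## Worked example

```python
from metapart.pipeline import AnalysisConfig, format_report, run_analysis
from metapart.synth import ScenarioConfig, generate_scenario

data = generate_scenario(ScenarioConfig(archetype="species_sorting", seed=42))
cfg = AnalysisConfig(seed=7, n_perm=199, moran_n_perm=199)
result = run_analysis(cfg, trees=data["trees"],
                      plots=data["plots"].set_index("plot_id"))
print(format_report(result.report, "text"))
```

prints (excerpt):

```
    attribute          group topography_pct shared_pct space_pct not_explained_pct
    Abundance          Total         20.4**          -         -             79.62
    Abundance  Common (1–30)         37.3**          -         -             62.75
    Abundance Rare (113–218)              -          -         -            100.00
 C. Abundance          Total          9.6**       30.0     3.1**             57.25
 C. Abundance  Common (1–30)         14.7**       46.0     4.7**             34.66
 C. Abundance Rare (113–218)          1.0**        1.8     0.3ns             96.83
```

Reading the `C. Abundance / Total` row: after forward selection, the pure
topographic component explains 9.6% (adjusted R²) of the Hellinger-
transformed composition, 30.0% is shared between topography and space
(the covariate fields are themselves spatially structured), 3.1% is purely
spatial, and 57.2% stays unexplained; stars mark permutation significance
(`*` p < 0.05, `**` p < 0.01, `***` p < 0.001).  As expected under species
sorting, environmental components dominate, and the rare-species rows are
mostly unexplained — rare species carry little signal.  `Common (1–30)`
means the knee of the rank-abundance curve put the 30 highest-ranked
species in the common group of this synthetic community.

The same analysis runs from the shell:

```
metapart simulate --archetype species_sorting --seed 42 --out data/
metapart analyze --config config.yaml --out reports/
```

and the numbered drivers under `analysis/` reproduce the full study
narrative (01 simulate → 02 rank/split → 03 PCNM → 04 partition reports →
05 recovery experiment), writing tables under `results/`.

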
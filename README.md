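# planktte

**Plankton size diversity and biomass trophic transfer.**

`planktte` is a Python toolkit for quantitative community ecologists working
with imaged plankton samples (FlowCAM, ZooSCAN and similar instruments). It
turns per-individual morphometric measurements into community-level
statistics and fits the models used to ask how size structure at two trophic
levels — nano-microplankton prey and mesozooplankton predators — shapes the
efficiency of biomass transfer between them.

The pipeline:

1. **Morphometry** — major/minor ellipse axes (µm) → prolate-spheroid
   biovolume `EllipVol = (π/6)·M·m²` → carbon biomass via configurable
   power-law conversion factors, with preservation-shrinkage correction for
   prey and removal of carnivorous mesozooplankton.
2. **Size diversity** — the Shannon-analogue entropy of the size
   distribution,

   ```
   μ = −∫ p_x(x) · log p_x(x) dx ,   x = log(EllipVol),
   ```

   where `p_x` is a weighted Gaussian kernel density estimate over the
   individuals of one trophic group in one sample. μ depends on relative
   abundances only, so it is mathematically independent of total biomass.
3. **Transfer metrics** — the trophic-transfer proxy
   `log₁₀(PPBR) = log₁₀(B_predator / B_prey)`, its production-rate
   validation target `log₁₀(PPPR)` (artificial-cohort growth rates,
   `g = ln(Wt/W0)/Δt`), the predator–prey mass ratio (PPMR), and a
   case-resampling bootstrap that propagates proxy uncertainty.
4. **Environment** — depth-weighted mean nutrient concentrations above the
   mixed layer (trapezoid rule) and log-transformed nutrient covariates.
5. **Inference** — random-intercept linear mixed models (station as the
   grouping unit), univariate predictor ranking, and exhaustive all-subsets
   model selection by AICc with interaction marginality, reporting
   estimate / s.e. / t / p / df tables under a containment-df convention
   (`df = n_obs − n_stations − n_slopes`).

Because real surveys of this kind are rarely redistributable, the package
includes a first-class synthetic-data generator producing station-structured
communities and regression tables with known ground truth, used throughout
the test suite for parameter-recovery checks.

## Worked example

Simulate a small survey, run the full chain, and select the best model:

```python
from planktte import (CommunitySimConfig, simulate_individuals,
                      BiomassConversionTable, size_diversity_table,
                      rank_univariate, dredge_all_subsets)
from planktte.morphometry import process_sample, communities_to_frame
from planktte.transfer_metrics import build_sample_summaries
from planktte.env_covariates import env_table

cfg = CommunitySimConfig(n_stations=10, samples_per_station=3,
                         n_prey_individuals=500, n_predator_individuals=300,
                         seed=42)
coms = [process_sample(c, BiomassConversionTable())
        for c in simulate_individuals(cfg)]
div = size_diversity_table(communities_to_frame(coms))
env = env_table({c.sample_id: c.env for c in coms})
summary = build_sample_summaries(coms, div, env)
print(summary[["sample_id", "log10_ppbr", "prey_mu", "predator_mu"]]
      .head(3).to_string(index=False))

table, _ = rank_univariate("log10_ppbr", ["prey_mu", "predator_mu", "sst"],
                           "station_id", summary)
print(table.to_string(index=False))
```

prints

```
sample_id  log10_ppbr  prey_mu  predator_mu
 ST001-01    4.118826 2.076887     2.169583
 ST001-02    3.984132 2.088167     2.069964
 ST001-03    3.995796 2.120199     2.066251

       term       aicc  estimate       se         t        p  df
predator_mu -31.537979  1.977574 0.578903  3.416074 0.002897  19
    prey_mu -25.251856 -2.474854 1.021328 -2.423173 0.025542  19
        sst -17.273516  0.004381 0.017353  0.252490 0.803374  19
```

Each summary row is one station/date sample: its predator:prey biomass
ratio on the log₁₀ scale and the two size diversities in nats (here both
groups were generated from bimodal log-biovolume mixtures, hence μ ≈ 2).
The ranking table reads like a standard mixed-model table: with 30 samples
over 10 stations and one slope, each univariate model carries
30 − 10 − 1 = 19 denominator df, and predictors are ordered by AICc. An
all-subsets search over `prey_mu`, `predator_mu` and their interaction
(`dredge_all_subsets`) then ranks the five admissible models and returns the
minimum-AICc fit.

The same stages are available from the shell:

```bash
planktte simulate --seed 42 --outdir data/
planktte run-all --config pipeline.yaml --outdir results/
```

`run-all` writes `sample_summary.csv`, `univariate_ranking.csv`,
`dredge_ranking.csv`, `best_model.csv` and a `run_manifest.json`; every
output embeds the configuration hash and reruns are byte-identical.

## Scope and limitations

The package deliberately excludes image processing and taxonomic
classification (inputs are already-measured particle tables), species-based
diversity indices, size-spectrum (NBSS) slope fitting, spatial
autocorrelation modelling and mechanistic food-web simulation. Biomass
conversion factors and the shrinkage correction default to placeholders and
must be supplied from the literature for real data. See `docs/methods.md`
for the full model documentation and numerical conventions.
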
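# stomacomm

Community-scale analysis of stomatal morphology: from locally measured
species traits to biomass-weighted trait distributions, environmental-
filtering tests, and trait–climate mixed models.

## The problem

Stomata — the epidermal pores that control leaf gas exchange — are
characterized at the species level by stomatal density (SD, pores mm⁻²),
stomatal length (SL, µm) and the stomatal pore index
(SPI = SD·SL², reported here as % of epidermis area). How these traits
assemble at the *community* level, and which climatic and soil gradients
drive that assembly, matters for predicting ecosystem carbon and water
fluxes. This package implements the full analysis chain for vegetation-
survey data (plots nested in sites, forest and grassland), plus a
synthetic-data generator with known ground truth so every stage can be
validated offline.

## The statistics at its core

For a plot with species relative biomass p_i and trait values t_i, the
community-weighted moments are

    CWM = Σ p_i t_i                      (mass-ratio identity)
    CWV = Σ p_i (t_i − CWM)²             (functional dispersion)
    CWS = Σ p_i (t_i − CWM)³ / CWV^(3/2)
    CWK = Σ p_i (t_i − CWM)⁴ / CWV²      (non-excess kurtosis)

Environmental filtering is tested by shuffling trait values across all
species-site records (composition and weights intact, 500
randomizations) and computing standardized effect sizes

    SES = (observed − mean(null)) / sd(null)

for the across-plot **variance of CWMs** (filtering ⇒ SES > 0:
communities diverge along gradients) and the across-plot **means of
CWV, CWS, CWK** (filtering ⇒ SES < 0: species converge within plots).

Trait–environment structure is quantified with random-intercept linear
mixed models (`moment ~ predictor + (1|site)`, REML), summarized by
Nakagawa marginal/conditional R², scanned over 27 environmental
variables (bio1–bio19 derived from monthly climate, the aridity index
MAP/PET, and 7 soil properties), and decomposed by all-orderings
hierarchical partitioning of per-group PCA axes into temperature /
precipitation / soil (or climatic mean / seasonality / extreme / soil)
shares.

## Worked example

```python
import stomacomm as sc

cfg = sc.SyntheticConfig(
    n_species=150, n_sites=20, plots_per_site=10,
    species_per_plot_mean=12, filtering_strength=2.0,
    env_effect_slope=0.8, seed=7,
)
ds = sc.generate_dataset(cfg)
moments = sc.moments_table(ds.species_traits, ds.plots)

wide = sc.pivot_moments(moments)
sd = wide[wide.trait == "SD"]
print("CWM(SD) fold range: %.1f" % sc.fold_range(sd["cwm"]))

ses = sc.run_null_model(
    ds.species_traits, ds.plots,
    sc.NullModelConfig(n_randomizations=500, seed=8, strata="all"),
)
print(ses[ses.trait == "SD"][["moment", "observed", "null_mean", "ses"]])

scan = sc.bivariate_scan(moments, ds.environment)
print(scan[(scan.trait == "SD") & (scan.moment == "cwm")].head(3))
```

prints (abridged):

```
CWM(SD) fold range: 3.8
trait moment    observed    null_mean    null_sd        ses
   SD    cwm 9361.185840  2521.887030 323.736703  21.126115
   SD    cwv 5606.735248 11166.938339 519.337407 -10.706340
   SD    cws    0.511551     0.791253   0.066466  -4.208215
   SD    cwk    3.473924     3.928462   0.248930  -1.825971
env_var  marginal_r2  conditional_r2
soil_ph     0.743819        0.863980
   sand     0.733605        0.864116
  bio12     0.725277        0.864227
```

This dataset was generated with strong filtering of stomatal density
along the precipitation gradient, and the analysis recovers exactly
that: the across-plot variance of CWM(SD) is far larger than the null
expects (SES ≈ +21), within-plot variance, skewness and kurtosis are
depressed (negative SES), and the top-ranked predictors of CWM(SD) are
the precipitation-gradient variables (annual precipitation and the soil
properties the generator co-varies with it).

## Command line

The same chain is available as a CLI:

```sh
stomacomm simulate --config cfg.yaml --out data/ --seed 1
stomacomm moments  --traits data/species_traits.csv --plots data/plots.csv --out moments.csv
stomacomm ses      --traits data/species_traits.csv --plots data/plots.csv --n 500 --seed 1 --strata each --out ses.csv
stomacomm env      --climate data/climate.csv --soil data/soil.csv --scheme both --out envdir/
stomacomm fit scan      --moments moments.csv --env envdir/env.csv --out scan.csv
stomacomm fit partition --moments moments.csv --env envdir/env.csv --scheme TPS --out partition.csv
stomacomm fit contrast  --moments moments.csv --out contrast.csv
```

Real survey data can be supplied in the same CSV formats (a species-site
trait table or raw photograph-level measurements, a plot composition
table, and per-site monthly climate and soil tables).

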
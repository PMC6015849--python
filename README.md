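# nichetime

Assemblage-level comparative analysis of **time-niche shifting in avian
predators** — hawks (Accipitriformes), owls (Strigiformes) and falcons
(Falconiformes).

Some predator species are active outside the period typical for their order:
crepuscular or occasionally nocturnal hawks, and day-active or strictly
crepuscular owls. These *time-shifters* are thought to arise where direct
**interference competition** (agonistic encounters with predators active in
the same period) is intense, rather than where indirect **exploitation
competition** (shared prey depletion) is. `nichetime` implements the full
analysis chain needed to test this at the assemblage level, and ships a
synthetic-data generator so that every stage can be exercised and validated
without the unpublished trait and range compilations.

## What the package does

1. **Activity classification** (`nichetime.activity`) — species are scored
   0/1/2 (unused / primary / occasional) for day, twilight and night.
   Hawks and falcons are *strict* when exclusively diurnal; owls are strict
   when nocturnal, with twilight counting as part of the night. Time-shifters
   are hawks with any twilight/night use and owls that are not strictly
   nocturnal. Falcons are excluded from shifter calls (mixed ancestral state).
2. **Ancestral states and phylogenetic signal** (`nichetime.phylo`) — the
   binary strict/non-strict character is modelled with the 2-state
   equal-rates Mk model (Felsenstein pruning, ML rate, flat root prior);
   continuous traits use Pagel's λ and λ-GLS regression
   (`MkAncestralState`, `PagelsLambda`, `PGLS` — statsmodels-style model
   objects whose `fit()` returns results with `summary()`).
3. **Assemblages** (`nichetime.rangegrid`) — breeding-range polygons are
   rasterized onto a 112.5 × 112.5 km grid in a spherical Mollweide
   projection. Per cell: total predator richness (exploitation index),
   richness of species frequently active in the focal order's typical period
   (interference index, optionally restricted to competitors > 30 cm), and
   time-shifter richness with a zero-versus-missing rule (zero only where
   the order occurs).
4. **Photoperiod** (`nichetime.photoperiod`) — day length and civil night
   length (sun more than 6° below the horizon) at the local summer solstice,
   the available "time resource".
5. **Body size** (`nichetime.sizestats`) — size resolution rules, log10
   transform, an exact implementation of **Hartigan's dip statistic** with
   Monte-Carlo p-values, the 30 cm small/large owl split, and shifter-versus-
   typical size comparisons with and without phylogenetic control.
6. **Spatial mixed model** (`nichetime.spatial`) — the headline model

   `y = Xβ + Zb + ε`, `b_realm ~ N(0, Ψ)`, `ε ~ N(0, σ²R)`,

   with z-scored response and fixed effects (interference, exploitation,
   day/night length), realm random intercept + random slope on total
   richness, and within-realm exponential correlation with nugget
   `r(d) = (1 − c)·exp(−d/ρ)`. REML estimation, ML-based AIC structure
   comparison, per-realm 40% subsampling and single-step simultaneous
   confidence intervals (max-|z| critical value).
7. **Synthetic data** (`nichetime.synthdata`) — Yule trees, Mk-evolved and
   clade-clustered activity states, Brownian log sizes with tunable λ and a
   shifter offset, disc ranges, longitude-band realms, and responses drawn
   from the spatial model with known coefficients.

The `nichetime` CLI (`classify`, `asr`, `lambda`, `grid`, `photoperiod`,
`sizes`, `fit`, `simulate`, `run`) wraps these stages; `nichetime run
--config config.toml` executes the whole pipeline with a reproducibility
manifest.

## Worked example

```python
import numpy as np
import nichetime as nt

# classification of the packaged worked-example table
fixture = nt.paper_fixture()
print(nt.tabulate_order_summary(fixture)[["n", "shifters", "pct_shifters"]])
#                    n  shifters  pct_shifters
# order
# Accipitriformes  158        38            24
# Falconiformes     46      <NA>          <NA>
# Strigiformes     192        71            37

# dip test of the owl-shifter size distribution (bimodal around 30 cm)
classified = nt.classify_table(fixture)
owls = classified[classified["order"] == "Strigiformes"]
sizes = owls.loc[owls["shifter"].fillna(False).astype(bool), "body_length_cm"]
print(nt.dip_test(np.log10(sizes), n_boot=9999, seed=1).summary())
# Hartigan dip test: D = 0.0796, p = 0.0016 (n = 71, 9999 Monte-Carlo draws)

# spatial mixed model on a synthetic world with known coefficients
df = nt.simulate_assemblage_scenario(seed=1)   # true beta = (0.5, 0.3, -0.2)
model = nt.SpatialRichnessModel(
    df, "response", ["interference", "exploitation", "time_length"],
    random_slope="exploitation", scale_response=False)
res = model.fit()
print(res.summary())
# Spatial realm mixed model (REML), family=exponential
#   n = 400, loglik = -537.155, AIC = 1094.31
#   sigma2 = 0.97473, range rho = 105.87 km, nugget c = 0.119
#   ...
# const                     0.1209    0.1121    1.08    0.2811
# interference              0.5303    0.0419   12.64 1.208e-36
# exploitation              0.3238    0.0805    4.03 5.697e-05
# time_length              -0.1419    0.0425   -3.34  0.000841
print(res.simultaneous_ci(seed=0))
```

The interference coefficient is recovered near its true value 0.5 with a
simultaneous 95% interval excluding zero — the qualitative signature the
analysis is designed to detect.

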
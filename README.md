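# driftlab

Tools for quantifying **ecological drift** — changes in population sizes due
to random births and deaths — in replicate bacterial communities, and for
simulating what the measured amount of drift does to diversity in large
metacommunities.

## The problem

In microbial ecology drift is usually inferred indirectly from community
snapshots, where it is confounded with selection, dispersal, and measurement
noise. A direct route is to grow *identical* replicate communities (triplicate
flasks split from one well-mixed culture) under identical conditions and ask
whether the variability of population densities across the replicates exceeds
what the counting method alone would produce. Flow-cytometric counting has a
density-dependent error: the coefficient of variation (CV) among repeated
aliquots of a single flask rises steeply at low cell density. Any replicate CV
in excess of that calibrated "background noise" can only be drift.

`driftlab` implements the full workflow:

1. **Noise calibration** (`driftlab.noise_model`). Candidate decreasing curves
   CV(d) — Michaelis–Menten decay `Vmax·K/(K+d)` (with and without a floor),
   exponential decay, power law, log-linear — are fitted to a calibration
   table by nonlinear least squares and ranked by AIC. The winner carries a
   parametric-bootstrap upper confidence band (default two-sided 99.5%) and
   the empirical false-discovery rate: the fraction of calibration
   observations above the band.
2. **Drift detection** (`driftlab.drift_detection`). Main-experiment
   observations are scored with z = (CV_obs − CV_noise(d)) / σ_resid. Two
   rules bracket the truth: the conservative *upper threshold* (z > 3, then
   the lowest `ceil(FDR · n_flagged)` positives are discarded; magnitude =
   CV_obs − upper band) and the sensitive *mean threshold* (z > 0; magnitude
   = CV_obs − mean curve). Positive magnitudes are fitted by maximum
   likelihood over {lognormal, exponential, gamma, weibull, normal} and
   ranked by AIC.
3. **Metacommunity simulation** (`driftlab.metacommunity_sim`). 100
   communities × 2000 species on a unidirectional dispersal ring, growth
   rates redrawn every generation from Normal(1, selection_sd), populations
   below one individual going extinct. Drift multiplies each population's
   growth rate by Normal(1, m/100) with m drawn from the fitted magnitude
   distribution. Each run evolves a drift-impacted and a drift-free twin
   under common random numbers, so the Bray–Curtis dissimilarity, richness
   difference ΔS, and Pielou-evenness difference between matched communities
   measure drift's effect in isolation.
4. **Synthetic data** (`driftlab.synthetic_data`). Generators for both
   experimental tables with known ground truth (true noise curve, injected
   drift of known magnitude distribution), making the pipeline testable end
   to end.

## Worked example

Generate synthetic data, calibrate, detect, and fit — all from the shell:

```bash
driftlab synth noise --seed 7 --out noise.csv
driftlab synth experiment --seed 2 --out main.csv
driftlab calibrate-noise --input noise.csv --out noise_model.json
# calibrate-noise: form=power_law fdr=0.3784 residual_sd=1.183 n=148
driftlab detect --input main.csv --noise-model noise_model.json \
    --threshold upper --out drift.csv
# detect[upper]: 177/360 populations, 128/210 communities positive
driftlab fit-drift --input drift.csv --threshold upper --out fit_upper.json
# fit-drift[upper]: family=lognormal params={'meanlog': 2.479, 'sdlog': 0.355} n=177
```

The calibration chose a power-law noise curve (on this synthetic draw it
edges out the generating Michaelis–Menten form by AIC — the two are nearly
identical over the calibrated density range) with an empirical FDR of 37.8%.
Under the upper threshold, 177 of 360 population observations exceed noise
(the synthetic table carries injected drift in every population, so roughly
half the observations being detectable is expected), and their magnitudes fit
a lognormal best — the family that was injected.

Simulating the reference scenario (strongest selection 0.167, weakest
dispersal 2%, drift magnitudes lognormal(meanlog 0.625, sdlog 0.889)):

```bash
driftlab simulate --config scenario.yaml --out run/
cat run/summary.json
# "final_bc": 0.3185,                       mean Bray-Curtis after 1000 generations
# "final_delta_s": -70.69,                  species lost per community due to drift
# "final_delta_evenness": -0.0381,          drift also makes communities less even
# "extinct_median_relabund_pct": 0.0424     the extinct are rare (median start ~0.04%)
```

Drift alone — identical selection, identical dispersal, common random
numbers — generates ~32% Bray–Curtis dissimilarity, costs each community ~71
of its 2000 species, and the casualties come from the rare tail.

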
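# Methods

## Background-noise model

**Model.** The coefficient of variation (percent) among triplicate counts of
identical samples is modelled as a smooth decreasing function of community
cell density d. Five candidate forms are fitted by nonlinear least squares on
untransformed (d, CV) pairs: Michaelis–Menten decay `Vmax·K/(K+d)`, the same
with an additive floor `+ c`, exponential decay `a·e^(−b·d) + c`, power law
`a·d^(−b)`, and a linear function of log10 d. Candidates are ranked by AIC
from the Gaussian residual likelihood; ties go to fewer parameters;
non-converging candidates are excluded with a warning. Over the calibrated
density range (1.6×10⁴–6.3×10⁷ cells/ml, all above the Michaelis constant)
the MM and power-law forms are nearly indistinguishable, so either may win on
a given dataset — downstream steps are agnostic to the winning form.

**Residual scale.** The z-score denominator is the standard deviation of
calibration residuals around the fitted curve. Default is a single constant
σ (degrees of freedom corrected for the fitted parameters); an optional
proportional mode σ(d) = α·CV(d) can be selected manually or by AIC
(`residual_mode="auto"`). Constant is the default because the z-score is
defined verbally as "standard deviations above the expected CV" with a
single scale, and because the proportional mode collapses to zero width at
high density, where a floor of instrument error clearly persists.

**Confidence band.** The upper detection band is the (1+level)/2 quantile
(default level 0.995, i.e. the 0.9975 quantile) of curve values under 2000
parameter vectors drawn from the estimated parameter covariance (fixed seed
stored in the model; the band is clipped from below at the fitted curve).
This is a *confidence band for the mean curve*, mirroring parameter-CI
machinery from standard statistics packages — not a prediction band for new
observations. Consequently the empirical false-discovery rate (the fraction
of calibration observations above the band) is far larger than 1 − level and
is itself a fitted quantity, carried forward to trim the weakest positives
during detection. The parametric bootstrap agrees with the first-order
delta-method band to within a few percent of the band width on
well-conditioned fits; at realistic residual scales the curve's nonlinearity
in (Vmax, K) skews the bootstrap band slightly wider, which we regard as the
more honest of the two.

## Drift detection

Observations are triplicate CVs at known community density, scored as
z = (CV_obs − CV_noise(d)) / σ. The start gate aborts an assay when any
population's time-zero z exceeds 2 (splitting the master culture introduced
variability); negative z never aborts. Two detection rules:

* **upper**: flag z > 3; among the flagged, discard the `ceil(FDR·n_flagged)`
  with the smallest magnitudes (magnitude = CV_obs − upper band). Ranking by
  magnitude rather than z reflects that magnitude is the reported,
  distribution-fitted quantity.
* **mean**: flag z > 0; magnitude = CV_obs − mean curve.

The upper rule's positives are a strict subset of the mean rule's. A
*community observation* is one (assay, time point) flask-triple snapshot; it
is positive when ≥ 1 member population is. With 7 strain mixes × 3 starting
densities × 10 time points this yields 210 community and 360 population
observations per experiment table.

Magnitudes (percent CV units throughout) are fitted by MLE over lognormal,
exponential, gamma, weibull (all with location fixed at 0) and normal, ranked
by AIC with k = number of free parameters. All-equal magnitudes return a
degenerate point-mass normal with a warning. Because weibull and gamma nest
the exponential at shape 1, AIC picks the exponential label on exponential
data only when the extra parameter buys < 1 nat of likelihood — about 70% of
replicate datasets; family identification should therefore be read as
"distribution shape", not an exact label.

## Metacommunity simulator

**State and update.** Communities × species abundance matrix, continuous
abundances. Per generation: (1) growth rates drawn i.i.d. Normal(1,
selection_sd) per population, truncated at 0 — fluctuating selection with no
persistent favourites, mean 1 approximating a system at carrying capacity
(no renormalization is applied; totals random-walk mildly); (2) the drift
twin multiplies each rate by Normal(1, m/100), m drawn per population per
generation from the fitted magnitude distribution (percent → fraction); (3)
abundances multiply by rates; (4) populations below the extinction threshold
(1 individual) are zeroed — extinction is deterministic truncation because
drift is modelled through rates, not demographic sampling; (5) ring
dispersal: community i sends fraction `dispersal` of every population to
community i+1 (the last feeds the first), conserving per-species totals
exactly. Dispersal-last matches a reading in which growing cells disperse.
A species extinct everywhere can never return (closed metacommunity).

**Initial state.** Per-species base abundances are log-normal with natural-log
parameters meanlog 4, sdlog 1.1 (median ≈ 55 individuals, a realistic rare
tail); each community's copy is the base × Normal(1, selection_sd) truncated
at 0 — the cross-community spread is *relative* to the base, since an
absolute spread of ~0.1 individuals would be invisible against abundances of
~55. A natural-scale mean of 4 would start half the species below the
extinction floor, so the log-scale reading is the only self-consistent one.

**Twins and randomness.** Each run evolves a drift and a no-drift twin from
the same initial matrix under three deterministic generator streams derived
from the config seed (initialization, shared base rates, drift). With no
drift distribution, the twins are bit-identical forever — every reported
difference is attributable to drift. Grid and sweep cells derive per-cell
seeds (< 2³¹) from the master seed, so individual cells are independently
reproducible.

**Outputs.** Per generation: metacommunity mean and sd of Bray–Curtis
dissimilarity between matched communities, mean ΔS (drift − no-drift
richness) and mean ΔPielou. At the end: every (community, species) pair
present in the no-drift twin but extinct in the drift twin, with its
generation-0 relative abundance; the metacommunity-wise *median* of those
abundances is reported because the distribution is strongly right-skewed.

**Reference scale and run times.** The reference scenario is 100 communities
× 2000 species × 1000 generations (~20 s on one CPU). Trend properties
(BC increasing with selection, decreasing with dispersal; no significant BC
trend with species count from 500 to 10,000) are established at a reduced
scale of 20 communities × 500 species × 200 generations with 5 (trends) or
3 (sweep) replicate seeds — the qualitative orderings are stable at this
scale and the sweep's OLS slope test is the same procedure as at full scale.

## Synthetic data generators

The noise generator draws log-uniform densities over the calibration range
and constructs triplicates whose sample CV is *exactly* the curve value plus
Gaussian scatter (residual_sd, default 1.5 percent CV), via a standardized
random direction — so the zero-scatter limit lies exactly on the curve. The
experiment generator grows triplicate flasks per assay exponentially
(per-assay doubling times uniform in 25–60 min), injects drift by perturbing
each flask's per-20-min growth factor by Normal(1, m/100) with m drawn per
(assay, strain, interval) from the configured distribution (default:
lognormal meanlog 0.625, sdlog 0.889), and applies measurement noise whose
CV scatters around the true noise curve with the same residual scale as the
calibration table — making noise-only z-scores approximately standard normal
by construction. Time-zero rows are emitted with CV at 0.8× the curve so the
start gate accepts by construction.

**What the generators do and do not emulate.** They reproduce the *design*
(7 mixes × 3 starting densities × 3 flasks × 10 time points; 148 calibration
observations) and the noise structure, not the organisms: growth kinetics
are generic, strain interactions absent, and the cytometer is reduced to a
CV curve. Because injected per-interval drift persists in flask densities,
the *observable* per-time-point magnitude accumulates roughly as the root of
the summed squared per-interval magnitudes: detected magnitudes are several
times larger than the injected per-interval values, and a heavy-tailed
injected family (e.g. exponential) is observed as lognormal-like. End-to-end
tests therefore validate recovery of the injected lognormal family and of
noise-curve parameters, not equality of per-interval and observed magnitude
scales. Passing tests show the pipeline is internally consistent; they do
not certify any particular biological magnitude of drift.

**Numerical notes.** vmax and K of the MM curve are strongly correlated when
all calibration densities exceed K (only their product is well constrained),
so parameter-recovery checks are run in the small-scatter regime
(residual_sd 0.1; median relative error ~2%, scaling roughly linearly with
scatter). Negative draws of truncated normals are clipped, not resampled
(tail mass ≤ 10⁻⁸ at the default sds). Degenerate inputs: all-zero abundance
vectors have richness 0 and evenness 1 by convention; calibration rows with
any zero count are dropped with a warning.

## Known limitations

* The drift-to-growth-rate conversion (magnitude percent → multiplicative
  rate CV) is the most direct reading of "drift changes growth rates with
  experimentally distributed magnitude", but other conversions with the same
  per-generation variance are observationally equivalent at the population
  level, and conversions with different variance scale the simulated
  β-diversity and species loss accordingly. Reference-scenario outputs
  should be read as order-of-magnitude statements.
* No demographic (integer, birth–death) stochasticity; drift acts only
  through rates, so very small populations are deterministic between the
  rate draw and the extinction floor.
* Dispersal topology is a fixed unidirectional ring; no dormancy, speciation
  or abundance-weighted species interactions.
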
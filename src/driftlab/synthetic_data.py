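"""Synthetic counterparts of the two experimental count tables.

The calibration workflow needs two inputs: a *noise table* of triplicate
counts of repeated aliquots from single flasks (no biology, only measurement
noise) and a *main-experiment table* of triplicate-flask growth time series
in which real replicate divergence — drift — may be present. This module
generates both with known ground truth so calibration, detection, and
distribution fitting can be validated end to end.

Ground-truth conventions
------------------------
* The true noise curve is Michaelis-Menten decay CV(d) = vmax * k / (k + d)
  with vmax = 30 (percent) and k = 1e4 (cells/ml): ~11% CV at the lowest
  calibration density (1.6e4), dropping below 3% above 1e5 cells/ml, matching
  the known accuracy plateau of the counting method at high density.
* Observed CVs scatter around the curve with Gaussian scale ``residual_sd``
  (default 1.5 percent CV — the order of the drift magnitudes the pipeline
  must resolve).
* Strain growth between samplings is exponential with per-assay doubling
  times uniform in 25-60 min; only between-flask variability matters to the
  pipeline, so the exact kinetics are deliberately generic.
* Injected drift multiplies each flask's per-20-min growth factor by
  Normal(1, m/100), with the magnitude m drawn per (assay, strain, interval)
  from the configured distribution — the same mechanism the metacommunity
  simulator assumes, so end-to-end recovery tests close the loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftlab.drift_detection import DriftDistributionFit
from driftlab.io import BASE_COLUMNS
from driftlab.noise_model import CANDIDATE_FORMS

STRAINS = ("chryseo", "staphylo", "bacillus")
#: the seven strain mixes: three monocultures, three pairs, the full triple
DEFAULT_COMBINATIONS = tuple(
    combo
    for r in (1, 2, 3)
    for combo in itertools.combinations(STRAINS, r)
)
DEFAULT_DENSITY_RANGE = (1.6e4, 6.3e7)
DEFAULT_START_DENSITIES = (5e4, 1e5, 1e6)
DEFAULT_TIME_POINTS = tuple(range(60, 241, 20))
SAMPLING_INTERVAL_MIN = 20

DEFAULT_INJECTED_DRIFT = DriftDistributionFit(
    "lognormal", {"meanlog": 0.625, "sdlog": 0.889}
)


@dataclass
class SyntheticNoiseSpec:
    """Ground truth for a noise-calibration table."""

    form: str = "michaelis_menten"
    params: dict = field(default_factory=lambda: {"vmax": 30.0, "k": 1e4})
    residual_sd: float = 1.5
    density_range: tuple = DEFAULT_DENSITY_RANGE
    n_observations: int = 148
    seed: int = 0

    def curve(self, density):
        form = CANDIDATE_FORMS[self.form]
        return form.func(np.asarray(density, float), *(self.params[p] for p in form.param_names))


@dataclass
class SyntheticExperimentSpec:
    """Ground truth for a main-experiment table (21 assays x 10 time points)."""

    combinations: tuple = DEFAULT_COMBINATIONS
    start_densities: tuple = DEFAULT_START_DENSITIES
    time_points: tuple = DEFAULT_TIME_POINTS
    doubling_time_range: tuple = (25.0, 60.0)
    injected_drift: DriftDistributionFit | None = field(
        default_factory=lambda: DEFAULT_INJECTED_DRIFT)
    noise: SyntheticNoiseSpec = field(default_factory=SyntheticNoiseSpec)
    measurement_noise: bool = True
    seed: int = 0


def _exact_cv_triplet(center: float, cv_pct: float, rng: np.random.Generator) -> np.ndarray:
    """Three counts with mean ``center`` and sample CV exactly ``cv_pct``.

    A standard-normal triple is standardized (mean 0, sample sd 1) and scaled,
    randomizing which replicate is high or low while pinning the CV.
    """
    while True:
        raw = rng.normal(size=3)
        sd = raw.std(ddof=1)
        if sd > 1e-9:
            break
    unit = (raw - raw.mean()) / sd
    counts = center * (1.0 + cv_pct / 100.0 * unit)
    return np.clip(counts, 0.0, None)


def generate_noise_table(spec: SyntheticNoiseSpec) -> pd.DataFrame:
    """Triplicate aliquot counts whose CVs scatter around the true noise curve.

    Densities are log-uniform over the calibration range; each observation is
    assigned a random strain mix and member strain (labels only — the noise
    model ignores them).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.density_range
    densities = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_observations))
    rows = []
    for density in densities:
        combo = DEFAULT_COMBINATIONS[rng.integers(len(DEFAULT_COMBINATIONS))]
        strain = combo[rng.integers(len(combo))]
        cv_true = float(spec.curve(density))
        cv_obs = max(cv_true + rng.normal(0.0, spec.residual_sd), 0.0) \
            if spec.residual_sd > 0 else cv_true
        counts = _exact_cv_triplet(density / len(combo), cv_obs, rng)
        rows.append(("-".join(combo), strain, density, *counts))
    df = pd.DataFrame(rows, columns=["combination_id", "strain_id", "density_cells_ml",
                                     "count1", "count2", "count3"])
    return df[BASE_COLUMNS]


def generate_experiment_table(spec: SyntheticExperimentSpec) -> pd.DataFrame:
    """Triplicate-flask growth time series with optional injected drift.

    Every (combination, starting density) assay grows three flasks from a
    common inoculum. Per 20-min interval each strain multiplies by a shared
    exponential growth factor; injected drift perturbs the factor per flask by
    Normal(1, m/100) with m drawn per (assay, strain, interval). Measured
    counts add multiplicative measurement noise of scale equal to the true
    noise CV at the flask's community density. Time-zero rows are emitted with
    sub-noise CV so the start gate accepts by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_intervals = max(spec.time_points) // SAMPLING_INTERVAL_MIN
    rows = []
    for combo in spec.combinations:
        for start_total in spec.start_densities:
            assay_id = f"{'-'.join(combo)}_{start_total:.0e}"
            d0 = start_total / len(combo)
            # true per-strain, per-flask trajectories over 20-min intervals
            traj = {}
            for strain in combo:
                doubling = rng.uniform(*spec.doubling_time_range)
                growth = 2.0 ** (SAMPLING_INTERVAL_MIN / doubling)
                flasks = np.full(3, d0)
                per_interval = [flasks.copy()]
                for _ in range(n_intervals):
                    if spec.injected_drift is not None:
                        m = float(spec.injected_drift.sample((), rng))
                        factors = np.clip(rng.normal(1.0, m / 100.0, 3), 0.0, None)
                    else:
                        factors = np.ones(3)
                    flasks = flasks * growth * factors
                    per_interval.append(flasks.copy())
                traj[strain] = np.vstack(per_interval)  # (n_intervals+1, 3)
            community = sum(traj[s] for s in combo)  # per-flask totals
            # time-zero gating rows: exact sub-noise CV
            density0 = float(community[0].mean())
            for strain in combo:
                cv0 = 0.8 * float(spec.noise.curve(density0))
                counts = _exact_cv_triplet(d0, cv0, rng)
                rows.append(("-".join(combo), assay_id, strain, density0, 0, *counts))
            for t in spec.time_points:
                k = t // SAMPLING_INTERVAL_MIN
                density = float(community[k].mean())
                for strain in combo:
                    true_counts = traj[strain][k]
                    if spec.measurement_noise:
                        # noise CV scatters around the curve exactly like the
                        # calibration table, so noise-only z-scores are ~N(0,1)
                        cv_noise = max(float(spec.noise.curve(density))
                                       + rng.normal(0.0, spec.noise.residual_sd), 0.0)
                        raw = rng.normal(size=3)
                        unit = (raw - raw.mean()) / max(raw.std(ddof=1), 1e-9)
                        measured = np.clip(
                            true_counts * (1.0 + cv_noise / 100.0 * unit), 0.0, None)
                    else:
                        measured = true_counts
                    rows.append(("-".join(combo), assay_id, strain, density, t, *measured))
    df = pd.DataFrame(rows, columns=["combination_id", "assay_id", "strain_id",
                                     "density_cells_ml", "time_min",
                                     "count1", "count2", "count3"])
    return df[["strain_id", "combination_id", "assay_id", "density_cells_ml",
               "count1", "count2", "count3", "time_min"]]
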
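"""Paired metacommunity simulations of ecological drift.

A metacommunity is a ring of communities linked by unidirectional dispersal
(community ``n`` sends a fixed fraction of every population to community
``n + 1``; the last feeds the first), with no gain or loss of individuals
from outside. Fluctuating selection is modelled as per-population growth
rates redrawn every generation from Normal(1, selection_sd), so no species is
permanently favoured; a mean rate of 1 represents a system at its carrying
capacity.

Drift enters as an extra multiplicative growth-rate perturbation whose CV is
drawn per population per generation from an experimentally fitted magnitude
distribution (percent CV units). Each simulation runs two *twins* from the
same initial state under common random numbers: one with the drift
perturbation, one without. Every difference between the twins — Bray–Curtis
dissimilarity between matched communities, richness difference ΔS, Pielou
evenness difference — is therefore attributable to drift alone.

Populations falling below one individual are truncated to extinct; a species
extinct everywhere can never return.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from driftlab.drift_detection import DriftDistributionFit

# paper-scale defaults; see ScenarioConfig
DEFAULT_SELECTION_LEVELS = tuple(np.round(np.linspace(0.071, 0.167, 5), 6))
DEFAULT_DISPERSAL_LEVELS = tuple(np.round(np.linspace(0.02, 0.20, 10), 6))
DEFAULT_SPECIES_COUNTS = (500, 1000, 2000, 4000, 6000, 8000, 10000)


@dataclass
class ScenarioConfig:
    """Parameters of one paired simulation.

    Defaults are the reference conditions: 100 communities of 2000 species
    grown for 1000 generations, initial per-species base abundances
    log-normal(meanlog 4, sdlog 1.1) (median ~55 individuals), cross-community
    variation proportional to selection strength, dispersal 2%, selection sd
    0.167, extinction below 1 individual.
    """

    n_communities: int = 100
    n_species: int = 2000
    generations: int = 1000
    dispersal: float = 0.02
    selection_sd: float = 0.167
    drift_distribution: DriftDistributionFit | None = None
    abundance_meanlog: float = 4.0
    abundance_sdlog: float = 1.1
    extinction_threshold: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_communities, self.n_species, self.generations) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.dispersal < 1:
            raise ValueError("dispersal must lie in [0, 1)")
        if self.selection_sd <= 0:
            raise ValueError("selection_sd must be > 0")
        if self.abundance_sdlog <= 0:
            raise ValueError("abundance_sdlog must be > 0")
        if self.drift_distribution is not None and not self.drift_distribution.positive_support:
            raise ValueError("drift distribution must have positive support")


@dataclass
class MetacommunityState:
    """Communities x species abundance matrix plus a generation counter."""

    abundances: np.ndarray
    generation: int = 0

    def copy(self) -> "MetacommunityState":
        return MetacommunityState(self.abundances.copy(), self.generation)


@dataclass
class PairedRunResult:
    """Trajectories and final summaries of one drift vs no-drift twin run.

    ``trajectory`` has one row per generation with columns ``generation,
    mean_bc, sd_bc, mean_delta_s, mean_delta_evenness`` (metacommunity mean /
    sd over matched community pairs; ΔS and ΔEvenness are drift minus
    no-drift, negative = loss in the drift twin). ``extinct_species`` lists
    every (community, species) pair present in the final no-drift community
    but extinct in its drift twin, with the species' generation-0 relative
    abundance in that community (percent).
    """

    config: ScenarioConfig
    trajectory: pd.DataFrame
    extinct_species: pd.DataFrame
    final_bc: float
    final_bc_sd: float
    final_delta_s: float
    final_delta_evenness: float
    extinct_median_relabund_pct: float
    final_drift_abundances: np.ndarray | None = None
    final_nodrift_abundances: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "selection_sd": self.config.selection_sd,
            "dispersal": self.config.dispersal,
            "n_species": self.config.n_species,
            "final_bc": self.final_bc,
            "final_bc_sd": self.final_bc_sd,
            "final_delta_s": self.final_delta_s,
            "final_delta_evenness": self.final_delta_evenness,
            "extinct_median_relabund_pct": self.extinct_median_relabund_pct,
            "n_extinct_records": len(self.extinct_species),
        }


# ---------------------------------------------------------------------------
# community metrics


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum(a)+sum(b)); 0 if both empty."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum() + b.sum()
    if total == 0:
        return 0.0
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / total)


def _bray_curtis_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    total = A.sum(axis=1) + B.sum(axis=1)
    mins = np.minimum(A, B).sum(axis=1)
    with np.errstate(invalid="ignore"):
        bc = np.where(total > 0, 1.0 - 2.0 * mins / total, 0.0)
    return bc


def richness(a) -> int:
    """Number of species with abundance > 0."""
    a = np.asarray(a, float)
    return int((a > 0).sum())


def pielou_evenness(a) -> float:
    """Shannon entropy of relative abundances over ln(richness); 1 when S <= 1."""
    a = np.asarray(a, float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size <= 1:
        return 1.0
    p = a / a.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(a.size)


def _pielou_rows(A: np.ndarray) -> np.ndarray:
    totals = A.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, A / totals, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    s = (A > 0).sum(axis=1)
    return np.where(s > 1, h / np.log(np.maximum(s, 2)), 1.0)


# ---------------------------------------------------------------------------
# simulation primitives


def initialize_metacommunity(config: ScenarioConfig, rng: np.random.Generator
                             ) -> MetacommunityState:
    """Initial abundances: log-normal species base x truncated-normal community factor.

    Each species draws a base abundance from
    log-normal(abundance_meanlog, abundance_sdlog); each community's copy is
    the base times Normal(1, selection_sd) truncated at zero, so the initial
    cross-community spread of a species scales with selection strength.
    """
    config.validate()
    base = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, config.n_species)
    factors = np.clip(
        rng.normal(1.0, config.selection_sd, (config.n_communities, config.n_species)), 0.0, None
    )
    return MetacommunityState(base[None, :] * factors, generation=0)


def draw_growth_rates(config: ScenarioConfig, shape, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Normal(1, selection_sd) growth rates truncated at zero."""
    if config.selection_sd < 0:
        raise ValueError("selection_sd must be >= 0")
    return np.clip(rng.normal(1.0, config.selection_sd, shape), 0.0, None)


def apply_drift(rates: np.ndarray, fit: DriftDistributionFit,
                rng: np.random.Generator) -> np.ndarray:
    """Perturb growth rates by drift of experimentally distributed magnitude.

    For each population a magnitude ``m`` (percent CV) is drawn from ``fit``
    and the rate is multiplied by Normal(1, m/100) truncated at zero. The
    input array is not modified.
    """
    if not fit.positive_support:
        raise ValueError("drift distribution must have positive support")
    m = fit.sample(rates.shape, rng)
    factors = np.clip(rng.normal(1.0, m / 100.0), 0.0, None)
    return rates * factors


def disperse(state: MetacommunityState, dispersal: float) -> MetacommunityState:
    """Ring dispersal: community i sends ``dispersal`` of each population to i+1.

    The per-species metacommunity total is conserved exactly.
    """
    if not 0 <= dispersal < 1:
        raise ValueError("dispersal must lie in [0, 1)")
    A = state.abundances
    moved = dispersal * A
    state.abundances = A - moved + np.roll(moved, 1, axis=0)
    return state


def step_generation(drift_state: MetacommunityState, nodrift_state: MetacommunityState,
                    config: ScenarioConfig, rng: np.random.Generator,
                    drift_rng: np.random.Generator | None = None) -> tuple:
    """Advance both twins one generation under common random numbers.

    One shared base-rate draw; the drift twin additionally perturbs its copy
    of the rates; abundances multiply by the rates, populations below the
    extinction threshold are zeroed, then both twins disperse. When
    ``drift_rng`` is omitted the drift perturbation consumes ``rng``.
    """
    if drift_state.abundances.shape != nodrift_state.abundances.shape:
        raise ValueError("twin states have mismatched shapes")
    rates = draw_growth_rates(config, nodrift_state.abundances.shape, rng)
    if config.drift_distribution is not None:
        drifted = apply_drift(rates, config.drift_distribution, drift_rng or rng)
    else:
        drifted = rates
    for state, r in ((drift_state, drifted), (nodrift_state, rates)):
        A = state.abundances
        A *= r
        A[A < config.extinction_threshold] = 0.0
        disperse(state, config.dispersal)
        state.generation += 1
    return drift_state, nodrift_state


# ---------------------------------------------------------------------------
# full runs


def run_paired_simulation(config: ScenarioConfig) -> PairedRunResult:
    """Run drift and no-drift twins from a common start and record trajectories.

    Randomness is split into three deterministic streams derived from
    ``config.seed`` — initialization, shared base rates, drift perturbation —
    so the no-drift twin of a run is bit-identical to a run with
    ``drift_distribution=None`` at the same seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    init_rng, base_rng, drift_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    start = initialize_metacommunity(config, init_rng)
    drift_state = start.copy()
    nodrift_state = start.copy()
    initial = start.abundances.copy()

    rows = np.empty((config.generations, 5))
    for g in range(config.generations):
        step_generation(drift_state, nodrift_state, config, base_rng, drift_rng)
        Ad, An = drift_state.abundances, nodrift_state.abundances
        bc = _bray_curtis_rows(Ad, An)
        delta_s = (Ad > 0).sum(axis=1) - (An > 0).sum(axis=1)
        delta_j = _pielou_rows(Ad) - _pielou_rows(An)
        rows[g] = (g + 1, bc.mean(), bc.std(ddof=1) if len(bc) > 1 else 0.0,
                   delta_s.mean(), delta_j.mean())

    trajectory = pd.DataFrame(
        rows, columns=["generation", "mean_bc", "sd_bc", "mean_delta_s", "mean_delta_evenness"]
    ).astype({"generation": int})

    extinct_mask = (nodrift_state.abundances > 0) & (drift_state.abundances == 0)
    comm_idx, spec_idx = np.nonzero(extinct_mask)
    with np.errstate(invalid="ignore"):
        rel0 = initial / initial.sum(axis=1, keepdims=True) * 100.0
    extinct = pd.DataFrame({
        "community": comm_idx,
        "species": spec_idx,
        "initial_relabund_pct": rel0[comm_idx, spec_idx],
    })
    median_relabund = float(np.median(extinct["initial_relabund_pct"])) if len(extinct) else np.nan

    last = trajectory.iloc[-1]
    return PairedRunResult(
        config=config,
        trajectory=trajectory,
        extinct_species=extinct,
        final_bc=float(last["mean_bc"]),
        final_bc_sd=float(last["sd_bc"]),
        final_delta_s=float(last["mean_delta_s"]),
        final_delta_evenness=float(last["mean_delta_evenness"]),
        extinct_median_relabund_pct=median_relabund,
        final_drift_abundances=drift_state.abundances,
        final_nodrift_abundances=nodrift_state.abundances,
    )


def _derived_seed(master: int, *key: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def run_scenario_grid(base_config: ScenarioConfig,
                      selection_levels: Sequence[float] = DEFAULT_SELECTION_LEVELS,
                      dispersal_levels: Sequence[float] = DEFAULT_DISPERSAL_LEVELS
                      ) -> pd.DataFrame:
    """Final summaries over the selection x dispersal scenario grid.

    Each cell runs one paired simulation under a deterministic per-cell seed
    derived from ``base_config.seed``. The default grid is 5 selection levels
    x 10 dispersal levels = 50 scenarios.
    """
    if list(selection_levels) != sorted(selection_levels) or \
            list(dispersal_levels) != sorted(dispersal_levels):
        raise ValueError("grid levels must be sorted ascending")
    rows = []
    for i, sel in enumerate(selection_levels):
        for j, disp in enumerate(dispersal_levels):
            cfg = replace(base_config, selection_sd=float(sel), dispersal=float(disp),
                          seed=_derived_seed(base_config.seed, i, j))
            rows.append(run_paired_simulation(cfg).summary())
    return pd.DataFrame(rows)


def run_species_sweep(base_config: ScenarioConfig,
                      scenarios: Sequence[tuple],
                      species_counts: Sequence[int] = DEFAULT_SPECIES_COUNTS,
                      replicates: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Final Bray-Curtis as a function of metacommunity species count.

    For each (selection_sd, dispersal) scenario the paired simulation is run
    ``replicates`` times at every species count, and final BC is regressed on
    species count by ordinary least squares.

    Returns
    -------
    (runs, trends)
        ``runs``: one row per (scenario, species count, replicate) with
        ``final_bc``. ``trends``: per-scenario OLS slope, adjusted R² and
        slope p-value.
    """
    import statsmodels.api as sm

    rows = []
    for k, (sel, disp) in enumerate(scenarios):
        for s_count in species_counts:
            for rep in range(replicates):
                cfg = replace(base_config, selection_sd=float(sel), dispersal=float(disp),
                              n_species=int(s_count),
                              seed=_derived_seed(base_config.seed, k, s_count, rep))
                res = run_paired_simulation(cfg)
                rows.append({"selection_sd": sel, "dispersal": disp,
                             "n_species": s_count, "replicate": rep,
                             "final_bc": res.final_bc})
    runs = pd.DataFrame(rows)

    trend_rows = []
    for (sel, disp), grp in runs.groupby(["selection_sd", "dispersal"], sort=False):
        X = sm.add_constant(grp["n_species"].to_numpy(float))
        fit = sm.OLS(grp["final_bc"].to_numpy(float), X).fit()
        trend_rows.append({"selection_sd": sel, "dispersal": disp,
                           "slope": float(fit.params[1]),
                           "adj_r2": float(fit.rsquared_adj),
                           "p_value": float(fit.pvalues[1])})
    return runs, pd.DataFrame(trend_rows)
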
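"""Detection and quantification of ecological drift against the noise model.

An observation is a triplicate-count CV at a known community cell density.
Its z-score is the number of residual standard deviations it lies above the
expected background-noise CV at that density. Two detection rules bracket the
true amount of drift:

* **upper threshold** (conservative): flag z > 3, then discard the lowest
  ``ceil(fdr * n_flagged)`` flagged observations ranked by magnitude — the
  empirical false-discovery fraction of the calibration set. Magnitude is the
  observed CV minus the upper confidence band.
* **mean threshold** (sensitive): flag any observation above the mean noise
  curve (z > 0); magnitude is the observed CV minus the mean curve.

The positive magnitudes (percent CV in excess of noise) are then fitted with
maximum likelihood across a set of candidate distributions; the winning
distribution parameterizes drift in the metacommunity simulator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from driftlab.io import COUNT_COLUMNS, triplicate_cv
from driftlab.noise_model import NoiseModel

logger = logging.getLogger(__name__)

THRESHOLDS = ("upper", "mean")
UPPER_Z_CUTOFF = 3.0
GATE_Z_CUTOFF = 2.0

#: candidate family -> (scipy distribution, frozen-fit kwargs, n free params)
_FAMILIES = {
    "lognormal": (st.lognorm, {"floc": 0}, 2),
    "exponential": (st.expon, {"floc": 0}, 1),
    "gamma": (st.gamma, {"floc": 0}, 2),
    "weibull": (st.weibull_min, {"floc": 0}, 2),
    "normal": (st.norm, {}, 2),
}
DEFAULT_FAMILIES = tuple(_FAMILIES)


@dataclass
class DriftDistributionFit:
    """A parametric distribution fitted to drift magnitudes (percent CV units).

    ``params`` uses conventional field parameterizations: lognormal
    ``meanlog/sdlog`` (natural log), exponential ``rate``, gamma
    ``shape/rate``, weibull ``shape/scale``, normal ``mean/sd``.
    """

    family: str
    params: dict
    n: int = 0
    aic_table: list = field(default_factory=list)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")

    @property
    def positive_support(self) -> bool:
        return self.family != "normal"

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        """Draw magnitudes (percent) from the fitted distribution."""
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["meanlog"], p["sdlog"], size)
        if self.family == "exponential":
            return rng.exponential(1.0 / p["rate"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], 1.0 / p["rate"], size)
        if self.family == "weibull":
            return p["scale"] * rng.weibull(p["shape"], size)
        return rng.normal(p["mean"], p["sd"], size)

    def median(self) -> float:
        p = self.params
        if self.family == "lognormal":
            return math.exp(p["meanlog"])
        if self.family == "exponential":
            return math.log(2.0) / p["rate"]
        if self.family == "gamma":
            return float(st.gamma.ppf(0.5, p["shape"], scale=1.0 / p["rate"]))
        if self.family == "weibull":
            return p["scale"] * math.log(2.0) ** (1.0 / p["shape"])
        return p["mean"]

    def to_dict(self) -> dict:
        return {"family": self.family, "params": self.params, "n": self.n,
                "aic_table": self.aic_table}

    @classmethod
    def from_dict(cls, d) -> "DriftDistributionFit":
        return cls(family=d["family"], params=dict(d["params"]), n=d.get("n", 0),
                   aic_table=list(d.get("aic_table", [])))


@dataclass
class DriftQuantification:
    """Annotated observations plus population- and community-level summaries."""

    observations: pd.DataFrame
    threshold: str
    n_populations: int
    n_positive: int
    n_communities: int
    n_communities_positive: int

    @property
    def population_fraction(self) -> float:
        return self.n_positive / self.n_populations if self.n_populations else 0.0

    @property
    def community_fraction(self) -> float:
        return self.n_communities_positive / self.n_communities if self.n_communities else 0.0

    def magnitudes(self) -> np.ndarray:
        """Positive drift magnitudes (percent) under the chosen threshold."""
        col = f"magnitude_{self.threshold}"
        vals = self.observations[col].to_numpy(float)
        return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# operations


def zscore(cv_obs, density, model: NoiseModel):
    """Standard-deviation units between an observed CV and the expected noise CV.

    Sign is preserved: observations below the curve get negative z.
    """
    scale = model.residual_scale(density)
    if np.any(np.asarray(scale) <= 0):
        raise ValueError("degenerate noise model: residual scale is zero")
    return (np.asarray(cv_obs, float) - model.predict(density)) / scale


@dataclass
class GateResult:
    accept: bool
    z_by_strain: dict


def gate_start(start_observations: pd.DataFrame, model: NoiseModel,
               strains: Sequence[str] | None = None) -> GateResult:
    """Check that replicate flasks were identical at inoculation.

    The experiment is aborted when any strain's time-zero z-score exceeds 2 —
    splitting the master culture then introduced variability, so the three
    flasks cannot be treated as identical starting communities. Negative z
    (variability below noise expectation) never aborts.
    """
    df = start_observations
    if "cv" not in df.columns:
        df = df.assign(cv=triplicate_cv(df[COUNT_COLUMNS].to_numpy(float)))
    if strains is not None:
        missing = set(strains) - set(df["strain_id"])
        if missing:
            raise ValueError(f"missing start observation for strain(s): {sorted(missing)}")
    z = zscore(df["cv"].to_numpy(float), df["density_cells_ml"].to_numpy(float), model)
    z_by_strain = dict(zip(df["strain_id"], (float(v) for v in z)))
    return GateResult(accept=bool(np.all(z <= GATE_Z_CUTOFF)), z_by_strain=z_by_strain)


def _community_key(df: pd.DataFrame) -> list:
    """A community observation is one (assay, time point) flask-triple snapshot."""
    keys = ["assay_id"] if "assay_id" in df.columns else ["combination_id"]
    if "time_min" in df.columns:
        keys.append("time_min")
    return keys


def annotate(observations: pd.DataFrame, model: NoiseModel) -> pd.DataFrame:
    """Append z, both positivity flags, and both magnitudes to an observation table.

    The upper-threshold FDR trim operates on the whole table: among rows with
    z > 3, the ``ceil(fdr * n_flagged)`` smallest ``magnitude_upper`` values
    are demoted to negative.
    """
    df = observations.copy()
    if "cv" not in df.columns:
        df["cv"] = triplicate_cv(df[COUNT_COLUMNS].to_numpy(float))
    density = df["density_cells_ml"].to_numpy(float)
    cv = df["cv"].to_numpy(float)
    df["z"] = zscore(cv, density, model)
    predicted = model.predict(density)
    upper = model.upper_ci(density)

    flagged = df["z"].to_numpy() > UPPER_Z_CUTOFF
    magnitude_upper = cv - upper
    n_flagged = int(flagged.sum())
    n_trim = math.ceil((model.fdr or 0.0) * n_flagged)
    positive_upper = flagged.copy()
    if n_trim > 0:
        idx = np.flatnonzero(flagged)
        order = idx[np.argsort(magnitude_upper[idx], kind="stable")]
        positive_upper[order[:n_trim]] = False
    df["positive_upper"] = positive_upper
    df["positive_mean"] = df["z"].to_numpy() > 0
    df["magnitude_upper"] = np.where(positive_upper, magnitude_upper, np.nan)
    df["magnitude_mean"] = np.where(df["positive_mean"], cv - predicted, np.nan)
    return df


def detect_and_quantify(observations: pd.DataFrame, model: NoiseModel,
                        threshold: str = "upper") -> DriftQuantification:
    """Score a main-experiment table against the noise model.

    ``observations`` must exclude the time-zero gating rows (``time_min`` 0);
    rows with ``time_min == 0`` are dropped here defensively.

    Returns per-population flags and magnitudes plus summary counts at the
    population level and at the community level (a community observation — one
    assay at one time point — is positive when at least one of its member
    populations is).
    """
    if threshold not in THRESHOLDS:
        raise ValueError(f"unknown threshold {threshold!r}; expected one of {THRESHOLDS}")
    if model.fdr is None:
        raise ValueError("noise model has no FDR; fit it on its calibration set first")
    df = observations
    if "time_min" in df.columns:
        df = df[df["time_min"] > 0]
    df = annotate(df, model)
    pos_col = f"positive_{threshold}"
    keys = _community_key(df)
    communities = df.groupby(keys, sort=False)[pos_col].any()
    return DriftQuantification(
        observations=df,
        threshold=threshold,
        n_populations=len(df),
        n_positive=int(df[pos_col].sum()),
        n_communities=len(communities),
        n_communities_positive=int(communities.sum()),
    )


def _params_from_scipy(family: str, fitted: tuple) -> dict:
    if family == "lognormal":
        s, _, scale = fitted
        return {"meanlog": float(np.log(scale)), "sdlog": float(s)}
    if family == "exponential":
        _, scale = fitted
        return {"rate": float(1.0 / scale)}
    if family == "gamma":
        a, _, scale = fitted
        return {"shape": float(a), "rate": float(1.0 / scale)}
    if family == "weibull":
        c, _, scale = fitted
        return {"shape": float(c), "scale": float(scale)}
    loc, scale = fitted
    return {"mean": float(loc), "sd": float(scale)}


def fit_drift_distribution(magnitudes, candidates: Sequence[str] = DEFAULT_FAMILIES
                           ) -> DriftDistributionFit:
    """Maximum-likelihood fit of candidate families to positive drift magnitudes.

    Families are ranked by AIC (2k - 2 logL); the best converged family is
    returned with its AIC table. Requires at least 20 strictly positive
    magnitudes — fewer cannot meaningfully discriminate the candidate shapes.
    """
    x = np.asarray(magnitudes, float)
    if len(x) < 20:
        raise ValueError("need at least 20 magnitudes to fit a distribution")
    if np.any(x <= 0):
        raise ValueError("drift magnitudes must be strictly positive")
    unknown = set(candidates) - set(_FAMILIES)
    if unknown:
        raise ValueError(f"unknown family/families: {sorted(unknown)}")

    if np.ptp(x) == 0:
        logger.warning("degenerate magnitudes (all equal): returning a point-mass normal fit")
        return DriftDistributionFit("normal", {"mean": float(x[0]), "sd": 0.0}, n=len(x),
                                    aic_table=[{"family": "normal", "aic": None,
                                                "converged": True, "degenerate": True}])

    aic_table = []
    best = None
    for family in candidates:
        dist, fit_kwargs, k = _FAMILIES[family]
        try:
            fitted = dist.fit(x, **fit_kwargs)
            loglik = float(np.sum(dist.logpdf(x, *fitted)))
            if not np.isfinite(loglik):
                raise ValueError("non-finite log-likelihood")
        except Exception as exc:
            logger.warning("family %s failed to fit: %s", family, exc)
            aic_table.append({"family": family, "aic": None, "converged": False})
            continue
        aic = 2 * k - 2 * loglik
        aic_table.append({"family": family, "aic": float(aic), "converged": True})
        if best is None or aic < best[0]:
            best = (aic, family, fitted)
    if best is None:
        raise RuntimeError("all candidate families failed to fit")
    _, family, fitted = best
    return DriftDistributionFit(family, _params_from_scipy(family, fitted),
                                n=len(x), aic_table=aic_table)
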
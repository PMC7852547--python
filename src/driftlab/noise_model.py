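"""Calibration of density-dependent measurement noise in triplicate cell counts.

Flow-cytometric counting of replicate aliquots from a single well-mixed flask
is not exact: at low cell density the signal-to-noise ratio of the instrument
drops and the coefficient of variation (CV) among identical samples grows.
Before replicate variability can be attributed to biology (ecological drift),
this "background noise" must be measured and modelled as a function of cell
density.

This module fits a set of candidate decreasing curves CV(density) to a
noise-calibration table by nonlinear least squares, selects the best by AIC,
and equips the winning curve with

* mean predictions (:func:`predict_cv`),
* an upper confidence band obtained by parametric bootstrap over the fitted
  parameter covariance (:func:`upper_ci`), and
* the empirical false-discovery rate — the fraction of calibration
  observations exceeding the band (:func:`compute_fdr`).

The band is a confidence band for the *mean* curve, not a prediction band for
new observations, so the empirical FDR is typically far above ``1 - ci_level``
and is carried forward by the detection step to trim the weakest positives.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from driftlab.io import COUNT_COLUMNS, triplicate_cv

logger = logging.getLogger(__name__)

DEFAULT_CI_LEVEL = 0.995
DEFAULT_BOOTSTRAP = 2000

# ---------------------------------------------------------------------------
# candidate curve forms


def _mm(d, vmax, k):
    return vmax * k / (k + d)


def _mm_floor(d, vmax, k, c):
    return vmax * k / (k + d) + c


def _exp_decay(d, a, b, c):
    return a * np.exp(-b * d) + c


def _power_law(d, a, b):
    return a * np.power(d, -b)


def _log_linear(d, a, b):
    return a + b * np.log10(d)


@dataclass(frozen=True)
class _Form:
    name: str
    func: Callable
    param_names: tuple
    guess: Callable  # (density, cv) -> dict of initial values
    bounds: Mapping  # param -> (lo, hi)


def _guess_mm(d, cv):
    vmax = max(float(np.max(cv)), 1e-6)
    return {"vmax": vmax, "k": float(np.quantile(d, 0.25))}


def _guess_mm_floor(d, cv):
    g = _guess_mm(d, cv)
    g["c"] = float(max(np.min(cv), 0.0))
    return g


def _guess_exp(d, cv):
    return {
        "a": float(max(np.max(cv) - np.min(cv), 1e-6)),
        "b": float(1.0 / np.quantile(d, 0.25)),
        "c": float(max(np.min(cv), 0.0)),
    }


def _guess_power(d, cv):
    pos = cv > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(d[pos]), np.log(cv[pos]), 1)
        return {"a": float(np.exp(intercept)), "b": float(-slope)}
    return {"a": 1.0, "b": 0.5}


def _guess_loglin(d, cv):
    slope, intercept = np.polyfit(np.log10(d), cv, 1)
    return {"a": float(intercept), "b": float(slope)}


_POS = (1e-12, np.inf)
CANDIDATE_FORMS: dict[str, _Form] = {
    f.name: f
    for f in [
        _Form("michaelis_menten", _mm, ("vmax", "k"), _guess_mm,
              {"vmax": _POS, "k": _POS}),
        _Form("michaelis_menten_floor", _mm_floor, ("vmax", "k", "c"), _guess_mm_floor,
              {"vmax": _POS, "k": _POS, "c": (0.0, np.inf)}),
        _Form("exponential_decay", _exp_decay, ("a", "b", "c"), _guess_exp,
              {"a": _POS, "b": _POS, "c": (0.0, np.inf)}),
        _Form("power_law", _power_law, ("a", "b"), _guess_power,
              {"a": _POS, "b": _POS}),
        _Form("log_linear", _log_linear, ("a", "b"), _guess_loglin,
              {"a": (-np.inf, np.inf), "b": (-np.inf, np.inf)}),
    ]
}
DEFAULT_CANDIDATES = tuple(CANDIDATE_FORMS)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TripletObservation:
    """One triplicate count measurement of a single bacterial population.

    ``density`` is the total cell density of the community the population was
    measured in (the covariate of the noise curve); ``counts`` are the three
    replicate density measurements of the population itself.
    """

    strain_id: str
    combination_id: str
    density: float
    counts: tuple
    time_min: float | None = None

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if len(self.counts) != 3:
            raise ValueError("exactly three replicate counts required")

    @property
    def cv(self) -> float:
        """Percent CV of the three counts (sample sd, n-1 denominator)."""
        return compute_cv(self.counts)


@dataclass
class NoiseModel:
    """A fitted CV-vs-density background-noise curve with its band machinery.

    Attributes
    ----------
    form : str
        Name of the winning candidate curve.
    params : dict
        Fitted coefficients of that curve, natural units.
    covariance : list of list
        Estimated parameter covariance (row order = ``param_names`` order),
        used by the parametric bootstrap of :func:`upper_ci`.
    residual_sd : float
        Standard deviation (percent CV) of calibration residuals around the
        fitted curve; the z-score denominator in constant mode.
    residual_alpha : float
        Proportionality constant of the optional proportional residual mode,
        sigma(d) = alpha * predict_cv(d).
    residual_mode : str
        "constant" or "proportional".
    ci_level : float
        Two-sided confidence level of the band (upper bound at the
        (1 + level)/2 bootstrap quantile).
    fdr : float or None
        Empirical exceedance fraction of the calibration set over the band.
    """

    form: str
    params: dict
    covariance: list
    residual_sd: float
    ci_level: float = DEFAULT_CI_LEVEL
    fdr: float | None = None
    n_obs: int = 0
    aic_table: list = field(default_factory=list)
    residual_mode: str = "constant"
    residual_alpha: float = 0.0
    bootstrap_n: int = DEFAULT_BOOTSTRAP
    seed: int = 0
    density_range: tuple = (0.0, np.inf)
    _param_draws: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- evaluation ---------------------------------------------------------

    def _curve(self, density):
        form = CANDIDATE_FORMS[self.form]
        return form.func(np.asarray(density, float), *(self.params[p] for p in form.param_names))

    def predict(self, density):
        density = np.asarray(density, float)
        if np.any(density <= 0):
            raise ValueError("density must be > 0")
        return self._curve(density)

    def residual_scale(self, density):
        """Standard deviation of CV scatter around the curve at ``density``."""
        if self.residual_mode == "proportional":
            return self.residual_alpha * self.predict(density)
        return np.broadcast_to(self.residual_sd, np.shape(np.asarray(density))).astype(float) \
            if np.ndim(density) else self.residual_sd

    def _bootstrap_params(self) -> np.ndarray:
        """Parameter vectors resampled from the estimated covariance (cached)."""
        if self._param_draws is None:
            names = CANDIDATE_FORMS[self.form].param_names
            mean = np.array([self.params[p] for p in names])
            cov = np.asarray(self.covariance, float)
            rng = np.random.default_rng(self.seed)
            if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
                draws = np.tile(mean, (self.bootstrap_n, 1))
            else:
                draws = rng.multivariate_normal(mean, cov, size=self.bootstrap_n,
                                                method="svd")
            self._param_draws = draws
        return self._param_draws

    def upper_ci(self, density, level: float | None = None):
        """Upper bound of the two-sided ``level`` confidence band at ``density``."""
        level = self.ci_level if level is None else level
        if not 0.5 < level < 1:
            raise ValueError("confidence level must lie in (0.5, 1)")
        density = np.asarray(density, float)
        if np.any(density <= 0):
            raise ValueError("density must be > 0")
        form = CANDIDATE_FORMS[self.form]
        draws = self._bootstrap_params()
        curves = form.func(density[..., None], *(draws[:, i] for i in range(draws.shape[1])))
        upper = np.quantile(curves, 0.5 + level / 2, axis=-1)
        # a mean-curve band never excludes the fitted mean itself
        return np.maximum(upper, self._curve(density))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": self.params,
            "covariance": np.asarray(self.covariance, float).tolist(),
            "residual_sd": self.residual_sd,
            "ci_level": self.ci_level,
            "fdr": self.fdr,
            "n_obs": self.n_obs,
            "aic_table": self.aic_table,
            "residual_mode": self.residual_mode,
            "residual_alpha": self.residual_alpha,
            "bootstrap_n": self.bootstrap_n,
            "seed": self.seed,
            "density_range": list(self.density_range),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseModel":
        d = dict(d)
        d["density_range"] = tuple(d.get("density_range", (0.0, np.inf)))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "NoiseModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# operations


def compute_cv(counts: Sequence[float]) -> float:
    """Percent CV of exactly three replicate counts: 100 * sd(n-1) / mean.

    Raises
    ------
    ValueError
        If not exactly three values are given (the assay design is strictly
        triplicate) or the mean is zero.
    """
    counts = np.asarray(counts, float)
    if counts.shape != (3,):
        raise ValueError("exactly three replicate counts required")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean of counts is zero")
    return float(100.0 * counts.std(ddof=1) / mean)


def _extract_density_cv(observations) -> tuple[np.ndarray, np.ndarray]:
    """(density, cv) arrays from a DataFrame or iterable of TripletObservation."""
    if isinstance(observations, pd.DataFrame):
        df = observations
        density = df["density_cells_ml"].to_numpy(float)
        if "cv" in df.columns:
            cv = df["cv"].to_numpy(float)
        else:
            cv = triplicate_cv(df[COUNT_COLUMNS].to_numpy(float))
        counts = df[COUNT_COLUMNS].to_numpy(float) if set(COUNT_COLUMNS) <= set(df.columns) else None
        if counts is not None:
            degenerate = (counts == 0).any(axis=1) | ~np.isfinite(cv)
        else:
            degenerate = ~np.isfinite(cv)
        if degenerate.any():
            logger.warning("dropping %d degenerate calibration rows (zero counts)",
                           int(degenerate.sum()))
            density, cv = density[~degenerate], cv[~degenerate]
        return density, cv
    obs = list(observations)
    return (np.array([o.density for o in obs], float),
            np.array([o.cv for o in obs], float))


def _fit_one(form: _Form, density, cv) -> lmfit.model.ModelResult | None:
    model = lmfit.Model(form.func, independent_vars=["d"])
    params = model.make_params()
    guesses = form.guess(density, cv)
    for name in form.param_names:
        lo, hi = form.bounds[name]
        params[name].set(value=guesses[name], min=lo, max=hi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(cv, params, d=density)
    except Exception as exc:  # non-convergence, singular jacobian, ...
        logger.warning("candidate %s failed to fit: %s", form.name, exc)
        return None
    if not result.success or not np.all(np.isfinite(list(result.best_values.values()))):
        logger.warning("candidate %s did not converge; excluded", form.name)
        return None
    return result


def fit_noise_model(
    observations,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    ci_level: float = DEFAULT_CI_LEVEL,
    residual_mode: str = "constant",
    bootstrap_n: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> NoiseModel:
    """Fit candidate noise curves to a calibration set and keep the AIC-best.

    Parameters
    ----------
    observations : DataFrame or iterable of TripletObservation
        Calibration measurements (repeated aliquots from single flasks); a
        DataFrame needs columns ``density_cells_ml`` and either ``cv`` or the
        three count columns.
    candidates : sequence of str
        Names from :data:`CANDIDATE_FORMS`.
    residual_mode : str
        "constant" (default), "proportional", or "auto" (choose by Gaussian
        AIC of the two residual-scale models).

    Notes
    -----
    At least 10 observations spanning two orders of magnitude in density are
    required — a narrower design cannot constrain a saturating decay curve.
    Candidates that fail to converge are excluded with a warning; AIC ties go
    to the candidate with fewer parameters.
    """
    density, cv = _extract_density_cv(observations)
    if len(density) < 10:
        raise ValueError("need at least 10 calibration observations")
    if np.any(density <= 0):
        raise ValueError("density must be > 0")
    if density.max() / density.min() < 100:
        raise ValueError("calibration densities must span >= 2 orders of magnitude")
    unknown = set(candidates) - set(CANDIDATE_FORMS)
    if unknown:
        raise ValueError(f"unknown candidate form(s): {sorted(unknown)}")

    results: dict[str, lmfit.model.ModelResult] = {}
    aic_table = []
    for name in candidates:
        res = _fit_one(CANDIDATE_FORMS[name], density, cv)
        if res is not None:
            results[name] = res
            aic_table.append({"form": name, "aic": float(res.aic),
                              "n_params": len(CANDIDATE_FORMS[name].param_names),
                              "converged": True})
        else:
            aic_table.append({"form": name, "aic": None,
                              "n_params": len(CANDIDATE_FORMS[name].param_names),
                              "converged": False})
    if not results:
        raise RuntimeError("all candidate noise curves failed to fit")

    best_name = min(results, key=lambda n: (results[n].aic, len(CANDIDATE_FORMS[n].param_names)))
    best = results[best_name]
    form = CANDIDATE_FORMS[best_name]
    params = {p: float(best.best_values[p]) for p in form.param_names}
    if best.covar is not None and np.all(np.isfinite(best.covar)):
        cov = best.covar
    else:
        cov = np.zeros((len(form.param_names),) * 2)

    fitted = form.func(density, *(params[p] for p in form.param_names))
    resid = cv - fitted
    residual_sd = float(resid.std(ddof=len(form.param_names)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fitted > 0, resid / fitted, np.nan)
    alpha = float(np.nanstd(ratio, ddof=len(form.param_names))) if np.isfinite(ratio).any() else 0.0

    mode = residual_mode
    if residual_mode == "auto":
        n = len(resid)
        ll_const = -0.5 * n * (np.log(2 * np.pi * residual_sd**2) + 1)
        sig_prop = np.maximum(alpha * fitted, 1e-12)
        ll_prop = float(np.sum(-0.5 * (np.log(2 * np.pi * sig_prop**2) + (resid / sig_prop) ** 2)))
        mode = "constant" if -2 * ll_const <= -2 * ll_prop else "proportional"
    elif residual_mode not in ("constant", "proportional"):
        raise ValueError(f"unknown residual_mode: {residual_mode!r}")

    model = NoiseModel(
        form=best_name,
        params=params,
        covariance=np.asarray(cov).tolist(),
        residual_sd=residual_sd,
        ci_level=ci_level,
        n_obs=len(density),
        aic_table=aic_table,
        residual_mode=mode,
        residual_alpha=alpha,
        bootstrap_n=bootstrap_n,
        seed=seed,
        density_range=(float(density.min()), float(density.max())),
    )
    model.fdr = compute_fdr(model, observations)
    return model


def predict_cv(model: NoiseModel, density):
    """Mean expected noise CV (percent) at ``density`` (cells per ml)."""
    return model.predict(density)


def upper_ci(model: NoiseModel, density, level: float | None = None):
    """Upper confidence bound of the noise curve at ``density``."""
    return model.upper_ci(density, level)


def compute_fdr(model: NoiseModel, observations) -> float:
    """Fraction of calibration observations whose CV exceeds the upper band."""
    density, cv = _extract_density_cv(observations)
    if len(density) == 0:
        raise ValueError("empty observation set")
    upper = model.upper_ci(density)
    return float(np.mean(cv > upper))
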
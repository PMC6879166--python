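"""Maximum-likelihood fitting and model selection.

The optimised parameters are the genome-wide average recombination rate
rho0, the category-switch probability delta and the Gamma shape alpha (both
only when k > 1), and the five spline control points of the demography (log
coalescence rates at the knot grid).  theta is *not* optimised: it is fixed
beforehand from the global heterozygosity h via theta = -log(1 - h), which
is unbiased to first order under the stationary coalescent.  Optimisation
uses Powell's derivative-free method on log/logit-transformed parameters
with box constraints enforced by the transforms, and is deterministic given
the data and starting point.

The homogeneous model (k = 1) doubles as the null model for AIC-based
selection and as the first step of the fixed-prior protocol used for
low-quality samples: demography is fitted with k = 1, then a heterogeneous
model is assembled from externally supplied (rho0, alpha, delta) without
re-optimisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .errors import InvalidArgumentError, NumericError
from .hmm import ObservedSequence, PosteriorField, forward_loglik, posterior_decode
from .model import (DEFAULT_KNOT_TIMES, Demography, MutationModel, RhoPrior,
                    build_kernel, build_rho_prior, build_time_discretization,
                    emission_matrix)

__all__ = ["ModelFit", "fit", "select_model", "decode_with_fixed_prior",
           "decode", "estimate_theta", "PRESETS"]

# discretisation presets (t x k); the product never exceeds 200 states
PRESETS = {"40x5": (40, 5), "20x10": (20, 10), "40x10": (40, 10),
           "40x1": (40, 1), "10x5": (10, 5)}

RHO_BOUNDS = (1e-6, 0.1)
DELTA_BOUNDS = (1e-8, 0.5)
ALPHA_BOUNDS = (0.05, 20.0)


@dataclass
class ModelFit:
    """A fitted (or assembled) model with its likelihood and AIC."""

    prior: RhoPrior
    demography: Demography
    mutation: MutationModel
    t: int
    k: int
    loglik: float
    n_params: int
    converged: bool = True
    n_iter: int = 0
    n_fev: int = 0
    data_hash: str = ""
    label: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def build(self):
        """(discretisation, kernel, emissions) for this parameter set."""
        disc = build_time_discretization(self.t, self.demography)
        kernel = build_kernel(self.prior, disc, self.demography)
        emissions = emission_matrix(self.mutation, disc)
        return disc, kernel, emissions

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "t": self.t, "k": self.k,
            "rho0": self.prior.rho0, "alpha": self.prior.alpha,
            "delta": self.prior.delta, "theta": self.mutation.theta,
            "knot_times": list(map(float, self.demography.knot_times))
            if self.demography.knot_times is not None else None,
            "knot_log_rates": list(map(float, self.demography.knot_log_rates))
            if self.demography.knot_log_rates is not None else None,
            "loglik": self.loglik, "n_params": self.n_params,
            "aic": self.aic, "converged": self.converged,
            "n_iter": self.n_iter, "n_fev": self.n_fev,
            "data_hash": self.data_hash, "label": self.label,
        }

    def save(self, path):
        from . import __version__
        d = {"version": __version__, **self.to_dict()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
        with open(str(path) + ".txt", "w") as fh:
            for key, val in d.items():
                fh.write(f"{key}={val}\n")

    @classmethod
    def load(cls, path) -> "ModelFit":
        with open(path) as fh:
            d = json.load(fh)
        if d["knot_log_rates"] is not None:
            demography = Demography.from_spline(
                np.asarray(d["knot_log_rates"]),
                np.asarray(d["knot_times"]))
        else:
            demography = Demography.constant(1.0)
        obj = cls(prior=build_rho_prior(d["alpha"], d["k"], d["delta"],
                                        d["rho0"]),
                  demography=demography,
                  mutation=MutationModel(d["theta"]),
                  t=d["t"], k=d["k"], loglik=d["loglik"],
                  n_params=d["n_params"], converged=d["converged"],
                  n_iter=d["n_iter"], n_fev=d["n_fev"],
                  data_hash=d["data_hash"], label=d["label"])
        return obj


def estimate_theta(obs: ObservedSequence) -> float:
    """Moment estimator of theta from global heterozygosity."""
    h = obs.het_fraction()
    if h <= 0:
        raise NumericError("no heterozygous sites; theta not estimable")
    return float(-np.log1p(-h))


def _clip_log(value, bounds):
    return np.log(np.clip(value, *bounds))


def _pack(rho0, delta, alpha, knots, k, opt_dem):
    x = [_clip_log(rho0, RHO_BOUNDS)]
    if k > 1:
        span = DELTA_BOUNDS[1] - DELTA_BOUNDS[0]
        x.append(logit(np.clip((delta - DELTA_BOUNDS[0]) / span, 1e-12,
                               1 - 1e-12)))
        x.append(_clip_log(alpha, ALPHA_BOUNDS))
    if opt_dem:
        x.extend(knots)
    return np.asarray(x, dtype=float)


def _unpack(x, k, opt_dem, fixed_knots):
    rho0 = float(np.clip(np.exp(x[0]), *RHO_BOUNDS))
    i = 1
    if k > 1:
        span = DELTA_BOUNDS[1] - DELTA_BOUNDS[0]
        delta = float(DELTA_BOUNDS[0] + span * expit(x[1]))
        alpha = float(np.clip(np.exp(x[2]), *ALPHA_BOUNDS))
        i = 3
    else:
        delta, alpha = 0.0, 1.0
    knots = np.asarray(x[i:], dtype=float) if opt_dem else fixed_knots
    knots = np.clip(knots, -8.0, 8.0)
    return rho0, delta, alpha, knots


def _objective_factory(obs, t, k, theta, knot_times, fit_demography,
                       opt_dem, fixed_knots, max_states):
    mutation = MutationModel(theta)

    def negloglik(x):
        rho0, delta, alpha, knots = _unpack(x, k, opt_dem, fixed_knots)
        try:
            demography = (Demography.from_spline(knots, knot_times)
                          if fit_demography else Demography.constant(1.0))
            disc = build_time_discretization(t, demography)
            prior = build_rho_prior(alpha, k, delta, rho0)
            kernel = build_kernel(prior, disc, demography, max_states)
            emissions = emission_matrix(mutation, disc)
            return -forward_loglik(obs, kernel, emissions)
        except NumericError:
            return 1e12

    return negloglik


def fit(obs: ObservedSequence, t: int, k: int,
        init: ModelFit | None = None, *, max_states: int = 200,
        maxiter: int = 200, maxfev: int | None = None,
        xtol: float = 1e-3, ftol: float = 1e-4,
        knot_times: np.ndarray | None = None,
        fit_demography: bool = True,
        refit_demography: bool = True) -> ModelFit:
    """Powell maximisation of the forward likelihood.

    For k > 1 without an explicit ``init``, the homogeneous (k = 1) model is
    fitted first and used as a warm start for rho0 and the demography.  With
    ``refit_demography=False`` the k > 1 stage keeps the warm-started spline
    control points fixed and only optimises (rho0, delta, alpha) — a staged
    scheme that co-estimates demography from the same data in the k = 1
    stage at a fraction of the cost.
    """
    if t < 1 or k < 1:
        raise InvalidArgumentError("t and k must be >= 1")
    if t * k > max_states:
        raise InvalidArgumentError(
            f"t*k = {t * k} exceeds the hidden-state budget {max_states}")
    theta = estimate_theta(obs)
    kt = DEFAULT_KNOT_TIMES if knot_times is None else np.asarray(knot_times)

    if init is None and k > 1:
        init = fit(obs, t, 1, max_states=max_states, maxiter=maxiter,
                   maxfev=maxfev, xtol=xtol, ftol=ftol, knot_times=kt,
                   fit_demography=fit_demography)
    if init is not None:
        rho0 = init.prior.rho0
        alpha = init.prior.alpha if init.k > 1 else 1.0
        delta = init.prior.delta if init.k > 1 else 1e-5
        knots = (init.demography.knot_log_rates
                 if init.demography.knot_log_rates is not None
                 else np.zeros(len(kt)))
    else:
        rho0, alpha, delta, knots = 0.5 * theta, 1.0, 1e-5, np.zeros(len(kt))

    opt_dem = fit_demography and (refit_demography or k == 1 or init is None
                                  or init.demography.knot_log_rates is None)
    knots = np.asarray(knots, dtype=float)
    x0 = _pack(rho0, delta, alpha, knots, k, opt_dem)
    fun = _objective_factory(obs, t, k, theta, kt, fit_demography, opt_dem,
                             knots, max_states)
    f0 = fun(x0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise NumericError("non-finite likelihood at the starting point")
    options = {"xtol": xtol, "ftol": ftol, "maxiter": maxiter}
    if maxfev is not None:
        options["maxfev"] = maxfev
    res = minimize(fun, x0, method="Powell", options=options)
    xbest = res.x if res.fun <= f0 else x0
    rho0, delta, alpha, kn = _unpack(xbest, k, opt_dem, knots)
    demography = (Demography.from_spline(kn, kt) if fit_demography
                  else Demography.constant(1.0))
    n_params = 1 + (2 if k > 1 else 0) + (len(kt) if fit_demography else 0)
    return ModelFit(prior=build_rho_prior(alpha, k, delta, rho0),
                    demography=demography, mutation=MutationModel(theta),
                    t=t, k=k, loglik=float(-min(res.fun, f0)),
                    n_params=n_params,
                    converged=bool(res.success), n_iter=int(res.nit),
                    n_fev=int(res.nfev), data_hash=obs.data_hash(),
                    label=f"fit_{t}x{k}")


@dataclass(frozen=True)
class ModelChoice:
    best: ModelFit
    delta_aic: float  # AIC(homogeneous) - AIC(heterogeneous); > 0 favours k>1
    heterogeneous_selected: bool


def select_model(fit_homogeneous: ModelFit,
                 fit_heterogeneous: ModelFit) -> ModelChoice:
    """AIC comparison of the constant-rho null against the heterogeneous
    model; ties go to the model with fewer parameters."""
    if fit_homogeneous.data_hash != fit_heterogeneous.data_hash:
        raise InvalidArgumentError("fits were produced on different data")
    if fit_homogeneous.t != fit_heterogeneous.t:
        raise InvalidArgumentError("fits use different time discretisations")
    d_aic = fit_homogeneous.aic - fit_heterogeneous.aic
    het_wins = d_aic > 0
    return ModelChoice(best=fit_heterogeneous if het_wins else fit_homogeneous,
                       delta_aic=float(d_aic),
                       heterogeneous_selected=bool(het_wins))


def decode_with_fixed_prior(obs: ObservedSequence, demography_fit: ModelFit,
                            rho0: float, alpha: float, delta: float,
                            k: int) -> ModelFit:
    """Assemble a heterogeneous model from a k = 1 demography fit plus
    externally supplied prior parameters, without re-optimising.

    This is the two-step protocol for samples whose missing data defeat the
    joint fit: coalescence rates come from the sample itself, the prior on
    recombination-rate variation from better data.
    """
    if demography_fit.k != 1:
        raise InvalidArgumentError("demography_fit must be a k = 1 fit")
    if k < 2:
        raise InvalidArgumentError("fixed-prior decoding requires k > 1")
    mf = ModelFit(prior=build_rho_prior(alpha, k, delta, rho0),
                  demography=demography_fit.demography,
                  mutation=demography_fit.mutation,
                  t=demography_fit.t, k=k, loglik=np.nan,
                  n_params=demography_fit.n_params,
                  converged=True, data_hash=demography_fit.data_hash,
                  label=f"fixed_prior_{demography_fit.t}x{k}")
    disc, kernel, emissions = mf.build()
    mf = replace(mf, loglik=forward_loglik(obs, kernel, emissions))
    return mf


def decode(obs: ObservedSequence, model_fit: ModelFit,
           window: int = 16384, want_joint: bool = False) -> PosteriorField:
    """Posterior decoding of a sequence under a fitted model.

    The model need not have been fitted on ``obs`` (fixed-prior protocol).
    """
    _, kernel, emissions = model_fit.build()
    return posterior_decode(obs, kernel, emissions, window=window,
                            want_joint=want_joint)
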
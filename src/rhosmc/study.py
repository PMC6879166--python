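"""Reproduction of the simulation study at desk scale.

One function runs a full replicate of a benchmark scenario: simulate a
piecewise-constant rho landscape and a pair of genomes, fit the homogeneous
and heterogeneous models, select by AIC, decode the posterior-mean map and
score it against the truth at 50 kb windows.

Study conditions (theta = 0.003, rho0 = 0.0012, Gamma shapes 0.5/5, mean
segment lengths 100 kb/1 Mb, 20-fold expansion at 0.01 / bottleneck at 0.5,
introgression split 2.0 with a 10% pulse at 0.125/0.25) are fixed; the
replicate length and discretisation are scaled down to desk size
(default 2 Mb, 10 x 5 states — see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inference, maps, simulate
from .hmm import ObservedSequence

__all__ = ["ScenarioResult", "LANDSCAPE_SCENARIOS", "run_landscape_replicate",
           "run_demography_replicate", "run_introgression_replicate",
           "shared_landscape_cohort"]

DEFAULT_L = 2_000_000
DEFAULT_T = 10
DEFAULT_K = 5
WINDOW = 50_000

# the four heterogeneous landscape designs plus the constant-rho null
LANDSCAPE_SCENARIOS = {
    "a0.5_g100k": (0.5, 100_000),
    "a0.5_g1M": (0.5, 1_000_000),
    "a5_g100k": (5.0, 100_000),
    "a5_g1M": (5.0, 1_000_000),
    "null": None,
}
# scenarios whose heterogeneity is identifiable at the reference scale
IDENTIFIABLE = ("a0.5_g100k", "a0.5_g1M", "a5_g1M")

# desk-scale lengths: the 1 Mb-segment designs run on longer sequences so a
# replicate still contains several landscape segments, and the low-contrast
# alpha=5 designs likewise, since their log-rate variance (the AIC effect
# size) is ~10x smaller than at alpha=0.5
SCENARIO_L = {"a0.5_g1M": 4_000_000, "a5_g1M": 6_000_000,
              "a5_g100k": 4_000_000}


@dataclass
class ScenarioResult:
    scenario: str
    seed: int
    r2_50kb: float | None
    aic_heterogeneous: bool
    fit_hom: inference.ModelFit
    fit_het: inference.ModelFit


def _sub_seed(seed: int, *idx: int) -> int:
    out = np.random.SeedSequence([seed, *idx]).generate_state(1)[0]
    return int(out % (2**31 - 1))


def _fit_and_score(obs, truth_rho, seed, t, k, maxiter, decode,
                   fit_span: int | None = None):
    """Fit both model classes, select by AIC, optionally decode and score.

    ``fit_span`` restricts the likelihood optimisation to a prefix of the
    sequence (decoding still covers all of it) — used for the very
    SNP-dense bottleneck replicates where full-length fitting dominates
    runtime without changing the optimum appreciably.
    """
    fit_obs = obs
    if fit_span is not None and fit_span < len(obs):
        fit_obs = ObservedSequence(obs.codes[:fit_span].copy())
    hom = inference.fit(fit_obs, t, 1, maxiter=maxiter, maxfev=150)
    het = inference.fit(fit_obs, t, k, init=hom, maxiter=maxiter, maxfev=80,
                        refit_demography=False)
    choice = inference.select_model(hom, het)
    r2 = None
    if decode:
        field = inference.decode(obs, het)
        rmap = maps.posterior_mean_rho(field, het.prior)
        r2 = maps.compare_r2(maps.bin_map(rmap, WINDOW),
                             maps.bin_values(truth_rho, WINDOW),
                             n_bootstrap=10, seed=seed).r2
    return het, hom, choice, r2


def run_landscape_replicate(scenario: str, seed: int, L: int | None = None,
                            t: int = DEFAULT_T, k: int = DEFAULT_K,
                            maxiter: int = 10,
                            decode: bool = True) -> ScenarioResult:
    """One replicate of a constant-demography landscape scenario."""
    if L is None:
        L = SCENARIO_L.get(scenario, DEFAULT_L)
    params = LANDSCAPE_SCENARIOS[scenario]
    if params is None:
        land = simulate.Landscape(
            starts=np.array([0]), lengths=np.array([L]),
            scales=np.array([1.0]), base_rate=simulate.RHO0_DEFAULT, L=L,
            seed=seed)
    else:
        alpha, g = params
        land = simulate.gen_rho_landscape(alpha, g, L,
                                          simulate.RHO0_DEFAULT,
                                          seed=_sub_seed(seed, 0))
    truth = simulate.simulate_sequential_smc(land, None, None,
                                             simulate.THETA_DEFAULT,
                                             seed=_sub_seed(seed, 1))
    het, hom, choice, r2 = _fit_and_score(truth.obs, land.per_site(), seed,
                                          t, k, maxiter, decode)
    return ScenarioResult(scenario=scenario, seed=seed, r2_50kb=r2,
                          aic_heterogeneous=choice.heterogeneous_selected,
                          fit_hom=hom, fit_het=het)


def run_demography_replicate(kind: str, seed: int, L: int = DEFAULT_L,
                             t: int = DEFAULT_T, k: int = DEFAULT_K,
                             maxiter: int = 10) -> ScenarioResult:
    """Landscape alpha=0.5, g=100 kb under a population-size change, with
    spline demography co-estimated."""
    dem = {"expansion": simulate.expansion_demography(),
           "bottleneck": simulate.bottleneck_demography()}[kind]
    land = simulate.gen_rho_landscape(0.5, 100_000, L,
                                      simulate.RHO0_DEFAULT,
                                      seed=_sub_seed(seed, 0))
    truth = simulate.simulate_sequential_smc(land, None, dem,
                                             simulate.THETA_DEFAULT,
                                             seed=_sub_seed(seed, 1))
    het, hom, choice, r2 = _fit_and_score(truth.obs, land.per_site(), seed,
                                          t, k, maxiter, decode=True,
                                          fit_span=1_200_000)
    return ScenarioResult(scenario=f"dem_{kind}", seed=seed, r2_50kb=r2,
                          aic_heterogeneous=choice.heterogeneous_selected,
                          fit_hom=hom, fit_het=het)


def run_introgression_replicate(pulse_time: float, seed: int,
                                L: int = DEFAULT_L, t: int = DEFAULT_T,
                                k: int = DEFAULT_K,
                                maxiter: int = 10) -> ScenarioResult:
    """Structured-coalescent pair (split 2.0, 10% pulse) fitted assuming
    panmixia."""
    land = simulate.gen_rho_landscape(0.5, 100_000, L,
                                      simulate.RHO0_DEFAULT,
                                      seed=_sub_seed(seed, 0))
    truth = simulate.simulate_structured_pair(land, pulse_time=pulse_time,
                                              seed=_sub_seed(seed, 1))
    het, hom, choice, r2 = _fit_and_score(truth.obs, land.per_site(), seed,
                                          t, k, maxiter, decode=True)
    return ScenarioResult(scenario=f"introgression_{pulse_time}", seed=seed,
                          r2_50kb=r2,
                          aic_heterogeneous=choice.heterogeneous_selected,
                          fit_hom=hom, fit_het=het)


def shared_landscape_cohort(n_pairs: int, seed: int, L: int = 1_000_000,
                            t: int = 10, k: int = 5):
    """Independent pairs evolving on one common rho landscape (no landscape
    evolution), for the time-restriction confounding analysis.

    Returns (landscape, list of SimulationTruth).
    """
    land = simulate.gen_rho_landscape(0.5, 100_000, L,
                                      simulate.RHO0_DEFAULT,
                                      seed=_sub_seed(seed, 0))
    truths = [simulate.simulate_sequential_smc(land, None, None,
                                               simulate.THETA_DEFAULT,
                                               seed=_sub_seed(seed, 1 + i))
              for i in range(n_pairs)]
    return land, truths
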
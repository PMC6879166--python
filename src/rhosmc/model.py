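"""Core model components of the Markov-modulated SMC' HMM.

Time is measured in coalescent units of 2·Ne generations throughout, so that
under a constant population size the pairwise TMRCA is Exp(1) distributed and
the per-site compound rates rho = 4·Ne·r and theta = 4·Ne·mu act on a tree of
height ``s`` as ``1 - exp(-rho*s)`` (recombination) and ``1 - exp(-theta*s)``
(heterozygosity).

The hidden state of the full model is a pair (recombination-rate category,
TMRCA interval).  The genealogy process along the genome follows the SMC'
transition kernel; the rate category follows its own symmetric Markov chain
with a single autocorrelation parameter delta.  The composite ("modulated")
chain has ``n = t*k`` states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

from .errors import InvalidArgumentError, NumericError

__all__ = [
    "Demography",
    "TimeDiscretization",
    "RhoPrior",
    "MutationModel",
    "TransitionKernel",
    "build_time_discretization",
    "build_rho_categories",
    "build_rho_transition",
    "smc_transition_matrix",
    "modulate",
    "emission_matrix",
    "spline_lambdas",
    "build_rho_prior",
    "build_kernel",
]

# Default spline knot grid on scaled time: two endpoints plus three internal
# knots, geometrically spaced so that both very recent (~0.01) and ancient
# (~0.5-2) population-size changes fall inside the flexible region.
DEFAULT_KNOT_TIMES = np.geomspace(0.005, 5.0, 5)

# Gauss-Legendre rule mapped to [0, 1]; 8 nodes are enough for ~1e-9 accuracy
# of the smooth within-interval integrals used below.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


class Demography:
    """Population-size history as a coalescence-rate function lambda(tau).

    Internally every history is represented as a piecewise-constant hazard on
    ``[0, inf)``; spline-parameterised histories are discretised on a fine
    geometric grid.  Rates are relative to the reference population size, so
    ``lambda = 1`` everywhere is the constant standard coalescent.
    """

    def __init__(self, breaks: np.ndarray, rates: np.ndarray,
                 knot_times: np.ndarray | None = None,
                 knot_log_rates: np.ndarray | None = None):
        breaks = np.asarray(breaks, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if breaks[0] != 0.0 or np.any(np.diff(breaks) <= 0):
            raise InvalidArgumentError("hazard breaks must start at 0 and increase")
        if len(rates) != len(breaks):
            raise InvalidArgumentError("need one rate per hazard segment")
        if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
            raise NumericError("coalescence rates must be positive and finite")
        self.breaks = breaks
        self.rates = rates
        # cumulative hazard at segment starts; sentinel +inf closes the tail
        cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(breaks))])
        self._cum = np.concatenate([cum, [np.inf]])
        self.knot_times = knot_times
        self.knot_log_rates = knot_log_rates

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, rate: float = 1.0) -> "Demography":
        return cls(np.array([0.0]), np.array([float(rate)]))

    @classmethod
    def piecewise(cls, change_times, rates) -> "Demography":
        """Step history: ``rates[i]`` applies on [change_times[i-1], change_times[i])."""
        breaks = np.concatenate([[0.0], np.asarray(change_times, dtype=float)])
        return cls(breaks, np.asarray(rates, dtype=float))

    @classmethod
    def from_spline(cls, knot_log_rates, knot_times=None,
                    grid_size: int = 128) -> "Demography":
        """Natural cubic spline through (log time, log rate) control points.

        ``knot_log_rates`` holds the log coalescence rate at the two endpoint
        knots and the three internal knots (five values); outside the knot
        span the rate is held constant at the endpoint values.
        """
        kt = DEFAULT_KNOT_TIMES if knot_times is None else np.asarray(knot_times, float)
        klr = np.asarray(knot_log_rates, dtype=float)
        if klr.shape != kt.shape:
            raise InvalidArgumentError("one log-rate per spline knot required")
        cs = CubicSpline(np.log(kt), klr, bc_type="natural")
        grid = np.geomspace(kt[0], kt[-1], grid_size)
        mids = np.sqrt(grid[:-1] * grid[1:])  # geometric midpoints
        log_rate = cs(np.log(np.clip(mids, kt[0], kt[-1])))
        rates = np.exp(np.concatenate([[klr[0]], log_rate, [klr[-1]]]))
        if not np.all(np.isfinite(rates)):
            raise NumericError("spline produced non-finite coalescence rates")
        breaks = np.concatenate([[0.0], grid])
        return cls(breaks, rates, knot_times=kt, knot_log_rates=klr)

    # -- queries -----------------------------------------------------------
    def rate_at(self, tau):
        tau = np.asarray(tau, dtype=float)
        idx = np.clip(np.searchsorted(self.breaks, tau, side="right") - 1,
                      0, len(self.rates) - 1)
        return self.rates[idx]

    def cumulative_hazard(self, tau):
        tau = np.asarray(tau, dtype=float)
        idx = np.clip(np.searchsorted(self.breaks, tau, side="right") - 1,
                      0, len(self.rates) - 1)
        return self._cum[idx] + self.rates[idx] * (tau - self.breaks[idx])

    def inverse_hazard(self, h):
        """Time tau with cumulative hazard h (prior quantile transform)."""
        h = np.asarray(h, dtype=float)
        idx = np.clip(np.searchsorted(self._cum, h, side="right") - 1,
                      0, len(self.rates) - 1)
        return self.breaks[idx] + (h - self._cum[idx]) / self.rates[idx]

    def hazard_arrays(self):
        """(breaks, rates, cumulative) triplet for compiled consumers."""
        return self.breaks, self.rates, self._cum


@dataclass(frozen=True)
class TimeDiscretization:
    """Discretisation of the TMRCA prior into ``t`` intervals.

    ``boundaries`` has length t+1, starts at 0 and ends with +inf;
    ``representative[j]`` is the conditional prior mean TMRCA inside interval
    j; ``lambdas[j]`` is the piecewise-constant coalescence rate used inside
    interval j and ``masses[j]`` the prior probability of the interval.
    """

    t: int
    boundaries: np.ndarray
    representative: np.ndarray
    lambdas: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        if self.t < 1:
            raise InvalidArgumentError("need at least one TMRCA interval")
        b = self.boundaries
        if len(b) != self.t + 1 or np.any(np.diff(b[:-1]) <= 0) or b[0] != 0:
            raise InvalidArgumentError("boundaries must be strictly increasing from 0")
        if not np.isinf(b[-1]):
            raise InvalidArgumentError("last boundary must be +inf")
        r = self.representative
        if np.any(r <= b[:-1]) or np.any(r[:-1] >= b[1:-1]):
            raise InvalidArgumentError("representatives must lie inside their interval")

    def boundary_hazard(self):
        """Cumulative hazard of the discretised prior at each boundary."""
        inc = self.lambdas[:-1] * np.diff(self.boundaries[:-1])
        return np.concatenate([[0.0], np.cumsum(inc), [np.inf]])


@dataclass(frozen=True)
class RhoPrior:
    """Discretised Gamma prior on the local recombination-rate multiplier.

    The Gamma has shape = rate = alpha (mean one); ``category_means`` are the
    means of its k equal-probability slices, ``delta`` the per-site switch
    probability, and ``rho0`` the genome-wide average rho per site.
    """

    alpha: float
    k: int
    category_means: np.ndarray
    delta: float
    rho0: float

    def __post_init__(self):
        if self.k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if not (0.0 <= self.delta < 1.0):
            raise InvalidArgumentError("delta must lie in [0, 1)")
        m = self.category_means
        if len(m) != self.k or np.any(np.diff(m) <= 0):
            raise InvalidArgumentError("category means must be strictly increasing")
        if abs(m.mean() - 1.0) > 1e-8:
            raise InvalidArgumentError("category means must average to 1")


@dataclass(frozen=True)
class MutationModel:
    """Scaled mutation rate theta = 4*Ne*mu, homogeneous for inference."""

    theta: float

    def __post_init__(self):
        if not (self.theta > 0 and np.isfinite(self.theta)):
            raise InvalidArgumentError("theta must be positive and finite")


@dataclass(frozen=True)
class TransitionKernel:
    """All transition matrices of the composite chain plus its stationary law."""

    q_smc_by_category: list
    q_rho: np.ndarray
    q_composite: np.ndarray
    stationary: np.ndarray
    t: int = field(default=0)
    k: int = field(default=0)

    @property
    def n(self) -> int:
        return self.q_composite.shape[0]


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def spline_lambdas(demography: Demography, disc) -> np.ndarray:
    """Per-interval coalescence rates: the history evaluated at interval
    left boundaries, held constant across each interval.

    ``disc`` may be a TimeDiscretization or a raw boundary array.
    """
    boundaries = getattr(disc, "boundaries", disc)
    lam = demography.rate_at(boundaries[:-1])
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise NumericError("non-finite or non-positive coalescence rate")
    return np.asarray(lam, dtype=float)


def build_time_discretization(t: int, demography: Demography | None = None,
                              tail_cap_factor: float = 5.0) -> TimeDiscretization:
    """Equal-prior-mass TMRCA intervals under ``demography``.

    Boundaries are the prior quantiles j/t; each interval's representative is
    the conditional prior mean, with the infinite final interval capped at
    ``tail_cap_factor`` times the penultimate boundary so that emissions stay
    finite.
    """
    if t < 1:
        raise InvalidArgumentError("t must be >= 1")
    dem = demography if demography is not None else Demography.constant(1.0)
    qs = np.arange(1, t) / t
    finite = dem.inverse_hazard(-np.log1p(-qs))
    boundaries = np.concatenate([[0.0], finite, [np.inf]])
    lambdas = spline_lambdas(dem, boundaries)

    # conditional means under the piecewise-constant discretised prior
    a = boundaries[:-1]
    b = boundaries[1:]
    width = b - a
    rep = np.empty(t)
    with np.errstate(over="ignore"):
        lam_w = lambdas * width
        # E[s | a <= s < b] = a + 1/lam - width / (exp(lam*width) - 1)
        tail = np.where(np.isinf(width), 0.0,
                        width / np.expm1(np.where(np.isinf(width), 1.0, lam_w)))
    rep[:] = a + 1.0 / lambdas - tail
    if t >= 2:
        cap = tail_cap_factor * boundaries[-2]
        rep[-1] = min(rep[-1], cap)

    inc = lambdas[:-1] * np.diff(boundaries[:-1])
    haz = np.concatenate([[0.0], np.cumsum(inc)])
    surv = np.exp(-haz)
    masses = np.concatenate([-np.diff(surv), [surv[-1]]])
    return TimeDiscretization(t=t, boundaries=boundaries, representative=rep,
                              lambdas=lambdas, masses=masses)


# ---------------------------------------------------------------------------
# recombination-rate prior
# ---------------------------------------------------------------------------

def build_rho_categories(alpha: float, k: int) -> np.ndarray:
    """Means of the k equal-probability slices of Gamma(alpha, rate=alpha).

    Uses the closed-form partial expectation of the Gamma distribution:
    E[X; X < x] = P(alpha+1, alpha*x) for mean-one shape/rate alpha, where P
    is the regularised lower incomplete gamma function.
    """
    if not (alpha > 0 and np.isfinite(alpha)):
        raise InvalidArgumentError("alpha must be positive")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    edges = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    partial = special.gammainc(alpha + 1.0, alpha * edges)  # E[X; X < edge]
    partial = np.concatenate([[0.0], partial, [1.0]])
    means = np.diff(partial) * k
    return means / means.mean()  # exact mean-one normalisation


def build_rho_prior(alpha: float, k: int, delta: float, rho0: float) -> RhoPrior:
    return RhoPrior(alpha=float(alpha), k=int(k),
                    category_means=build_rho_categories(alpha, k),
                    delta=float(delta), rho0=float(rho0))


def build_rho_transition(delta: float, k: int) -> np.ndarray:
    """Symmetric category-switch matrix: 1-delta on the diagonal and
    delta/(k-1) elsewhere."""
    if not (0.0 <= delta < 1.0):
        raise InvalidArgumentError("delta must lie in [0, 1)")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k == 1:
        return np.array([[1.0]])
    q = np.full((k, k), delta / (k - 1))
    np.fill_diagonal(q, 1.0 - delta)
    return q


# ---------------------------------------------------------------------------
# SMC' genealogy transition kernel
# ---------------------------------------------------------------------------

def smc_transition_matrix(disc: TimeDiscretization, demography: Demography | None,
                          rho_per_site: float) -> np.ndarray:
    """Single-site SMC' transition matrix between TMRCA intervals.

    On a tree of height ``s`` recombination events occur at rate ``rho*s``
    per site; each event places a uniform break point on the tree, and the
    detached lineage re-coalesces at the local coalescence rate, with two
    available partner lineages below ``s`` (one of which restores the old
    height: back-coalescence) and one above.  The matrix is computed as the
    exponential of the discretised jump generator, so multiple events per
    site are handled exactly and — because the continuous SMC' process is
    stationary with respect to the coalescent prior — the discretised prior
    is the stationary distribution of the result (up to quadrature error).
    The source height is integrated over its interval under the conditional
    prior; the within-interval re-coalescence integrals are evaluated in
    closed form on the piecewise-constant hazard.

    ``demography`` is accepted for interface symmetry; the per-interval rates
    already stored on ``disc`` define the hazard actually used.
    """
    if rho_per_site < 0:
        raise InvalidArgumentError("rho must be non-negative")
    t = disc.t
    if rho_per_site == 0.0:
        return np.eye(t)

    b = disc.boundaries          # t+1, last inf
    lam = disc.lambdas
    haz = disc.boundary_hazard()  # t+1, last inf
    masses = disc.masses
    cum_mass = np.concatenate([[0.0], np.cumsum(masses)])
    cum_mass[-1] = 1.0

    def hz(x):
        """Cumulative hazard of the discretised prior at times x (>=0)."""
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(b, x, side="right") - 1, 0, t - 1)
        out = haz[idx] + lam[idx] * (x - b[idx])
        return np.where(np.isinf(x), np.inf, out)

    def hz_inv(h):
        idx = np.clip(np.searchsorted(haz, h, side="right") - 1, 0, t - 1)
        return b[idx] + (h - haz[idx]) / lam[idx]

    gen = np.zeros((t, t))
    lower = b[:-1]
    upper = b[1:]
    for i in range(t):
        # source heights: Gauss-Legendre in conditional prior-CDF space
        p_nodes = cum_mass[i] + _GL_X * masses[i]
        s_nodes = hz_inv(-np.log1p(-np.minimum(p_nodes, 1.0 - 1e-15)))
        row = np.zeros(t)
        rate = 0.0
        for s, ws in zip(s_nodes, _GL_W):
            # break point u: piecewise Gauss-Legendre over [0, s], split at
            # the interval boundaries crossed below s
            cuts = np.concatenate([[0.0], b[1:i + 1][b[1:i + 1] < s], [s]])
            seg_lo = cuts[:-1]
            seg_len = np.diff(cuts)
            u = (seg_lo[:, None] + seg_len[:, None] * _GL_X[None, :]).ravel()
            wu = (seg_len[:, None] / s * _GL_W[None, :]).ravel()

            a_u = hz(u)[:, None]
            a_s = hz(s)
            # re-coalescence below s (rate 2*lambda, half of it changes TMRCA)
            x_lo = np.clip(lower[None, :], u[:, None], s)
            x_hi = np.clip(upper[None, :], u[:, None], s)
            below = 0.5 * (np.exp(-2.0 * (hz(x_lo) - a_u))
                           - np.exp(-2.0 * (hz(x_hi) - a_u)))
            # back-coalescence: TMRCA stays s (interval i)
            surv = np.exp(-2.0 * (a_s - a_u))  # (m, 1)
            below[:, i] += 0.5 * (1.0 - surv[:, 0])
            # re-coalescence above s (single partner lineage)
            y_lo = np.maximum(lower[None, :], s)
            y_hi = np.maximum(upper[None, :], s)
            with np.errstate(invalid="ignore"):
                above = surv * (np.exp(-(hz(y_lo) - a_s))
                                - np.exp(-(hz(y_hi) - a_s)))
            dest = below + np.nan_to_num(above)
            # jump intensity rho*s; destination split from the jump kernel
            row += ws * (rho_per_site * s) * (wu @ dest)
            rate += ws * rho_per_site * s
        gen[i] = row
        gen[i, i] -= rate
    q = expm(gen)
    # clip the tiny negative round-off expm can leave and re-normalise rows
    np.clip(q, 0.0, None, out=q)
    q /= q.sum(axis=1, keepdims=True)
    return q


# ---------------------------------------------------------------------------
# modulation and emissions
# ---------------------------------------------------------------------------

def modulate(q_smc_by_category: list, q_rho: np.ndarray) -> np.ndarray:
    """Composite n x n transition matrix with block (l, m) equal to
    ``q_rho[l, m] * q_smc_by_category[l]`` (source-category rate)."""
    k = len(q_smc_by_category)
    if q_rho.shape != (k, k):
        raise InvalidArgumentError("category matrix dimension mismatch")
    t = q_smc_by_category[0].shape[0]
    for m in q_smc_by_category:
        if m.shape != (t, t):
            raise InvalidArgumentError("all genealogy matrices must share dimensions")
    n = t * k
    q = np.empty((n, n))
    for l in range(k):
        block_row = q_smc_by_category[l]
        for m in range(k):
            q[l * t:(l + 1) * t, m * t:(m + 1) * t] = q_rho[l, m] * block_row
    return q


def emission_matrix(model: MutationModel, disc: TimeDiscretization) -> np.ndarray:
    """t x 3 emission probabilities for {homozygous, heterozygous, missing}.

    A site on a tree of height tau is heterozygous with probability
    1 - exp(-theta*tau) (infinite-sites pairwise difference); missing sites
    are uninformative and emit with probability one from every state.
    """
    tau = disc.representative
    p_het = -np.expm1(-model.theta * tau)
    return np.column_stack([1.0 - p_het, p_het, np.ones_like(tau)])


def build_kernel(prior: RhoPrior, disc: TimeDiscretization,
                 demography: Demography | None = None,
                 max_states: int = 200) -> TransitionKernel:
    """Assemble the composite transition kernel for a prior/discretisation.

    The stationary distribution is uniform over categories crossed with the
    discretised TMRCA prior, which is exact for this block construction.
    """
    n = disc.t * prior.k
    if n > max_states:
        raise InvalidArgumentError(
            f"{n} hidden states exceeds the configured maximum {max_states}")
    q_rho = build_rho_transition(prior.delta, prior.k)
    q_by_cat = [smc_transition_matrix(disc, demography, prior.rho0 * r)
                for r in prior.category_means]
    q_composite = modulate(q_by_cat, q_rho)
    stationary = np.kron(np.full(prior.k, 1.0 / prior.k), disc.masses)
    return TransitionKernel(q_smc_by_category=q_by_cat, q_rho=q_rho,
                            q_composite=q_composite, stationary=stationary,
                            t=disc.t, k=prior.k)
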
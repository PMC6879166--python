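"""Forward likelihood and posterior decoding for the composite HMM.

Sequences are run-length compressed: within a run of ``m`` identical symbols
the forward vector is advanced with cached binary powers of the
emission-weighted transition matrix, which reduces the recursion from ``m``
to ``popcount(m) + log2(m)`` matrix-vector products.  Contigs are chained by
re-initialising at the stationary distribution (genealogies do not continue
across chromosome boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import InvalidArgumentError, NumericError
from .model import TransitionKernel

__all__ = [
    "ObservedSequence",
    "PosteriorField",
    "compress_runs",
    "forward_loglik",
    "backward_loglik",
    "posterior_decode",
]

HOM, HET, MISSING = 0, 1, 2


@dataclass
class ObservedSequence:
    """Per-site observation codes {0: hom, 1: het, 2: missing} with a
    partition into contigs (half-open, 0-based intervals)."""

    codes: np.ndarray
    contigs: list = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 1:
            raise InvalidArgumentError("codes must be one-dimensional")
        if self.codes.size and self.codes.max() > 2:
            raise InvalidArgumentError("codes must be in {0, 1, 2}")
        if not self.contigs:
            self.contigs = [("seq", 0, len(self.codes))]
        pos = 0
        for name, start, end in self.contigs:
            if start != pos or end < start:
                raise InvalidArgumentError("contigs must tile [0, L) in order")
            pos = end
        if pos != len(self.codes):
            raise InvalidArgumentError("contigs must cover the full sequence")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.codes == MISSING)) if len(self) else 0.0

    def het_fraction(self) -> float:
        """Heterozygous fraction among non-missing sites."""
        ok = self.codes != MISSING
        n = int(ok.sum())
        if n == 0:
            raise NumericError("no informative (non-missing) sites")
        return float(np.sum(self.codes[ok] == HET) / n)

    def data_hash(self) -> str:
        import hashlib
        h = hashlib.blake2b(self.codes.tobytes(), digest_size=12)
        for name, start, end in self.contigs:
            h.update(f"{name}:{start}-{end}".encode())
        return h.hexdigest()


@dataclass
class PosteriorField:
    """Per-site posterior summaries over (category, TMRCA interval) states.

    ``cat_marginal[i, l]`` is the posterior probability of rate category l at
    site i (summed over intervals); ``map_interval[i]`` the MAP TMRCA
    interval (marginalised over categories); ``cat_given_map[i, l]`` the
    category posterior conditioned on that interval; ``fallback`` flags sites
    whose MAP interval had numerically vanishing mass (the conditional then
    falls back to the plain marginal).  ``joint`` (L x n) is materialised
    only for small problems.
    """

    cat_marginal: np.ndarray
    map_interval: np.ndarray
    cat_given_map: np.ndarray
    fallback: np.ndarray
    loglik: float
    t: int
    k: int
    codes: np.ndarray
    contigs: list
    joint: np.ndarray | None = None


def _rle(codes: np.ndarray):
    """Maximal runs of identical symbols as (symbols, lengths) arrays."""
    if len(codes) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(codes)]])
    return codes[starts].astype(np.int64), (ends - starts).astype(np.int64)


def compress_runs(obs: ObservedSequence):
    """Run-length representation, one (symbols, lengths) pair per contig."""
    return [_rle(obs.codes[start:end]) for _, start, end in obs.contigs]


def expand_emissions(emissions: np.ndarray, k: int) -> np.ndarray:
    """Tile the t x 3 emission table to the n = t*k composite states."""
    return np.ascontiguousarray(np.tile(emissions, (k, 1)))


def _power_tables(q: np.ndarray, e_n: np.ndarray, max_len: int):
    """Cached binary powers of Q·diag(e_c), normalised with log scalers.

    Returns (powers, powers_t, logscale) with shapes (3, nb, n, n) twice and
    (3, nb).
    """
    n = q.shape[0]
    nb = max(1, int(max_len).bit_length())
    powers = np.zeros((3, nb, n, n))
    logscale = np.full((3, nb), -np.inf)
    for c in range(3):
        p = q * e_n[None, :, c]
        for a in range(nb):
            sc = p.max()
            if sc <= 0 or not np.isfinite(sc):
                break
            powers[c, a] = p / sc
            logscale[c, a] = (logscale[c, a - 1] * 2 if a else 0.0) + np.log(sc)
            p = powers[c, a] @ powers[c, a]
    powers_t = np.ascontiguousarray(powers.transpose(0, 1, 3, 2))
    return powers, powers_t, logscale


def _check(ll: float, fail: int, contig) -> float:
    if fail >= 0 or not np.isfinite(ll):
        name, start, _ = contig
        raise NumericError(
            f"zero total probability at site {start + max(fail, 0)} "
            f"(contig {name})")
    return ll


def forward_loglik(obs: ObservedSequence, kernel: TransitionKernel,
                   emissions: np.ndarray) -> float:
    """Log-likelihood of the observations under the composite HMM.

    Each contig starts from the stationary distribution; per-site scaling
    keeps the recursion stable in probability space.
    """
    e_n = expand_emissions(emissions, kernel.k)
    if e_n.shape[0] != kernel.n:
        raise InvalidArgumentError("emission/kernel dimension mismatch")
    pi = kernel.stationary
    total = 0.0
    for (name, start, end), (syms, lens) in zip(obs.contigs, compress_runs(obs)):
        if len(syms) == 0:
            continue
        _, powers_t, logscale = _power_tables(kernel.q_composite, e_n,
                                              int(lens.max()))
        ll, fail = _kernels.forward_runs(syms, lens, powers_t, logscale, pi, e_n)
        total += _check(ll, fail, (name, start, end))
    return total


def backward_loglik(obs: ObservedSequence, kernel: TransitionKernel,
                    emissions: np.ndarray) -> float:
    """Same likelihood computed with the backward recursion (cross-check)."""
    e_n = expand_emissions(emissions, kernel.k)
    pi = kernel.stationary
    total = 0.0
    for contig, (syms, lens) in zip(obs.contigs, compress_runs(obs)):
        if len(syms) == 0:
            continue
        powers, _, logscale = _power_tables(kernel.q_composite, e_n, int(lens.max()))
        ll, fail = _kernels.backward_runs(syms, lens, powers, logscale, pi, e_n)
        total += _check(ll, fail, contig)
    return total


def posterior_decode(obs: ObservedSequence, kernel: TransitionKernel,
                     emissions: np.ndarray, window: int = 16384,
                     want_joint: bool = False) -> PosteriorField:
    """Forward-backward smoothed per-site posteriors.

    Memory is bounded by O(n * window); set ``want_joint`` to additionally
    materialise the full L x n joint posterior (small problems only).
    """
    e_n = expand_emissions(emissions, kernel.k)
    if e_n.shape[0] != kernel.n:
        raise InvalidArgumentError("emission/kernel dimension mismatch")
    t, k = kernel.t, kernel.k
    L = len(obs)
    q = np.ascontiguousarray(kernel.q_composite)
    q_t = np.ascontiguousarray(q.T)
    pi = kernel.stationary
    cat_marg = np.empty((L, k), dtype=np.float32)
    map_iv = np.empty(L, dtype=np.int16)
    cat_map = np.empty((L, k), dtype=np.float32)
    fallback = np.zeros(L, dtype=np.bool_)
    total = 0.0
    for name, start, end in obs.contigs:
        if end == start:
            continue
        ll, fail = _kernels.decode_core(
            obs.codes[start:end], q, q_t, e_n, pi, t, k,
            min(window, end - start),
            cat_marg[start:end], map_iv[start:end], cat_map[start:end],
            fallback[start:end])
        total += _check(ll if np.isfinite(ll) else -np.inf,
                        fail if not np.isfinite(ll) else -1,
                        (name, start, end))
    joint = None
    if want_joint:
        if L * kernel.n > 4_000_000:
            raise InvalidArgumentError("joint posterior requested for too "
                                       "large a problem; use the summaries")
        joint = _dense_joint(obs, q, e_n, pi)
    return PosteriorField(cat_marginal=cat_marg, map_interval=map_iv,
                          cat_given_map=cat_map, fallback=fallback,
                          loglik=total, t=t, k=k, codes=obs.codes,
                          contigs=obs.contigs, joint=joint)


def _dense_joint(obs, q, e_n, pi):
    """Plain dense forward-backward; reference path for small inputs."""
    L = len(obs)
    joint = np.empty((L, q.shape[0]))
    for _, start, end in obs.contigs:
        codes = obs.codes[start:end]
        m = end - start
        if m == 0:
            continue
        fs = np.empty((m, q.shape[0]))
        f = pi * e_n[:, codes[0]]
        fs[0] = f / f.sum()
        for i in range(1, m):
            f = (fs[i - 1] @ q) * e_n[:, codes[i]]
            fs[i] = f / f.sum()
        b = np.ones(q.shape[0])
        for i in range(m - 1, -1, -1):
            g = fs[i] * b
            joint[start + i] = g / g.sum()
            if i > 0:
                b = q @ (e_n[:, codes[i]] * b)
                b /= b.sum()
    return joint
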
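"""Compiled (numba) hot loops for the HMM recursions and the simulators.

All functions operate on a single contig; chaining across contigs (with
re-initialisation at the stationary distribution) happens in the callers.
Transition matrices are passed transposed where the access pattern benefits.
"""

import numpy as np
from numba import njit

__all__ = [
    "forward_runs",
    "backward_runs",
    "decode_core",
    "sample_hmm_path",
    "sequential_smc",
]


@njit(cache=True)
def forward_runs(symbols, lengths, powers_t, logscale, pi, e_n):
    """Scaled forward recursion over a run-length encoded contig.

    ``powers_t[c, a]`` is the transposed (normalised) 2^a-th power of
    Q·diag(e_c) and ``logscale[c, a]`` its accumulated log normaliser.
    Returns (logL, fail_site); ``fail_site >= 0`` flags a zero-probability
    site.
    """
    n = pi.shape[0]
    f = np.empty(n)
    c0 = symbols[0]
    for i in range(n):
        f[i] = pi[i] * e_n[i, c0]
    s = f.sum()
    if s <= 0.0 or not np.isfinite(s):
        return -np.inf, 0
    ll = np.log(s)
    f /= s
    site = 1
    for r in range(symbols.shape[0]):
        c = symbols[r]
        m = lengths[r]
        if r == 0:
            m -= 1
        bit = 0
        while m > 0:
            if m & 1:
                f = np.dot(powers_t[c, bit], f)
                s = f.sum()
                if s <= 0.0 or not np.isfinite(s):
                    return -np.inf, site
                ll += np.log(s) + logscale[c, bit]
                f /= s
            bit += 1
            m >>= 1
        site += lengths[r]
    return ll, -1


@njit(cache=True)
def backward_runs(symbols, lengths, powers, logscale, pi, e_n):
    """Backward analogue of :func:`forward_runs` (identical logL).

    ``powers`` here are the *untransposed* matrix powers.
    """
    n = pi.shape[0]
    b = np.ones(n)
    ll = 0.0
    for r in range(symbols.shape[0] - 1, -1, -1):
        c = symbols[r]
        m = lengths[r]
        if r == 0:
            m -= 1
        bit = 0
        while m > 0:
            if m & 1:
                b = np.dot(powers[c, bit], b)
                s = b.sum()
                if s <= 0.0 or not np.isfinite(s):
                    return -np.inf, r
                ll += np.log(s) + logscale[c, bit]
                b /= s
            bit += 1
            m >>= 1
    c0 = symbols[0]
    s = 0.0
    for i in range(n):
        s += pi[i] * e_n[i, c0] * b[i]
    if s <= 0.0 or not np.isfinite(s):
        return -np.inf, 0
    return ll + np.log(s), -1


@njit(cache=True)
def decode_core(codes, q, q_t, e_n, pi, t, k, window,
                cat_marg, map_iv, cat_map, fallback):
    """Forward-backward posterior decoding with windowed memory.

    A first backward sweep stores the (normalised) backward vector at window
    boundaries only; the second sweep reconstructs backward vectors inside
    one window at a time while running the forward recursion, so memory is
    O(n * window).  Per-site summaries are written into the pre-allocated
    output arrays: category marginals, the MAP TMRCA interval, the category
    posterior conditioned on that interval, and a flag for sites where the
    MAP interval carries (numerically) no mass.
    """
    L = codes.shape[0]
    n = q.shape[0]
    nw = (L + window - 1) // window
    bchk = np.empty((nw, n))

    # pass 1: backward checkpoints (b[i] = P(obs after i | state at i), scaled)
    b = np.ones(n)
    tmp = np.empty(n)
    bn = np.empty(n)
    if (L - 1) % window == 0 and (L - 1) // window < nw:
        bchk[(L - 1) // window] = b
    for i in range(L - 1, 0, -1):
        c = codes[i]
        for v in range(n):
            tmp[v] = e_n[v, c] * b[v]
        s = 0.0
        for u in range(n):
            acc = 0.0
            for v in range(n):
                acc += q[u, v] * tmp[v]
            bn[u] = acc
            s += acc
        if s <= 0.0:
            return np.nan, i
        for u in range(n):
            b[u] = bn[u] / s
        j = i - 1
        if j % window == 0:
            bchk[j // window] = b

    # pass 2: per-window backward reconstruction + forward sweep
    f = np.empty(n)
    fn = np.empty(n)
    c0 = codes[0]
    for v in range(n):
        f[v] = pi[v] * e_n[v, c0]
    s = f.sum()
    if s <= 0.0:
        return np.nan, 0
    ll = np.log(s)
    f /= s

    bbuf = np.empty((window, n))
    ivp = np.empty(t)
    for w in range(nw):
        s0 = w * window
        s1 = min(s0 + window, L)
        if s1 == L:
            for v in range(n):
                bbuf[s1 - 1 - s0, v] = 1.0
        else:
            c = codes[s1]
            for v in range(n):
                tmp[v] = e_n[v, c] * bchk[w + 1, v]
            s = 0.0
            for u in range(n):
                acc = 0.0
                for v in range(n):
                    acc += q[u, v] * tmp[v]
                bn[u] = acc
                s += acc
            for u in range(n):
                bbuf[s1 - 1 - s0, u] = bn[u] / s
        for i in range(s1 - 2, s0 - 1, -1):
            c = codes[i + 1]
            for v in range(n):
                tmp[v] = e_n[v, c] * bbuf[i + 1 - s0, v]
            s = 0.0
            for u in range(n):
                acc = 0.0
                for v in range(n):
                    acc += q[u, v] * tmp[v]
                bn[u] = acc
                s += acc
            for u in range(n):
                bbuf[i - s0, u] = bn[u] / s
        for i in range(s0, s1):
            gs = 0.0
            for v in range(n):
                gs += f[v] * bbuf[i - s0, v]
            for j in range(t):
                ivp[j] = 0.0
            for l in range(k):
                acc = 0.0
                for j in range(t):
                    p = f[l * t + j] * bbuf[i - s0, l * t + j] / gs
                    acc += p
                    ivp[j] += p
                cat_marg[i, l] = acc
            mi = 0
            best = ivp[0]
            for j in range(1, t):
                if ivp[j] > best:
                    best = ivp[j]
                    mi = j
            map_iv[i] = mi
            if best <= 1e-12:
                fallback[i] = True
                for l in range(k):
                    cat_map[i, l] = cat_marg[i, l]
            else:
                for l in range(k):
                    cat_map[i, l] = f[l * t + mi] * bbuf[i - s0, l * t + mi] \
                        / gs / best
            if i + 1 < L:
                c = codes[i + 1]
                s = 0.0
                for v in range(n):
                    acc = 0.0
                    for u in range(n):
                        acc += q_t[v, u] * f[u]
                    acc *= e_n[v, c]
                    fn[v] = acc
                    s += acc
                if s <= 0.0:
                    return np.nan, i + 1
                ll += np.log(s)
                for v in range(n):
                    f[v] = fn[v] / s
    return ll, -1


@njit(cache=True)
def sample_hmm_path(q_cum, e_het, pi_cum, L, seed):
    """Sample a hidden path and emissions from the composite chain.

    ``q_cum`` holds row-wise cumulative transition probabilities, ``e_het``
    the per-state heterozygosity probability.  Returns (states, codes).
    """
    np.random.seed(seed)
    n = q_cum.shape[0]
    states = np.empty(L, dtype=np.int32)
    codes = np.empty(L, dtype=np.uint8)
    u = np.random.random()
    s = 0
    while s < n - 1 and pi_cum[s] < u:
        s += 1
    for i in range(L):
        states[i] = s
        codes[i] = 1 if np.random.random() < e_het[s] else 0
        if i + 1 < L:
            u = np.random.random()
            nxt = 0
            row = q_cum[s]
            while nxt < n - 1 and row[nxt] < u:
                nxt += 1
            s = nxt
    return states, codes


@njit(cache=True)
def _haz_at(x, breaks, rates, cum):
    m = breaks.shape[0]
    i = m - 1
    for j in range(1, m):
        if breaks[j] > x:
            i = j - 1
            break
    return cum[i] + rates[i] * (x - breaks[i])


@njit(cache=True)
def _inv_haz_from(x0, h, breaks, rates, cum):
    """Smallest w >= x0 whose hazard integral from x0 equals h."""
    m = breaks.shape[0]
    target = _haz_at(x0, breaks, rates, cum) + h
    i = m - 1
    for j in range(1, m):
        if cum[j] > target:
            i = j - 1
            break
    return breaks[i] + (target - cum[i]) / rates[i]


@njit(cache=True)
def sequential_smc(rho_site, theta_site, breaks, rates, cum, seed):
    """Sequential pairwise SMC' simulator with a continuous TMRCA.

    Walks left to right: at each site the tree of height ``s`` recombines
    with probability 1 - exp(-rho_i*s); the break point is uniform on [0, s],
    and the floating lineage re-coalesces at rate 2*lambda below ``s`` (half
    of those events restore the old height: back-coalescence) and rate
    lambda above.  Emits heterozygous sites with probability
    1 - exp(-theta_i*s).
    """
    np.random.seed(seed)
    L = rho_site.shape[0]
    codes = np.empty(L, dtype=np.uint8)
    tmrca = np.empty(L, dtype=np.float32)
    s = _inv_haz_from(0.0, -np.log(np.random.random()), breaks, rates, cum)
    for i in range(L):
        tmrca[i] = s
        codes[i] = 1 if np.random.random() < -np.expm1(-theta_site[i] * s) else 0
        if i + 1 < L:
            if np.random.random() < -np.expm1(-rho_site[i] * s):
                u = np.random.random() * s
                # phase 1: two partner lineages on (u, s)
                h1 = -np.log(np.random.random()) / 2.0
                w = _inv_haz_from(u, h1, breaks, rates, cum)
                if w < s:
                    if np.random.random() < 0.5:
                        s = w  # coalesced onto the sister branch
                    # else back-coalescence: height unchanged
                else:
                    # phase 2: single ancestral lineage above s
                    h2 = -np.log(np.random.random())
                    s = _inv_haz_from(s, h2, breaks, rates, cum)
    return codes, tmrca
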
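import numpy as np
import pytest

import rhosmc as r


@pytest.fixture(scope="session")
def disc5():
    return r.build_time_discretization(5)


@pytest.fixture(scope="session")
def toy_model():
    """Tiny t=2, k=2 model for exhaustive-enumeration checks."""
    disc = r.build_time_discretization(2)
    prior = r.build_rho_prior(alpha=1.0, k=2, delta=0.05, rho0=0.02)
    kernel = r.build_kernel(prior, disc)
    emissions = r.emission_matrix(r.MutationModel(0.4), disc)
    return disc, prior, kernel, emissions


@pytest.fixture(scope="session")
def human_like_sim():
    """A 300 kb sequential-SMC' simulation with human-like rates."""
    land = r.gen_rho_landscape(0.5, 100_000, 300_000, 0.0012, seed=7)
    truth = r.simulate_sequential_smc(land, None, None, theta0=0.003, seed=8)
    return land, truth


def brute_force_forward(codes, q, e_n, pi):
    """Sum over all n^L hidden paths; independent oracle for the forward
    recursion (feasible only for tiny instances)."""
    n = q.shape[0]
    L = len(codes)
    total = 0.0
    paths = np.indices((n,) * L).reshape(L, -1).T
    for path in paths:
        p = pi[path[0]] * e_n[path[0], codes[0]]
        for i in range(1, L):
            p *= q[path[i - 1], path[i]] * e_n[path[i], codes[i]]
        total += p
    return np.log(total)


def brute_force_posterior(codes, q, e_n, pi):
    """Exact per-site posteriors by path enumeration."""
    n = q.shape[0]
    L = len(codes)
    post = np.zeros((L, n))
    paths = np.indices((n,) * L).reshape(L, -1).T
    for path in paths:
        p = pi[path[0]] * e_n[path[0], codes[0]]
        for i in range(1, L):
            p *= q[path[i - 1], path[i]] * e_n[path[i], codes[i]]
        for i in range(L):
            post[i, path[i]] += p
    return post / post.sum(axis=1, keepdims=True)
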
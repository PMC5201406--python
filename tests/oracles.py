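"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the scaled dynamic-programming code paths in
``hmdm.hmm``: likelihoods and posteriors are computed by enumerating
all N**T hidden-state paths, and the spectral norm by power iteration.
They are only feasible at tiny sizes, which is the point.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def enumerate_path_probs(params, sequence):
    """(paths, probabilities) over all N**T hidden-state paths."""
    obs = np.asarray(sequence, dtype=int) - 1
    T, N = obs.size, params.n_states
    paths = np.array(list(product(range(N), repeat=T)), dtype=int)
    probs = params.pi[paths[:, 0]] * params.B[paths[:, 0], obs[0]]
    for t in range(1, T):
        probs = probs * params.A[paths[:, t - 1], paths[:, t]]
        probs = probs * params.B[paths[:, t], obs[t]]
    return paths, probs


def brute_force_log_likelihood(params, sequence) -> float:
    _, probs = enumerate_path_probs(params, sequence)
    total = probs.sum()
    return float(np.log(total)) if total > 0 else -np.inf


def brute_force_best_path(params, sequence, tie_rel=1e-9):
    """Max-probability path, its log probability, and a uniqueness flag.

    ``unique`` is False when the runner-up path is within relative
    ``tie_rel`` of the best: distinct paths can share the exact same
    product of factors, in which case any optimal path is acceptable.
    """
    paths, probs = enumerate_path_probs(params, sequence)
    order = np.argsort(probs)[::-1]
    best = order[0]
    logp = float(np.log(probs[best])) if probs[best] > 0 else -np.inf
    unique = len(order) < 2 or probs[order[1]] < probs[best] * (1 - tie_rel)
    return paths[best], logp, unique


def brute_force_posteriors(params, sequence):
    """gamma and xi by path enumeration."""
    obs = np.asarray(sequence, dtype=int) - 1
    T, N = obs.size, params.n_states
    paths, probs = enumerate_path_probs(params, sequence)
    total = probs.sum()
    gamma = np.zeros((T, N))
    xi = np.zeros((max(T - 1, 0), N, N))
    for path, p in zip(paths, probs):
        for t in range(T):
            gamma[t, path[t]] += p
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += p
    return gamma / total, xi / total


def naive_forward_alpha(params, sequence):
    """Unscaled forward trellis (only safe for short sequences)."""
    obs = np.asarray(sequence, dtype=int) - 1
    T, N = obs.size, params.n_states
    alpha = np.zeros((T, N))
    alpha[0] = params.pi * params.B[:, obs[0]]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ params.A) * params.B[:, obs[t]]
    return alpha


def naive_backward_beta(params, sequence):
    obs = np.asarray(sequence, dtype=int) - 1
    T, N = obs.size, params.n_states
    beta = np.zeros((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = params.A @ (params.B[:, obs[t + 1]] * beta[t + 1])
    return beta


def naive_baum_welch_update(params, sequence):
    """Single-sequence unscaled EM update (reference for one step)."""
    obs = np.asarray(sequence, dtype=int) - 1
    gamma, xi = brute_force_posteriors(params, obs + 1)
    N, M = params.n_states, params.n_symbols
    pi_new = gamma[0]
    A_new = xi.sum(axis=0) / gamma[:-1].sum(axis=0)[:, None]
    B_new = np.zeros((N, M))
    for k in range(M):
        mask = obs == k
        if mask.any():
            B_new[:, k] = gamma[mask].sum(axis=0)
    B_new /= gamma.sum(axis=0)[:, None]
    return pi_new, A_new, B_new


def power_iteration_2norm(mat, n_iter: int = 2000, seed: int = 0) -> float:
    """Largest singular value via power iteration on mat^T mat."""
    mat = np.asarray(mat, dtype=float)
    rng = np.random.default_rng(seed)
    v = rng.normal(size=mat.shape[1])
    v /= np.linalg.norm(v)
    gram = mat.T @ mat
    for _ in range(n_iter):
        w = gram @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v = w / norm
    return float(np.sqrt(v @ gram @ v))


def random_hmm(n_states, n_symbols, rng):
    """Random dense parameters (ties have probability zero)."""
    from hmdm.hmm import HmmParameters

    return HmmParameters(
        pi=rng.dirichlet(np.ones(n_states)),
        A=rng.dirichlet(np.ones(n_states), size=n_states),
        B=rng.dirichlet(np.ones(n_symbols), size=n_states),
    )
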
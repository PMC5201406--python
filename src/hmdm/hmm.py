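"""Discrete hidden Markov model machinery.

Forward/backward with per-step scaling, state posteriors,
multi-sequence Baum-Welch (EM) estimation, supervised
maximum-likelihood estimation from labeled sequences, and log-space
Viterbi decoding.  States are indexed 0..N-1 and observation symbols
1..M (the 1-based alphabet of the discretization stage).

Scaling convention: at every step t the unnormalized forward vector is
divided by its sum c_t, so sum_i alpha_hat_t(i) = 1 and
log P(O | lambda) = sum_t log c_t.  The backward pass reuses the same
c_t, which makes alpha_hat_t(i) * beta_hat_t(i) proportional to the
state posterior gamma_t(i).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    mat = np.atleast_2d(mat)
    if (mat < 0).any():
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(mat.sum(axis=-1), 1.0, atol=_ROW_SUM_TOL, rtol=0):
        raise ValueError(f"{name} rows must sum to 1 within {_ROW_SUM_TOL}")


@dataclass
class HmmParameters:
    """Model parameters lambda = (pi, A, B).

    ``pi`` is the initial state distribution (length N), ``A`` the N x N
    state transition matrix and ``B`` the N x M emission matrix over the
    1-based symbol alphabet (column k-1 holds the probabilities of
    symbol k).
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.pi.size
        if self.A.shape != (n, n):
            raise ValueError("A must be N x N with N = len(pi)")
        if self.B.shape[0] != n:
            raise ValueError("B must have one row per state")
        _check_stochastic(self.pi, "pi")
        _check_stochastic(self.A, "A")
        _check_stochastic(self.B, "B")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_symbols": self.n_symbols,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        return cls(pi=np.array(d["pi"]), A=np.array(d["A"]), B=np.array(d["B"]))

    @classmethod
    def from_json(cls, path) -> "HmmParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TrellisResult:
    """Scaled forward (and optionally backward) variables of one sequence."""

    alpha: np.ndarray  # (T, N), rows sum to 1
    scale: np.ndarray  # (T,), c_t
    log_likelihood: float
    beta: np.ndarray | None = None  # (T, N), scaled by the same c_t

    @property
    def T(self) -> int:
        return self.alpha.shape[0]


@dataclass
class Posteriors:
    gamma: np.ndarray  # (T, N)
    xi: np.ndarray  # (T-1, N, N)


@dataclass
class ViterbiResult:
    path: np.ndarray  # (T,) best state sequence
    delta: np.ndarray  # (T, N) log-space trellis
    backpointers: np.ndarray  # (T, N)
    log_probability: float


@dataclass
class CountMatrices:
    """Raw transition/emission/initial-state counts from labeled data."""

    A_counts: np.ndarray
    B_counts: np.ndarray
    initial_counts: np.ndarray


@dataclass(frozen=True)
class FitConfig:
    """Baum-Welch stopping, restart and smoothing policy."""

    max_iterations: int = 500
    tolerance: float = 1e-6
    n_restarts: int = 5
    smoothing_epsilon: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


def _symbols_to_cols(sequence: np.ndarray, n_symbols: int) -> np.ndarray:
    obs = np.asarray(sequence, dtype=np.int64)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if obs.min() < 1 or obs.max() > n_symbols:
        raise ValueError(
            f"symbols must lie in 1..{n_symbols}; got range "
            f"[{obs.min()}, {obs.max()}]"
        )
    return obs - 1


def forward(params: HmmParameters, sequence) -> TrellisResult:
    """Scaled forward pass; ``log_likelihood`` is log P(O | lambda).

    A symbol with zero emission probability in every state yields a
    reported log-likelihood of -inf rather than an exception.
    """
    obs = _symbols_to_cols(sequence, params.n_symbols)
    T, N = obs.size, params.n_states
    alpha = np.empty((T, N))
    scale = np.empty(T)
    a = params.pi * params.B[:, obs[0]]
    impossible = False
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ params.A) * params.B[:, obs[t]]
        c = a.sum()
        if c == 0.0:
            impossible = True
            alpha[t] = 1.0 / N  # keep the trellis usable downstream
            scale[t] = 0.0
        else:
            alpha[t] = a / c
            scale[t] = c
    if impossible:
        ll = -np.inf
    else:
        ll = float(np.log(scale).sum())
    return TrellisResult(alpha=alpha, scale=scale, log_likelihood=ll)


def backward(
    params: HmmParameters, sequence, scale: np.ndarray | None = None
) -> np.ndarray:
    """Scaled backward variables, using the forward pass's scale factors.

    Returns the (T, N) array beta_hat with beta_hat_T = 1.  For every t,
    sum_i alpha_hat_t(i) * beta_hat_t(i) * prod_{u<=t} c_u recovers
    P(O | lambda).
    """
    obs = _symbols_to_cols(sequence, params.n_symbols)
    T, N = obs.size, params.n_states
    if scale is None:
        scale = forward(params, sequence).scale
    beta = np.empty((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = params.A @ (params.B[:, obs[t + 1]] * beta[t + 1])
        c = scale[t + 1]
        beta[t] = b / c if c > 0 else 1.0 / N
    return beta


def posteriors(params: HmmParameters, sequence) -> Posteriors:
    """State posteriors gamma_t(i) and pair posteriors xi_t(i, j)."""
    obs = _symbols_to_cols(sequence, params.n_symbols)
    trellis = forward(params, sequence)
    beta = backward(params, sequence, trellis.scale)
    T, N = trellis.T, params.n_states

    gamma = trellis.alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.empty((max(T - 1, 0), N, N))
    for t in range(T - 1):
        m = (
            trellis.alpha[t][:, None]
            * params.A
            * (params.B[:, obs[t + 1]] * beta[t + 1])[None, :]
        )
        xi[t] = m / m.sum()
    return Posteriors(gamma=gamma, xi=xi)


# ---------------------------------------------------------------------------
# Baum-Welch


def _accumulate(params: HmmParameters, sequence):
    """Per-sequence EM sufficient statistics (and the sequence loglik)."""
    obs = _symbols_to_cols(sequence, params.n_symbols)
    post = posteriors(params, sequence)
    ll = forward(params, sequence).log_likelihood
    N, M = params.n_states, params.n_symbols
    B_num = np.zeros((N, M))
    np.add.at(B_num.T, obs, post.gamma)
    return (
        post.gamma[0],
        post.xi.sum(axis=0),
        post.gamma[:-1].sum(axis=0),
        B_num,
        post.gamma.sum(axis=0),
        ll,
    )


def _accumulate_batch(params: HmmParameters, obs_matrix: np.ndarray):
    """Vectorized sufficient statistics for S equal-length sequences.

    ``obs_matrix`` is an (S, T) array of 0-based symbol columns.  The
    forward/backward recursions run across all S sequences at once, one
    (S, N) matrix per time step, which keeps the per-iteration cost of
    multi-sequence training dominated by small dense matmuls.
    """
    S, T = obs_matrix.shape
    N, M = params.n_states, params.n_symbols
    A, B, pi = params.A, params.B, params.pi

    alpha = np.empty((T, S, N))
    scale = np.empty((T, S))
    a = pi[None, :] * B[:, obs_matrix[:, 0]].T
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ A) * B[:, obs_matrix[:, t]].T
        c = a.sum(axis=1)
        bad = c == 0.0
        c_safe = np.where(bad, 1.0, c)
        alpha[t] = a / c_safe[:, None]
        alpha[t][bad] = 1.0 / N
        scale[t] = c
    with np.errstate(divide="ignore"):
        ll_per_seq = np.where(
            (scale == 0).any(axis=0), -np.inf, np.log(np.where(scale > 0, scale, 1)).sum(axis=0)
        )

    beta = np.empty((T, S, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        emit = B[:, obs_matrix[:, t + 1]].T * beta[t + 1]
        b = emit @ A.T
        c = scale[t + 1]
        c_safe = np.where(c > 0, c, 1.0)
        beta[t] = b / c_safe[:, None]

    gamma = alpha * beta  # (T, S, N)
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi_sum = np.zeros((N, N))
    for t in range(T - 1):
        emit = B[:, obs_matrix[:, t + 1]].T * beta[t + 1]  # (S, N)
        m = np.einsum("si,ij,sj->ij", alpha[t], A, emit)
        # normalize per sequence: each sequence's xi_t sums to 1
        denom = np.einsum("si,ij,sj->s", alpha[t], A, emit)
        m_per = np.einsum("si,sj->sij", alpha[t], emit) * A[None, :, :]
        xi_sum += (m_per / denom[:, None, None]).sum(axis=0)

    B_num = np.zeros((N, M))
    for t in range(T):
        np.add.at(B_num.T, obs_matrix[:, t], gamma[t])

    return (
        gamma[0].sum(axis=0),  # initial-state posterior mass
        xi_sum,
        gamma[:-1].sum(axis=(0, 1)),
        B_num,
        gamma.sum(axis=(0, 1)),
        float(ll_per_seq.sum()),
        S,
    )


def _group_by_length(sequences) -> dict[int, np.ndarray]:
    groups: dict[int, list] = {}
    for seq in sequences:
        arr = np.asarray(seq, dtype=np.int64)
        groups.setdefault(arr.size, []).append(arr)
    return {T: np.vstack(seqs) for T, seqs in groups.items()}


def baum_welch_step(
    params: HmmParameters,
    sequences,
    smoothing_epsilon: float = 1e-10,
) -> tuple[HmmParameters, float]:
    """One pooled EM update over multiple sequences.

    Numerators and denominators of the transition/emission updates are
    summed over all sequences before dividing; the initial distribution
    is the mean first-step posterior.  Rows are smoothed by an additive
    epsilon and renormalized; a state never visited gets a uniform row
    (logged).  Returns the updated parameters and the total
    log-likelihood of the data under the *input* parameters.
    """
    seq_list = [np.asarray(s, dtype=np.int64) for s in sequences]
    if not seq_list:
        raise ValueError("need at least one sequence")
    for s in seq_list:
        if s.size < 2:
            raise ValueError("Baum-Welch requires sequences of length >= 2")
        _symbols_to_cols(s, params.n_symbols)

    N, M = params.n_states, params.n_symbols
    pi_num = np.zeros(N)
    A_num = np.zeros((N, N))
    A_den = np.zeros(N)
    B_num = np.zeros((N, M))
    B_den = np.zeros(N)
    total_ll = 0.0
    n_seq = 0
    for T, obs_matrix in _group_by_length([s - 1 for s in seq_list]).items():
        g1, xi, gden, bnum, bden, ll, S = _accumulate_batch(
            params, obs_matrix
        )
        pi_num += g1
        A_num += xi
        A_den += gden
        B_num += bnum
        B_den += bden
        total_ll += ll
        n_seq += S

    pi_new = pi_num / n_seq
    A_new = np.empty((N, N))
    B_new = np.empty((N, M))
    for i in range(N):
        if A_den[i] > 0:
            A_new[i] = A_num[i] / A_den[i]
        else:
            logger.warning("state %d never visited; transition row reset to uniform", i)
            A_new[i] = 1.0 / N
        if B_den[i] > 0:
            B_new[i] = B_num[i] / B_den[i]
        else:
            B_new[i] = 1.0 / M

    eps = smoothing_epsilon
    A_new = (A_new + eps) / (A_new + eps).sum(axis=1, keepdims=True)
    B_new = (B_new + eps) / (B_new + eps).sum(axis=1, keepdims=True)
    pi_new = (pi_new + eps) / (pi_new + eps).sum()
    return HmmParameters(pi=pi_new, A=A_new, B=B_new), total_ll


def total_log_likelihood(params: HmmParameters, sequences) -> float:
    groups = _group_by_length(
        [_symbols_to_cols(s, params.n_symbols) for s in sequences]
    )
    total = 0.0
    for obs_matrix in groups.values():
        total += _accumulate_batch(params, obs_matrix)[5]
    return total


def random_parameters(
    n_states: int, n_symbols: int, rng: np.random.Generator
) -> HmmParameters:
    """Dirichlet-uniform random row-stochastic initialization."""
    return HmmParameters(
        pi=rng.dirichlet(np.ones(n_states)),
        A=rng.dirichlet(np.ones(n_states), size=n_states),
        B=rng.dirichlet(np.ones(n_symbols), size=n_states),
    )


def baum_welch_fit(
    sequences,
    n_states: int,
    n_symbols: int,
    config: FitConfig | None = None,
    init: HmmParameters | None = None,
) -> tuple[HmmParameters, list[float]]:
    """Fit an HMM by Baum-Welch with random restarts.

    Each restart starts from a seeded Dirichlet-uniform random
    initialization (or from ``init``, if given, in which case a single
    run is performed), iterates pooled EM updates until the relative
    log-likelihood improvement drops below ``config.tolerance`` or
    ``config.max_iterations`` is reached, and the restart with the
    highest final log-likelihood wins.  Returns the winning parameters
    and their per-iteration log-likelihood trace (non-decreasing up to
    numerical tolerance, by the EM ascent property).
    """
    config = config or FitConfig()
    seq_list = [np.asarray(s, dtype=np.int64) for s in sequences]
    if not seq_list:
        raise ValueError("no sequences to fit")
    max_symbol = max(int(s.max()) for s in seq_list)
    if max_symbol > n_symbols:
        raise ValueError(
            f"n_symbols={n_symbols} smaller than max observed symbol {max_symbol}"
        )

    rng = np.random.default_rng(config.seed)
    starts = (
        [init]
        if init is not None
        else [random_parameters(n_states, n_symbols, rng) for _ in range(config.n_restarts)]
    )

    best: tuple[float, HmmParameters, list[float]] | None = None
    for params in starts:
        trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(config.max_iterations):
            params_new, ll = baum_welch_step(
                params, seq_list, config.smoothing_epsilon
            )
            trace.append(ll)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= config.tolerance * abs(prev_ll):
                params = params_new
                break
            params = params_new
            prev_ll = ll
        final_ll = total_log_likelihood(params, seq_list)
        trace.append(final_ll)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, trace)
    assert best is not None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Supervised MLE


def count_matrices(labeled_sequences, n_states: int, n_symbols: int) -> CountMatrices:
    A_counts = np.zeros((n_states, n_states), dtype=np.int64)
    B_counts = np.zeros((n_states, n_symbols), dtype=np.int64)
    initial = np.zeros(n_states, dtype=np.int64)
    for seq in labeled_sequences:
        states = np.asarray(seq.states, dtype=np.int64)
        obs = _symbols_to_cols(seq.symbols, n_symbols)
        if states.min() < 0 or states.max() >= n_states:
            raise ValueError("state labels out of range")
        initial[states[0]] += 1
        np.add.at(A_counts, (states[:-1], states[1:]), 1)
        np.add.at(B_counts, (states, obs), 1)
    return CountMatrices(A_counts=A_counts, B_counts=B_counts, initial_counts=initial)


def supervised_mle(
    labeled_sequences, n_states: int = 4, n_symbols: int = 81
) -> HmmParameters:
    """Closed-form MLE from labeled sequences: row-normalized counts.

    States never visited get uniform rows with a logged warning, so the
    result is always a valid parameter set.
    """
    seqs = list(labeled_sequences)
    if not seqs:
        raise ValueError("no labeled sequences")
    counts = count_matrices(seqs, n_states, n_symbols)

    A = np.empty((n_states, n_states))
    B = np.empty((n_states, n_symbols))
    for i in range(n_states):
        arow = counts.A_counts[i].sum()
        brow = counts.B_counts[i].sum()
        if arow == 0:
            logger.warning("state %d has no outgoing transitions; uniform row", i)
            A[i] = 1.0 / n_states
        else:
            A[i] = counts.A_counts[i] / arow
        if brow == 0:
            logger.warning("state %d never emits; uniform emission row", i)
            B[i] = 1.0 / n_symbols
        else:
            B[i] = counts.B_counts[i] / brow
    pi = counts.initial_counts / counts.initial_counts.sum()
    return HmmParameters(pi=pi, A=A, B=B)


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(params: HmmParameters, sequence) -> ViterbiResult:
    """Most probable state path, computed in log space.

    Ties are broken toward the lowest state index.  Replaying the path
    through (pi, A, B) reproduces ``log_probability`` exactly.
    """
    obs = _symbols_to_cols(sequence, params.n_symbols)
    T, N = obs.size, params.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
        log_B = np.log(params.B)

    delta = np.empty((T, N))
    psi = np.zeros((T, N), dtype=np.int64)
    delta[0] = log_pi + log_B[:, obs[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_A  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta[t] = cand[psi[t], np.arange(N)] + log_B[:, obs[t]]

    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return ViterbiResult(
        path=path,
        delta=delta,
        backpointers=psi,
        log_probability=float(delta[T - 1].max()),
    )
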
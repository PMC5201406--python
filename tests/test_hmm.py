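import numpy as np
import pytest

from hmdm.hmm import (
    FitConfig,
    HmmParameters,
    backward,
    baum_welch_fit,
    baum_welch_step,
    forward,
    posteriors,
    supervised_mle,
    total_log_likelihood,
    viterbi,
)
from hmdm.sequences import ObservationSequence

from oracles import (
    brute_force_best_path,
    brute_force_log_likelihood,
    brute_force_posteriors,
    naive_backward_beta,
    naive_baum_welch_update,
    naive_forward_alpha,
    random_hmm,
)


# ---------------------------------------------------------------------------
# parameter container


def test_parameters_validated():
    with pytest.raises(ValueError):
        HmmParameters(pi=[0.5, 0.6], A=np.eye(2), B=np.eye(2))
    with pytest.raises(ValueError):
        HmmParameters(pi=[0.5, 0.5], A=[[1.2, -0.2], [0.5, 0.5]], B=np.eye(2))


def test_parameters_json_roundtrip(tmp_path, rng):
    params = random_hmm(4, 81, rng)
    path = tmp_path / "params.json"
    params.to_json(path)
    loaded = HmmParameters.from_json(path)
    np.testing.assert_array_equal(params.pi, loaded.pi)
    np.testing.assert_array_equal(params.A, loaded.A)
    np.testing.assert_array_equal(params.B, loaded.B)


# ---------------------------------------------------------------------------
# forward / backward / posteriors


def test_forward_matches_enumeration_on_random_models(rng):
    for _ in range(50):
        n = int(rng.integers(2, 5))
        m = int(rng.integers(2, 6))
        T = int(rng.integers(1, 7))
        params = random_hmm(n, m, rng)
        seq = rng.integers(1, m + 1, size=T)
        expected = brute_force_log_likelihood(params, seq)
        got = forward(params, seq).log_likelihood
        assert got == pytest.approx(expected, rel=1e-10)


def test_single_state_model_collapses_to_emission_product():
    params = HmmParameters(pi=[1.0], A=[[1.0]], B=[[0.2, 0.3, 0.5]])
    seq = [1, 3, 2, 3]
    expected = np.log([0.2, 0.5, 0.3, 0.5]).sum()
    assert forward(params, seq).log_likelihood == pytest.approx(expected, rel=1e-12)


def test_deterministic_emissions_closed_form():
    # uniform pi and A, one-hot emissions: only one path survives,
    # P(O) = (1/N)^T
    n = 3
    params = HmmParameters(
        pi=np.full(n, 1 / n), A=np.full((n, n), 1 / n), B=np.eye(n)
    )
    seq = [1, 3, 2, 2, 1]
    assert forward(params, seq).log_likelihood == pytest.approx(
        len(seq) * np.log(1 / n), rel=1e-12
    )


def test_impossible_symbol_reports_minus_inf():
    params = HmmParameters(
        pi=[0.5, 0.5],
        A=[[0.5, 0.5], [0.5, 0.5]],
        B=[[1.0, 0.0], [1.0, 0.0]],
    )
    result = forward(params, [1, 2, 1])
    assert result.log_likelihood == -np.inf


def test_empty_sequence_rejected(toy_params):
    with pytest.raises(ValueError):
        forward(toy_params, [])
    with pytest.raises(ValueError):
        forward(toy_params, [0, 1])  # symbols are 1-based


def test_forward_scaled_rows_normalized(toy_params, rng):
    seq = rng.integers(1, 4, size=15)
    trellis = forward(toy_params, seq)
    np.testing.assert_allclose(trellis.alpha.sum(axis=1), 1.0, atol=1e-12)


def test_backward_terminal_is_one(toy_params):
    beta = backward(toy_params, [2])
    np.testing.assert_array_equal(beta, [[1.0, 1.0]])


def test_scaled_forward_backward_agree_with_naive(toy_params, rng):
    # scaled and unscaled implementations agree on short sequences
    seq = rng.integers(1, 4, size=12)
    trellis = forward(toy_params, seq)
    alpha_naive = naive_forward_alpha(toy_params, seq)
    beta_naive = naive_backward_beta(toy_params, seq)
    p_naive = alpha_naive[-1].sum()
    assert trellis.log_likelihood == pytest.approx(np.log(p_naive), rel=1e-12)
    np.testing.assert_allclose(
        trellis.alpha,
        alpha_naive / alpha_naive.sum(axis=1, keepdims=True),
        rtol=1e-10,
    )
    # alpha_t . beta_t is constant (= P(O)) in the unscaled convention
    products = (alpha_naive * beta_naive).sum(axis=1)
    np.testing.assert_allclose(products, p_naive, rtol=1e-10)


def test_single_state_posterior_is_one():
    params = HmmParameters(pi=[1.0], A=[[1.0]], B=[[0.4, 0.6]])
    post = posteriors(params, [1, 2, 2])
    np.testing.assert_allclose(post.gamma, 1.0)


def test_posterior_identities_and_enumeration(toy_params, rng):
    seq = rng.integers(1, 4, size=6)
    post = posteriors(toy_params, seq)
    np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-12)
    # gamma_t(i) = sum_j xi_t(i, j) for t < T
    np.testing.assert_allclose(post.gamma[:-1], post.xi.sum(axis=2), rtol=1e-10)
    gamma_ref, xi_ref = brute_force_posteriors(toy_params, seq)
    np.testing.assert_allclose(post.gamma, gamma_ref, rtol=1e-9)
    np.testing.assert_allclose(post.xi, xi_ref, rtol=1e-9)


def test_pair_posterior_frozen_hand_case(toy_params):
    # sequence (v1, v3): total path probability 0.091, e.g.
    # xi_1(0,1) = 0.6*0.5 * 0.3 * 0.6 / 0.091 = 0.59340659...
    post = posteriors(toy_params, [1, 3])
    np.testing.assert_allclose(
        post.xi[0],
        [[0.23076923, 0.59340659], [0.01758242, 0.15824176]],
        atol=1e-8,
    )
    assert forward(toy_params, [1, 3]).log_likelihood == pytest.approx(
        -2.396895772465287, rel=1e-12
    )


# ---------------------------------------------------------------------------
# Baum-Welch


def test_baum_welch_step_matches_naive_single_sequence(toy_params):
    seq = [1, 3, 2, 1]
    updated, _ll = baum_welch_step(toy_params, [seq], smoothing_epsilon=0.0)
    pi_ref, A_ref, B_ref = naive_baum_welch_update(toy_params, seq)
    np.testing.assert_allclose(updated.pi, pi_ref, rtol=1e-9)
    np.testing.assert_allclose(updated.A, A_ref, rtol=1e-9)
    np.testing.assert_allclose(updated.B, B_ref, rtol=1e-9)


def test_baum_welch_step_frozen_values(toy_params):
    # naive-EM reference values for the sequence (v1, v3, v2, v1)
    updated, _ = baum_welch_step(toy_params, [[1, 3, 2, 1]], smoothing_epsilon=0.0)
    np.testing.assert_allclose(updated.pi, [0.82929512, 0.17070488], atol=1e-8)
    np.testing.assert_allclose(
        updated.A,
        [[0.61973134, 0.38026866], [0.56321671, 0.43678329]],
        atol=1e-8,
    )
    np.testing.assert_allclose(
        updated.B,
        [[0.64757914, 0.24356154, 0.10885932],
         [0.22044674, 0.26219612, 0.51735715]],
        atol=1e-8,
    )


def test_fixed_point_unchanged():
    # a degenerate model that already maximizes the likelihood of its data
    params = HmmParameters(
        pi=[1.0, 0.0], A=[[1.0, 0.0], [0.0, 1.0]], B=[[1.0, 0.0], [0.0, 1.0]]
    )
    updated, _ = baum_welch_step(params, [[1, 1, 1, 1]], smoothing_epsilon=0.0)
    np.testing.assert_allclose(updated.pi, params.pi, atol=1e-12)
    np.testing.assert_allclose(updated.A[0], params.A[0], atol=1e-12)
    np.testing.assert_allclose(updated.B[0], params.B[0], atol=1e-12)


def test_em_updates_never_decrease_likelihood(rng):
    params = random_hmm(3, 5, rng)
    seqs = [rng.integers(1, 6, size=20) for _ in range(8)]
    prev = total_log_likelihood(params, seqs)
    for _ in range(15):
        params, _ = baum_welch_step(params, seqs)
        cur = total_log_likelihood(params, seqs)
        assert cur >= prev - 1e-9 * abs(prev)
        prev = cur


def test_step_preserves_row_stochasticity(rng):
    params = random_hmm(4, 7, rng)
    seqs = [rng.integers(1, 8, size=12) for _ in range(5)]
    updated, _ = baum_welch_step(params, seqs)
    np.testing.assert_allclose(updated.A.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(updated.B.sum(axis=1), 1.0, atol=1e-12)
    assert updated.pi.sum() == pytest.approx(1.0, abs=1e-12)


def test_multi_sequence_pooling_differs_from_averaging(rng):
    # pooled update must weight sequences by their posterior mass, which
    # an average of per-sequence updates would not
    params = random_hmm(2, 3, rng)
    seqs = [[1, 2, 3, 1, 2], [3, 3]]
    pooled, _ = baum_welch_step(params, seqs, smoothing_epsilon=0.0)
    upd_a, _ = baum_welch_step(params, [seqs[0]], smoothing_epsilon=0.0)
    upd_b, _ = baum_welch_step(params, [seqs[1]], smoothing_epsilon=0.0)
    averaged = (upd_a.A + upd_b.A) / 2
    assert not np.allclose(pooled.A, averaged)


def test_fit_trace_non_decreasing(rng):
    seqs = [rng.integers(1, 6, size=25) for _ in range(10)]
    _, trace = baum_welch_fit(seqs, 3, 5, FitConfig(n_restarts=2, max_iterations=60, seed=3))
    diffs = np.diff(trace)
    assert (diffs >= -1e-9 * np.abs(np.array(trace[:-1]))).all()


def test_fit_degenerate_constant_symbol():
    seqs = [[4, 4, 4, 4, 4]] * 6
    params, _ = baum_welch_fit(seqs, 2, 5, FitConfig(n_restarts=1, max_iterations=30, seed=0))
    assert (params.B[:, 3] >= 1 - 1e-8).all()


def test_fit_rejects_too_small_alphabet():
    with pytest.raises(ValueError):
        baum_welch_fit([[1, 9]], 2, 5, FitConfig())


def test_fit_recovers_from_near_truth_init(rng):
    # moderate-size identifiability check; the full-scale recovery
    # experiment lives in the acceptance suite
    truth = random_hmm(2, 4, rng)
    from hmdm.synthetic import GroundTruth, sample_hmm_sequences

    gt = GroundTruth(
        pi=truth.pi, A_by_zone={1: truth.A}, B_by_zone={1: truth.B}
    )
    seqs = [s.symbols for s in sample_hmm_sequences(gt, 1, 150, 40, seed=9)]
    init = HmmParameters(
        pi=truth.pi,
        A=(truth.A + 0.03) / (truth.A + 0.03).sum(axis=1, keepdims=True),
        B=(truth.B + 0.03) / (truth.B + 0.03).sum(axis=1, keepdims=True),
    )
    fitted, _ = baum_welch_fit(seqs, 2, 4, FitConfig(seed=1), init=init)
    assert np.abs(fitted.A - truth.A).mean() < 0.05


# ---------------------------------------------------------------------------
# supervised MLE


def _labeled(symbols, states, vid=0):
    return ObservationSequence(
        vehicle_id=vid,
        symbols=np.array(symbols),
        zones=np.zeros(len(symbols), dtype=int),
        states=np.array(states),
    )


def test_supervised_mle_hand_counts():
    seq = _labeled([5, 5, 7], [0, 0, 1])
    params = supervised_mle([seq], n_states=2, n_symbols=8)
    assert params.A[0, 0] == pytest.approx(0.5)
    assert params.A[0, 1] == pytest.approx(0.5)
    assert params.B[0, 4] == pytest.approx(1.0)
    assert params.B[1, 6] == pytest.approx(1.0)
    np.testing.assert_allclose(params.pi, [1.0, 0.0])


def test_supervised_mle_absorbing_labels():
    seq = _labeled([1, 2, 1], [0, 0, 0])
    params = supervised_mle([seq], n_states=2, n_symbols=3)
    np.testing.assert_allclose(params.A[0], [1.0, 0.0])
    # state 1 never seen: uniform fallback rows
    np.testing.assert_allclose(params.A[1], [0.5, 0.5])


def test_supervised_mle_order_invariant(rng):
    seqs = [
        _labeled(rng.integers(1, 6, size=10), rng.integers(0, 3, size=10), vid=i)
        for i in range(6)
    ]
    a = supervised_mle(seqs, 3, 5)
    b = supervised_mle(list(reversed(seqs)), 3, 5)
    np.testing.assert_array_equal(a.A, b.A)
    np.testing.assert_array_equal(a.B, b.B)
    np.testing.assert_array_equal(a.pi, b.pi)


def test_supervised_mle_empty_rejected():
    with pytest.raises(ValueError):
        supervised_mle([], 2, 3)


# ---------------------------------------------------------------------------
# Viterbi


def test_viterbi_single_observation(toy_params):
    result = viterbi(toy_params, [1])
    expected = int(np.argmax(toy_params.pi * toy_params.B[:, 0]))
    assert result.path.tolist() == [expected]


def test_viterbi_matches_enumeration_on_random_models(rng):
    for _ in range(50):
        n = int(rng.integers(2, 5))
        m = int(rng.integers(2, 6))
        T = int(rng.integers(1, 7))
        params = random_hmm(n, m, rng)
        seq = rng.integers(1, m + 1, size=T)
        path_ref, logp_ref, unique = brute_force_best_path(params, seq)
        result = viterbi(params, seq)
        assert result.log_probability == pytest.approx(logp_ref, rel=1e-10)
        if unique:
            np.testing.assert_array_equal(result.path, path_ref)


def test_viterbi_replay_reproduces_log_probability(toy_params, rng):
    seq = rng.integers(1, 4, size=10)
    result = viterbi(toy_params, seq)
    logp = np.log(toy_params.pi[result.path[0]]) + np.log(
        toy_params.B[result.path[0], seq[0] - 1]
    )
    for t in range(1, len(seq)):
        logp += np.log(toy_params.A[result.path[t - 1], result.path[t]])
        logp += np.log(toy_params.B[result.path[t], seq[t] - 1])
    assert result.log_probability == pytest.approx(logp, abs=1e-10)


def test_viterbi_deterministic_chain():
    params = HmmParameters(
        pi=[0.0, 0.0, 1.0],
        A=np.eye(3),
        B=np.full((3, 2), 0.5),
    )
    result = viterbi(params, [1, 2, 1, 1])
    assert result.path.tolist() == [2, 2, 2, 2]


def test_viterbi_tie_breaks_to_lowest_state():
    params = HmmParameters(
        pi=[0.5, 0.5], A=np.full((2, 2), 0.5), B=np.full((2, 3), 1 / 3)
    )
    assert viterbi(params, [1, 2, 3]).path.tolist() == [0, 0, 0]


def test_viterbi_bounded_by_forward(rng):
    for _ in range(20):
        params = random_hmm(3, 4, rng)
        seq = rng.integers(1, 5, size=8)
        assert (
            viterbi(params, seq).log_probability
            <= forward(params, seq).log_likelihood + 1e-12
        )


# ---------------------------------------------------------------------------
# independent library cross-check


def test_against_reference_library(rng):
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    params = random_hmm(4, 81, rng)
    seq = rng.integers(1, 82, size=60)

    model = hmmlearn.CategoricalHMM(n_components=4)
    model.startprob_ = params.pi
    model.transmat_ = params.A
    model.emissionprob_ = params.B
    obs = (seq - 1).reshape(-1, 1)
    assert forward(params, seq).log_likelihood == pytest.approx(
        model.score(obs), rel=1e-10
    )
    logp, path = model.decode(obs, algorithm="viterbi")
    result = viterbi(params, seq)
    assert result.log_probability == pytest.approx(logp, rel=1e-10)
    np.testing.assert_array_equal(result.path, path)
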
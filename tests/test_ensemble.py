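"""Tests of the multinomial mixture-of-partitions ensemble."""

import math

import numpy as np
import pytest

from cedr import (
    BaseClustering,
    LabelMatrix,
    bic,
    build_label_matrix,
    em_fit,
    fit_consensus,
    log_likelihood,
    nmi,
)
from cedr.exceptions import ValidationError


def _clustering(labels, G):
    labels = np.asarray(labels)
    tau = np.zeros((len(labels), G + 1))
    tau[np.arange(len(labels)), labels] = 1.0
    return BaseClustering(labels=labels, tau=tau, G=G)


def _sample_mixture(rng, n, Q, S, crisp=0.9, C=4):
    """Draw a label matrix from a known mixture with crisp nu tables."""
    alpha = np.full(Q, 1.0 / Q)
    z = rng.choice(Q, size=n, p=alpha)
    nu = np.full((S, Q, C), (1.0 - crisp) / (C - 1))
    for l in range(S):
        for q in range(Q):
            nu[l, q, q % C] = crisp
    Y = np.empty((n, S), dtype=int)
    for l in range(S):
        for i in range(n):
            Y[i, l] = rng.choice(C, p=nu[l, z[i]])
    return Y + 1, z, nu  # labels 1..C (no noise level)


# ---------------------------------------------------------------------------
# build_label_matrix

def test_clean_ensemble_has_no_trimming():
    parts = [_clustering([1, 1, 2, 2], 2) for _ in range(4)]
    Y = build_label_matrix(parts)
    assert Y.Y.shape == (4, 4)
    assert Y.trimmed_ids == []
    assert all(0 not in levels for levels in Y.column_levels)


def test_all_noise_sample_is_trimmed():
    parts = [_clustering([0, 1, 2, 2], 2) for _ in range(4)]
    Y = build_label_matrix(parts, sample_ids=["a", "b", "c", "d"])
    assert Y.n == 3
    assert Y.trimmed_ids == ["a"]


def test_partially_noisy_sample_is_retained():
    parts = [_clustering([0, 1, 2, 2], 2)] + \
            [_clustering([1, 1, 2, 2], 2) for _ in range(3)]
    Y = build_label_matrix(parts)
    assert Y.n == 4
    assert 0 in Y.column_levels[0]  # noise kept as its own level
    assert Y.trimmed_ids == []


def test_inconsistent_sample_sets_rejected():
    with pytest.raises(ValidationError):
        build_label_matrix([_clustering([1, 2], 2),
                            _clustering([1, 2, 1], 2)])


# ---------------------------------------------------------------------------
# em_fit

def test_identical_partitions_reproduce_common_partition():
    labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
    Y = build_label_matrix([_clustering(labels, 3) for _ in range(4)])
    model = em_fit(Y, Q=3, seed=0)
    from cedr.ensemble import _log_prob_matrix
    consensus = _log_prob_matrix(model, Y).argmax(axis=1)
    assert nmi(labels, consensus) == pytest.approx(1.0)


def test_single_component_fit_matches_closed_form():
    """Q=1: alpha=(1), nu = empirical frequencies, loglik by counting."""
    Y = LabelMatrix(Y=np.array([[1, 1], [1, 2], [2, 2], [2, 2], [1, 1]]),
                    sample_ids=list("abcde"))
    model = em_fit(Y, Q=1, seed=0, n_restarts=2)
    np.testing.assert_allclose(model.alpha, [1.0])
    np.testing.assert_allclose(model.nu[0][0], [3 / 5, 2 / 5], atol=1e-6)
    np.testing.assert_allclose(model.nu[1][0], [2 / 5, 3 / 5], atol=1e-6)
    expected = (3 * math.log(3 / 5) + 2 * math.log(2 / 5)
                + 2 * math.log(2 / 5) + 3 * math.log(3 / 5))
    assert model.loglik == pytest.approx(expected, abs=1e-6)


def test_parameter_recovery_on_simulated_ensemble(rng):
    Ylab, z, nu_true = _sample_mixture(rng, n=1000, Q=4, S=4)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(1000)])
    model = em_fit(Y, Q=4, seed=0)
    # match consensus components to the generating ones via argmax agreement
    from cedr.ensemble import _log_prob_matrix
    assign = _log_prob_matrix(model, Y).argmax(axis=1)
    # build the mapping q_est -> q_true by majority vote
    mapping = {}
    for q in range(4):
        members = z[assign == q]
        assert members.size > 0
        mapping[q] = np.bincount(members, minlength=4).argmax()
    assert len(set(mapping.values())) == 4  # one-to-one
    for l in range(4):
        for q_est, q_true in mapping.items():
            # the finite-sample target is the empirical conditional table
            members = Y.Y[z == q_true, l] - 1
            empirical = np.bincount(members, minlength=4) / members.size
            np.testing.assert_allclose(model.nu[l][q_est], empirical,
                                       atol=0.05)
            # and the generating table is recovered to sampling precision
            np.testing.assert_allclose(model.nu[l][q_est], nu_true[l, q_true],
                                       atol=0.07)


def test_em_loglik_monotone(rng):
    Ylab, _, _ = _sample_mixture(rng, n=200, Q=3, S=4, crisp=0.7)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(200)])
    from cedr.ensemble import _em_single, _one_hot
    X = _one_hot(Y.encoded(), Y.category_counts)
    _, _, trace, _, _ = _em_single(X, Y.category_counts, 3,
                                   np.random.default_rng(0), 1e-4, 500)
    assert np.all(np.diff(trace) >= -1e-9)


def test_q_larger_than_n_rejected():
    Y = LabelMatrix(Y=np.array([[1, 2], [2, 1]]), sample_ids=["a", "b"])
    with pytest.raises(ValidationError):
        em_fit(Y, Q=3)


# ---------------------------------------------------------------------------
# log_likelihood / bic

def test_loglik_oracle_agreement(rng):
    Ylab, _, _ = _sample_mixture(rng, n=150, Q=3, S=4)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(150)])
    model = em_fit(Y, Q=3, seed=1)
    # brute-force evaluation of sum_i log sum_q alpha_q prod_l nu
    enc = Y.encoded()
    direct = 0.0
    for i in range(Y.n):
        total = 0.0
        for q in range(3):
            term = model.alpha[q]
            for l in range(Y.S):
                term *= model.nu[l][q, enc[i, l]]
            total += term
        direct += math.log(total)
    assert log_likelihood(model, Y) == pytest.approx(direct, abs=1e-8)
    assert model.loglik == pytest.approx(direct, abs=1e-8)


def test_duplicated_sample_doubles_its_contribution():
    Y1 = LabelMatrix(Y=np.array([[1, 1], [2, 2], [1, 2]]),
                     sample_ids=["a", "b", "c"])
    model = em_fit(Y1, Q=2, seed=0)
    base = log_likelihood(model, Y1)
    Y2 = LabelMatrix(Y=np.array([[1, 1], [2, 2], [1, 2], [1, 2]]),
                     sample_ids=["a", "b", "c", "c2"])
    # hand-computed contribution of row (1, 2): levels encode to index (0, 1)
    row_prob = sum(model.alpha[q] * model.nu[0][q, 0] * model.nu[1][q, 1]
                   for q in range(2))
    assert log_likelihood(model, Y2) == pytest.approx(
        base + math.log(row_prob), abs=1e-10)


def test_bic_penalty_arithmetic():
    """Q=1, S=1, C=2, n=10: p=1, BIC = -2 loglik + log 10."""
    Y = LabelMatrix(Y=np.array([[1]] * 6 + [[2]] * 4), sample_ids=[str(i) for i in range(10)])
    model = em_fit(Y, Q=1, seed=0, n_restarts=2)
    expected_loglik = 6 * math.log(0.6) + 4 * math.log(0.4)
    assert model.loglik == pytest.approx(expected_loglik, abs=1e-6)
    assert bic(model, Y) == pytest.approx(-2 * expected_loglik + math.log(10),
                                          abs=1e-5)


def test_bic_penalty_monotone_in_Q(rng):
    Ylab, _, _ = _sample_mixture(rng, n=100, Q=2, S=3)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(100)])
    m2 = em_fit(Y, Q=2, seed=0)
    m4 = em_fit(Y, Q=4, seed=0)
    p2 = (2 - 1) + 2 * sum(C - 1 for C in Y.category_counts)
    p4 = (4 - 1) + 4 * sum(C - 1 for C in Y.category_counts)
    assert p4 > p2
    # identical loglik would imply strictly larger BIC for Q=4
    assert (bic(m4, Y) - (-2 * m4.loglik)) > (bic(m2, Y) - (-2 * m2.loglik))


# ---------------------------------------------------------------------------
# fit_consensus

def test_bic_recovers_true_Q_on_crisp_ensembles(rng):
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        Ylab, _, _ = _sample_mixture(r, n=400, Q=4, S=4, crisp=0.9)
        Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(400)])
        res = fit_consensus(Y, Q_range=range(2, 7), seed=seed, n_restarts=10)
        hits += res.model.Q == 4
    assert hits >= 18  # >= 90% of 20 seeds


def test_singleton_Q_range(rng):
    Ylab, _, _ = _sample_mixture(rng, n=60, Q=2, S=3)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(60)])
    res = fit_consensus(Y, Q_range=[2], seed=0, n_restarts=5)
    assert res.model.Q == 2
    np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(res.labels, res.posteriors.argmax(axis=1) + 1)


def test_label_permutation_invariance_of_best_loglik(rng):
    Ylab, _, _ = _sample_mixture(rng, n=200, Q=3, S=4)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(200)])
    res_a = fit_consensus(Y, Q_range=range(2, 5), seed=3, n_restarts=10,
                          tol=1e-9)
    # consistently permute the category names of column 0
    perm = {1: 4, 2: 3, 3: 2, 4: 1}
    Yp_lab = Ylab.copy()
    Yp_lab[:, 0] = [perm[v] for v in Ylab[:, 0]]
    Yp = LabelMatrix(Y=Yp_lab, sample_ids=[str(i) for i in range(200)])
    res_b = fit_consensus(Yp, Q_range=range(2, 5), seed=3, n_restarts=10,
                          tol=1e-9)
    assert res_a.model.Q == res_b.model.Q
    assert res_a.model.loglik == pytest.approx(res_b.model.loglik, abs=1e-6)
    assert nmi(res_a.labels, res_b.labels) == pytest.approx(1.0)


def test_consensus_not_materially_worse_than_best_member(rng):
    """Columns are independently corrupted copies of one truth."""
    n = 300
    truth = np.repeat([1, 2, 3, 4], n // 4)
    cols = []
    flip_rates = [0.1, 0.2, 0.3, 0.3]
    for rate in flip_rates:
        col = truth.copy()
        flip = rng.random(n) < rate
        col[flip] = rng.integers(1, 5, size=int(flip.sum()))
        cols.append(col)
    Y = LabelMatrix(Y=np.column_stack(cols),
                    sample_ids=[str(i) for i in range(n)])
    res = fit_consensus(Y, Q_range=range(2, 7), seed=0, n_restarts=10)
    consensus_nmi = nmi(truth, res.labels)
    best_member = max(nmi(truth, col) for col in cols)
    assert consensus_nmi >= best_member - 0.05


def test_empty_Q_range_rejected(rng):
    Ylab, _, _ = _sample_mixture(rng, n=30, Q=2, S=3)
    Y = LabelMatrix(Y=Ylab, sample_ids=[str(i) for i in range(30)])
    with pytest.raises(ValidationError):
        fit_consensus(Y, Q_range=[])
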
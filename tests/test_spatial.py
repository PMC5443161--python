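"""Scatter matrices and the Fisher-criterion beamformer."""

import numpy as np
import pytest
from scipy import linalg

from rpbci.core import EpochSet
from rpbci.spatial import (BeamformerModel, ScatterPair, apply_beamformer,
                           associated_pattern, compute_scatter, fisher_quotient,
                           fit_beamformer)

from conftest import make_epochset


def brute_force_scatter(data, labels):
    """Independent double-loop evaluation of the scatter definitions."""
    classes = sorted(set(labels))
    K = len(labels)
    n = data.shape[1]
    grand = sum(data[k] for k in range(K)) / K
    S_b = np.zeros((n, n))
    S_w = np.zeros((n, n))
    for c in classes:
        idx = [k for k in range(K) if labels[k] == c]
        m_c = sum(data[k] for k in idx) / len(idx)
        p_c = len(idx) / K
        S_b += p_c * (m_c - grand) @ (m_c - grand).T
        for k in idx:
            S_w += (data[k] - m_c) @ (data[k] - m_c).T
    return S_b, S_w


def random_scatter_pair(rng, n):
    """A random PSD pair with S_w positive definite."""
    a = rng.standard_normal((n, 2 * n))
    S_w = a @ a.T + 0.5 * np.eye(n)
    b = rng.standard_normal((n, 2))
    S_b = b @ b.T
    return ScatterPair(S_b=S_b, S_w=S_w)


class TestComputeScatter:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        es = make_epochset(rng, {"R": 5, "I": 7, "L": 4}, n_channels=4,
                           n_samples=10)
        _, sp = compute_scatter(es)
        S_b, S_w = brute_force_scatter(es.data, list(es.labels))
        np.testing.assert_allclose(sp.S_b, S_b, atol=1e-10)
        np.testing.assert_allclose(sp.S_w, S_w, atol=1e-10)

    def test_identical_class_means_give_zero_between(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, 3, 10))
        # two classes constructed with exactly equal means
        data = np.concatenate([base, base + 0.0], axis=0)
        data[4:] = base[::-1]  # permute epochs within class: same mean
        es = EpochSet(data, np.array(["R"] * 4 + ["I"] * 4, dtype=object),
                      ["a", "b", "c"], 100.0)
        _, sp = compute_scatter(es)
        np.testing.assert_allclose(sp.S_b, 0.0, atol=1e-10)

    def test_epochs_equal_to_class_mean_give_zero_within(self):
        x_r = np.ones((3, 10))
        x_i = np.full((3, 10), -2.0)
        data = np.stack([x_r, x_r, x_i, x_i])
        es = EpochSet(data, np.array(["R", "R", "I", "I"], dtype=object),
                      ["a", "b", "c"], 100.0)
        _, sp = compute_scatter(es)
        np.testing.assert_allclose(sp.S_w, 0.0, atol=1e-12)

    def test_grand_mean_is_count_weighted_combination(self):
        rng = np.random.default_rng(2)
        es = make_epochset(rng, {"R": 3, "I": 6}, n_channels=3, n_samples=8)
        stats, _ = compute_scatter(es)
        combo = sum(stats.class_priors[c] * stats.class_means[c]
                    for c in stats.class_means)
        np.testing.assert_allclose(stats.grand_mean, combo, atol=1e-12)
        assert sum(stats.class_priors.values()) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        es = make_epochset(rng, {"I": 5}, n_channels=3)
        with pytest.raises(ValueError, match="2 classes"):
            compute_scatter(es)


class TestFitBeamformer:
    def test_axis_aligned_discriminant(self):
        # S_w = I, class-mean difference on channel 1 only -> W = e1
        sp = ScatterPair(S_b=np.diag([4.0, 0.0]), S_w=np.eye(2))
        m = fit_beamformer(sp, gamma=0.0)
        np.testing.assert_allclose(m.W, [1.0, 0.0], atol=1e-12)

    def test_matches_dense_generalized_eig_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sp = random_scatter_pair(rng, 4)
            m = fit_beamformer(sp, gamma=0.0)
            # independent route: dense non-symmetric eigendecomposition
            evals, evecs = linalg.eig(np.linalg.solve(sp.S_w, sp.S_b))
            lead = evecs[:, np.argmax(evals.real)].real
            lead /= np.linalg.norm(lead)
            assert abs(m.W @ lead) > 1 - 1e-8

    def test_large_gamma_limit_is_leading_Sb_eigenvector(self):
        rng = np.random.default_rng(5)
        sp = random_scatter_pair(rng, 5)
        gamma = 1e6 * np.linalg.norm(sp.S_w)
        m = fit_beamformer(sp, gamma=gamma)
        evals, evecs = np.linalg.eigh(sp.S_b)
        lead = evecs[:, -1]
        assert abs(m.W @ lead) > 0.999

    def test_gamma_zero_on_singular_Sw_raises(self):
        sp = ScatterPair(S_b=np.eye(2), S_w=np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError, match="gamma"):
            fit_beamformer(sp, gamma=0.0)

    def test_monte_carlo_maximality_of_fisher_quotient(self):
        rng = np.random.default_rng(6)
        sp = random_scatter_pair(rng, 6)
        m = fit_beamformer(sp, gamma=0.0)
        j_star = fisher_quotient(sp, m.W)
        v = rng.standard_normal((1000, 6))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        j_rand = np.array([fisher_quotient(sp, vi) for vi in v])
        assert np.all(j_star >= j_rand - 1e-12)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        es = make_epochset(rng, {"R": 6, "I": 6}, n_channels=5,
                           n_samples=12, class_shift=1.0)
        perm = rng.permutation(5)
        es_p = es.with_data(es.data[:, perm, :])
        _, sp = compute_scatter(es)
        _, sp_p = compute_scatter(es_p)
        m = fit_beamformer(sp, gamma=0.1)
        m_p = fit_beamformer(sp_p, gamma=0.1)
        np.testing.assert_allclose(m_p.W, m.W[perm], atol=1e-8)
        y = apply_beamformer(es.data, m)
        y_p = apply_beamformer(es_p.data, m_p)
        np.testing.assert_allclose(y_p, y, atol=1e-8)

    def test_scale_invariance_of_normalized_filter(self):
        rng = np.random.default_rng(8)
        es = make_epochset(rng, {"R": 6, "I": 6}, n_channels=4,
                           n_samples=12, class_shift=1.0)
        _, sp = compute_scatter(es)
        es2 = es.with_data(3.7 * es.data)
        _, sp2 = compute_scatter(es2)
        m = fit_beamformer(sp, gamma=0.0)
        m2 = fit_beamformer(sp2, gamma=0.0)
        np.testing.assert_allclose(m2.W, m.W, atol=1e-8)

    def test_planted_pattern_recovered_through_whitening(self):
        # x = a s(t) + noise with class-dependent s: W aligns with
        # S_w^-1 a at high SNR
        rng = np.random.default_rng(9)
        n_ch, n_t = 6, 40
        a = rng.standard_normal(n_ch)
        a /= np.linalg.norm(a)
        data, labels = [], []
        for lab, mean_s in [("R", 3.0), ("I", -3.0)]:
            for _ in range(40):
                s = mean_s + 0.1 * rng.standard_normal(n_t)
                data.append(np.outer(a, s) + 0.05 * rng.standard_normal((n_ch, n_t)))
                labels.append(lab)
        es = EpochSet(np.stack(data), np.array(labels, dtype=object),
                      [f"c{i}" for i in range(n_ch)], 100.0)
        _, sp = compute_scatter(es)
        m = fit_beamformer(sp, gamma=1e-6 * np.trace(sp.S_w))
        target = np.linalg.solve(sp.S_w + 1e-9 * np.eye(n_ch), a)
        target /= np.linalg.norm(target)
        assert abs(m.W @ target) >= 0.9


class TestApplyBeamformer:
    def test_unit_filter_selects_channel(self):
        m = BeamformerModel(W=np.array([1.0, 0.0, 0.0]), gamma=0.0,
                            eigenvalues=np.array([1.0]))
        X = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(apply_beamformer(X, m), X[0])

    def test_zero_input_zero_output(self):
        m = BeamformerModel(W=np.array([0.6, 0.8]), gamma=0.0,
                            eigenvalues=np.array([1.0]))
        np.testing.assert_array_equal(apply_beamformer(np.zeros((2, 5)), m),
                                      np.zeros(5))

    def test_rank_one_epoch_recovers_source(self):
        rng = np.random.default_rng(10)
        w = rng.standard_normal(4)
        w /= np.linalg.norm(w)
        s = rng.standard_normal(30)
        m = BeamformerModel(W=w, gamma=0.0, eigenvalues=np.array([1.0]))
        y = apply_beamformer(np.outer(w, s), m)
        corr = np.corrcoef(y, s)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        m = BeamformerModel(W=np.array([1.0, 0.0]), gamma=0.0,
                            eigenvalues=np.array([1.0]))
        with pytest.raises(ValueError, match="channels"):
            apply_beamformer(np.zeros((3, 5)), m)

    def test_associated_pattern_of_planted_source(self):
        rng = np.random.default_rng(11)
        a = np.array([0.8, 0.6, 0.0])
        s = rng.standard_normal(200)
        data = np.stack([np.outer(a, s[i * 20:(i + 1) * 20]) for i in range(10)])
        es = EpochSet(data, np.array(["R", "I"] * 5, dtype=object),
                      ["x", "y", "z"], 100.0)
        m = BeamformerModel(W=np.array([1.0, 0.0, 0.0]), gamma=0.0,
                            eigenvalues=np.array([1.0]))
        pat = associated_pattern(es, m)
        assert abs(pat @ a) == pytest.approx(1.0, abs=1e-8)
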
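"""Mixed HMM: likelihood oracles, gradients, fitting, selection, decoding."""

import numpy as np
import pandas as pd
import pytest

from phocoena.divemetrics import METRIC_COLUMNS
from phocoena.hmm import (
    FitResult,
    MixedHMM,
    _n_free,
    _nll_and_grad,
    _pack,
    _prepare_sequences,
    decode_states,
    emission_logdensity,
    fit_mixed_hmm,
    name_states,
    select_model,
    sequence_loglik,
    stationary_distribution,
)
from phocoena.synthetic import simulate_metric_sequences

from .oracles import eigen_stationary, enumerate_loglik


def random_model(K, C, rng):
    return MixedHMM(
        K=K,
        C=C,
        tpms=rng.dirichlet(np.ones(K) * 2, size=(C, K)),
        weights=rng.dirichlet(np.ones(C)),
        mu=rng.normal(0, 1, K),
        sd=rng.uniform(0.3, 1.5, K),
        beta_a=rng.uniform(0.5, 5, (K, 6)),
        beta_b=rng.uniform(0.5, 5, (K, 6)),
        bern_p=rng.uniform(0.1, 0.9, K),
    )


THREE_STATE = MixedHMM(
    K=3,
    C=1,
    tpms=[[[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]],
    weights=[1.0],
    mu=[0.45, 0.85, 0.60],
    sd=[0.08, 0.08, 0.08],
    beta_a=[[2, 2, 2, 2, 2, 2], [8, 5, 3, 4, 2, 3], [18, 2, 2, 2, 10, 2]],
    beta_b=[[8, 5, 4, 4, 6, 5], [8, 4, 5, 4, 7, 4], [2, 5, 4, 5, 3, 4]],
    bern_p=[0.05, 0.95, 0.90],
)


class TestStationary:
    def test_matches_eigen_oracle(self, rng):
        for _ in range(20):
            K = int(rng.integers(2, 5))
            tpm = rng.dirichlet(np.ones(K), size=K)
            assert np.allclose(stationary_distribution(tpm), eigen_stationary(tpm), atol=1e-10)


class TestEmissionDensity:
    def test_gaussian_plus_bernoulli_closed_form(self):
        theta = {
            "mu": 0.0, "sd": 1.0,
            "beta_a": np.ones(6), "beta_b": np.ones(6), "bern_p": 0.5,
        }
        vec = [0.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.0]
        expected = -0.5 * np.log(2 * np.pi) + np.log(0.5)
        assert emission_logdensity(theta, vec) == pytest.approx(expected)

    def test_uniform_beta_contributes_zero(self):
        theta = {
            "mu": 0.0, "sd": 1.0,
            "beta_a": np.ones(6), "beta_b": np.ones(6), "bern_p": 0.5,
        }
        for x in (0.1, 0.5, 0.93):
            vec = [np.nan, x, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan]
            assert emission_logdensity(theta, vec) == pytest.approx(0.0)

    def test_impossible_bernoulli_floored_finite(self):
        theta = {
            "mu": 0.0, "sd": 1.0,
            "beta_a": np.ones(6), "beta_b": np.ones(6), "bern_p": 1.0,
        }
        vec = [np.nan] * 7 + [0.0]
        out = emission_logdensity(theta, vec)
        assert np.isfinite(out)
        assert out == pytest.approx(-700.0)

    def test_out_of_support_rejected(self):
        theta = {"mu": 0, "sd": 1, "beta_a": np.ones(6), "beta_b": np.ones(6), "bern_p": 0.5}
        vec = [0.0, 1.5, np.nan, np.nan, np.nan, np.nan, np.nan, 1.0]
        with pytest.raises(ValueError, match="rel_buzz_depth"):
            emission_logdensity(theta, vec)


class TestSequenceLoglik:
    def test_single_state_collapse(self, rng):
        m = random_model(1, 1, rng)
        seqs, _, _ = simulate_metric_sequences(m, [15], seed=0)
        ll = sequence_loglik(m, seqs)
        theta = m.state_params(0)
        direct = sum(
            emission_logdensity(theta, row) for row in seqs[0].to_numpy()
        )
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_context_degeneracy(self, rng):
        m1 = random_model(3, 1, rng)
        m2 = MixedHMM(
            K=3, C=2,
            tpms=np.stack([m1.tpms[0], m1.tpms[0]]),
            weights=[0.3, 0.7],
            mu=m1.mu, sd=m1.sd, beta_a=m1.beta_a, beta_b=m1.beta_b, bern_p=m1.bern_p,
        )
        seqs, _, _ = simulate_metric_sequences(m1, [30, 20], seed=1)
        assert sequence_loglik(m2, seqs) == pytest.approx(sequence_loglik(m1, seqs), abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(25):
            K = int(rng.integers(1, 4))
            C = int(rng.integers(1, 3))
            m = random_model(K, C, rng)
            seqs, _, _ = simulate_metric_sequences(m, [int(rng.integers(2, 6))], seed=trial)
            assert sequence_loglik(m, seqs) == pytest.approx(
                enumerate_loglik(m, seqs), abs=1e-8
            )

    def test_label_permutation_symmetry(self, rng):
        m = random_model(3, 2, rng)
        seqs, _, _ = simulate_metric_sequences(m, [40], seed=3)
        perm = [2, 0, 1]
        permuted = MixedHMM(
            K=3, C=2,
            tpms=m.tpms[:, perm][:, :, perm],
            weights=m.weights,
            mu=m.mu[perm], sd=m.sd[perm],
            beta_a=m.beta_a[perm], beta_b=m.beta_b[perm], bern_p=m.bern_p[perm],
        )
        assert sequence_loglik(permuted, seqs) == pytest.approx(
            sequence_loglik(m, seqs), abs=1e-9
        )

    def test_empty_rejected(self, rng):
        m = random_model(2, 1, rng)
        with pytest.raises(ValueError):
            sequence_loglik(m, [])


class TestGradient:
    def test_analytic_matches_finite_differences(self, rng):
        m = random_model(3, 2, rng)
        seqs, _, _ = simulate_metric_sequences(m, [40, 30], seed=5)
        prepped = _prepare_sequences(seqs)
        w0 = _pack(m) + rng.normal(0, 0.1, _n_free(3, 2))
        _, g = _nll_and_grad(w0, prepped, 3, 2)
        eps = 1e-6
        num = np.empty_like(g)
        for i in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            num[i] = (
                _nll_and_grad(wp, prepped, 3, 2)[0] - _nll_and_grad(wm, prepped, 3, 2)[0]
            ) / (2 * eps)
        assert np.abs(g - num).max() < 1e-5 * max(1.0, np.abs(num).max())


class TestFit:
    def test_k1_recovers_sample_mean(self, rng):
        m = random_model(1, 1, rng)
        seqs, _, _ = simulate_metric_sequences(m, [300], seed=2)
        fit = fit_mixed_hmm(seqs, K=1, C=1, n_restarts=2, seed=0)
        sample_mean = seqs[0]["log_mean_msa"].mean()
        assert fit.model.mu[0] == pytest.approx(sample_mean, abs=1e-6)

    def test_aic_identity(self, rng):
        seqs, _, _ = simulate_metric_sequences(THREE_STATE, [200], seed=4)
        fit = fit_mixed_hmm(seqs, K=2, C=1, n_restarts=2, seed=0)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)
        assert fit.n_params == 15 * 2 + 1 * 2 * 1 + 0

    def test_best_of_restarts_and_determinism(self, rng):
        seqs, _, _ = simulate_metric_sequences(THREE_STATE, [300], seed=6)
        fit1 = fit_mixed_hmm(seqs, K=3, C=1, n_restarts=3, seed=42)
        fit2 = fit_mixed_hmm(seqs, K=3, C=1, n_restarts=3, seed=42)
        assert fit1.loglik == fit2.loglik
        assert np.array_equal(fit1.model.mu, fit2.model.mu)
        assert fit1.loglik >= max(fit1.restart_logliks) - 1e-9

    def test_invalid_k_rejected(self, rng):
        seqs, _, _ = simulate_metric_sequences(THREE_STATE, [50], seed=0)
        with pytest.raises(ValueError):
            fit_mixed_hmm(seqs, K=5, C=1)


class TestSelectModel:
    def _fake(self, aic, K, C):
        m = MixedHMM(
            K=K, C=C,
            tpms=np.tile(np.eye(K) * 0 + 1.0 / K, (C, 1, 1)),
            weights=np.ones(C) / C,
            mu=np.zeros(K), sd=np.ones(K),
            beta_a=np.ones((K, 6)), beta_b=np.ones((K, 6)), bern_p=np.full(K, 0.5),
        )
        return FitResult(m, loglik=0.0, n_params=1, aic=aic, n_restarts=1, converged=True, seed=0)

    def test_single_candidate(self):
        f = self._fake(10.0, 2, 1)
        assert select_model([f]) is f

    def test_tie_prefers_smaller_k(self):
        f3 = self._fake(100.0, 3, 1)
        f4 = self._fake(100.0, 4, 1)
        assert select_model([f4, f3]).model.K == 3

    def test_minimum_aic_wins(self):
        fits = [self._fake(a, k, 1) for a, k in [(50.0, 2), (40.0, 3), (45.0, 4)]]
        assert select_model(fits).model.K == 3


class TestDecode:
    def test_single_state_single_label(self, rng):
        m = random_model(1, 1, rng)
        seqs, _, _ = simulate_metric_sequences(m, [20], seed=0)
        paths, post = decode_states(m, seqs)
        assert np.array_equal(paths[0], np.zeros(20, dtype=int))
        assert post.shape == (1, 1)

    def test_viterbi_accuracy_on_separated_states(self):
        seqs, states, _ = simulate_metric_sequences(THREE_STATE, [500, 500], seed=8)
        paths, _ = decode_states(THREE_STATE, seqs)
        acc = np.mean(np.concatenate(paths) == np.concatenate(states))
        assert acc >= 0.90

    def test_smoothing_close_to_viterbi(self):
        seqs, _, _ = simulate_metric_sequences(THREE_STATE, [300], seed=9)
        v, _ = decode_states(THREE_STATE, seqs, method="viterbi")
        s, _ = decode_states(THREE_STATE, seqs, method="smoothing")
        assert np.mean(v[0] == s[0]) > 0.95

    def test_state_naming_rule(self):
        names = name_states(THREE_STATE)
        # state 0: lowest buzz probability -> nonfeeding;
        # state 2 concentrates buzzes at depth (beta mean 0.9) -> bottom
        assert names[0] == "nonfeeding"
        assert names[2] == "bottom"
        assert names[1] == "pelagic"

    def test_roundtrip_serialization(self, tmp_path):
        path = tmp_path / "model.json"
        THREE_STATE.to_json(path)
        loaded = MixedHMM.from_json(path)
        assert np.allclose(loaded.tpms, THREE_STATE.tpms)
        assert np.allclose(loaded.beta_a, THREE_STATE.beta_a)
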
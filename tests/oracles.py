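"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: buzz rules are
applied with explicit loops, the HMM likelihood is computed by exhaustive
path enumeration, and the stationary distribution by eigen-decomposition.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_buzzes(
    times,
    max_ici=0.010,
    min_run=5,
    min_dur=0.2,
    min_clicks=101,
    merge_gap=1.0,
):
    """Rules (i)-(iv) applied one by one with plain loops."""
    times = list(times)
    runs = []
    current = []
    for t in times:
        if current and t - current[-1] >= max_ici:
            runs.append(current)
            current = []
        current.append(t)
    if current:
        runs.append(current)
    runs = [r for r in runs if len(r) >= min_run]
    runs = [r for r in runs if (r[-1] - r[0]) >= min_dur and len(r) >= min_clicks]
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) < merge_gap:
            merged[-1] = (merged[-1][0], r[-1], merged[-1][2] + len(r))
        else:
            merged.append((r[0], r[-1], len(r)))
    return merged


def enumerate_loglik(model, sequences):
    """Marginal log-likelihood by summing over every state path and context."""
    from phocoena.hmm import _emission_logB, _prepare_sequences

    seqs = _prepare_sequences(sequences)
    arrays = (model.mu, model.sd, model.beta_a, model.beta_b, model.bern_p)
    total = 0.0
    for X in seqs:
        logB = _emission_logB(X, arrays)
        T = X.shape[0]
        mix = 0.0
        for c in range(model.C):
            delta = eigen_stationary(model.tpms[c])
            like = 0.0
            for path in itertools.product(range(model.K), repeat=T):
                lp = np.log(delta[path[0]]) + logB[0, path[0]]
                for t in range(1, T):
                    lp += np.log(model.tpms[c][path[t - 1], path[t]]) + logB[t, path[t]]
                like += np.exp(lp)
            mix += model.weights[c] * like
        total += np.log(mix)
    return total


def eigen_stationary(tpm):
    """Stationary distribution from the unit left eigenvector."""
    vals, vecs = np.linalg.eig(np.asarray(tpm, dtype=float).T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    return v / v.sum()


def random_click_train(rng, n_runs=4, straddle=True):
    """Click trains mixing ICIs just below and above the 10 ms threshold."""
    t = rng.uniform(0, 5)
    times = []
    for _ in range(n_runs):
        n = int(rng.integers(2, 180))
        if straddle and rng.random() < 0.5:
            icis = rng.uniform(0.0005, 0.0099, n)
        else:
            icis = rng.uniform(0.0005, 0.03, n)
        # occasionally pin ICIs exactly at the threshold to hit the boundary
        if rng.random() < 0.3:
            icis[rng.integers(0, n)] = 0.010
        for d in icis:
            t += d
            times.append(t)
        t += rng.uniform(0.0, 2.5)
    return np.array(times)
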
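"""Scaled forward-backward and Viterbi recursions.

Kernels are written in plain loops so they can be numba-jitted when numba
is importable and still run (slower) as pure Python otherwise. Emission
probabilities arrive as per-time-step shifted likelihoods ``b`` (each row
of log densities is shifted by its maximum before exponentiation); the
caller adds the shift total back onto the log-likelihood.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, error_model="numpy")
def forward_backward(b, gamma_mat, delta):
    """Return (loglik, gamma, xi_sum) for one sequence under one TPM.

    b: (T, K) shifted emission likelihoods; gamma_mat: (K, K) row-stochastic
    TPM; delta: (K,) initial distribution. gamma is the (T, K) state
    posterior; xi_sum the (K, K) expected transition counts.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = delta[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * gamma_mat[i, j]
            alpha[t, j] = acc * b[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    beta = np.ones(K)
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        bb = np.empty(K)
        for j in range(K):
            bb[j] = b[t + 1, j] * beta[j]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += alpha[t, i] * gamma_mat[i, j] * bb[j] / c[t + 1]
        newbeta = np.empty(K)
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += gamma_mat[i, j] * bb[j]
            newbeta[i] = acc / c[t + 1]
        for i in range(K):
            beta[i] = newbeta[i]
            gamma[t, i] = alpha[t, i] * beta[i]
    return loglik, gamma, xi_sum


@njit(cache=True, error_model="numpy")
def forward_loglik(b, gamma_mat, delta):
    """Scaled forward pass only; returns the (shifted) log-likelihood."""
    T, K = b.shape
    alpha = np.empty(K)
    s = 0.0
    for k in range(K):
        alpha[k] = delta[k] * b[0, k]
        s += alpha[k]
    loglik = np.log(s)
    for k in range(K):
        alpha[k] /= s
    for t in range(1, T):
        new = np.empty(K)
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[i] * gamma_mat[i, j]
            new[j] = acc * b[t, j]
            s += new[j]
        loglik += np.log(s)
        for j in range(K):
            alpha[j] = new[j] / s
    return loglik


@njit(cache=True, error_model="numpy")
def viterbi(logb, log_gamma, log_delta):
    """Most probable state path (log-domain dynamic programming)."""
    T, K = logb.shape
    score = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        score[0, k] = log_delta[k] + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = score[t - 1, i] + log_gamma[i, j]
                if v > best:
                    best = v
                    arg = i
            score[t, j] = best + logb[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    last = 0
    best = -np.inf
    for k in range(K):
        if score[T - 1, k] > best:
            best = score[T - 1, k]
            last = k
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
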
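"""Mixed hidden Markov model for dive-level behavioral states.

K latent states emit eight per-dive metrics through heterogeneous
state-dependent distributions (Gaussian for log mean MSA, beta for the six
unit-interval metrics, Bernoulli for buzz presence; missing metrics are
marginalized by omission). A discrete random effect lets each animal's
transition probabilities derive from one of C shared "behavioral
contexts", each with its own transition probability matrix (TPM); the
marginal likelihood for an animal is the context-weighted mixture of
standard HMM likelihoods. Emissions are shared across contexts, so
contexts differ only in how states succeed one another.

Fitting maximizes the exact marginal log-likelihood by quasi-Newton search
on an unconstrained working scale (log/logit/softmax transforms) with
analytic gradients assembled from forward-backward posteriors; the initial
state distribution of each context is tied to the stationary distribution
of its TPM and differentiated implicitly. Multi-restart protocol with AIC
model selection across (K, C).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import betaln, digamma, logsumexp

from ._recursions import forward_backward, forward_loglik, viterbi
from .divemetrics import METRIC_COLUMNS

__all__ = [
    "MixedHMM",
    "FitResult",
    "emission_logdensity",
    "sequence_loglik",
    "fit_mixed_hmm",
    "select_model",
    "decode_states",
    "name_states",
    "stationary_distribution",
]

_LOG_FLOOR = -700.0
_N_BETA = 6
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model container


@dataclass
class MixedHMM:
    """K states x C contexts: shared emissions, per-context TPMs."""

    K: int
    C: int
    tpms: np.ndarray  # (C, K, K)
    weights: np.ndarray  # (C,)
    mu: np.ndarray  # (K,) Gaussian mean of log_mean_msa
    sd: np.ndarray  # (K,) Gaussian sd, > 0
    beta_a: np.ndarray  # (K, 6)
    beta_b: np.ndarray  # (K, 6)
    bern_p: np.ndarray  # (K,)
    state_names: list | None = None

    def __post_init__(self):
        self.tpms = np.asarray(self.tpms, dtype=float).reshape(self.C, self.K, self.K)
        self.weights = np.asarray(self.weights, dtype=float)
        for arr in ("mu", "sd", "beta_a", "beta_b", "bern_p"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if not np.allclose(self.tpms.sum(axis=2), 1.0, atol=1e-10):
            raise ValueError("TPM rows must sum to 1")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-10):
            raise ValueError("context weights must sum to 1")
        if np.any(self.sd <= 0) or np.any(self.beta_a <= 0) or np.any(self.beta_b <= 0):
            raise ValueError("scale/shape parameters must be positive")

    @property
    def n_params(self) -> int:
        return 15 * self.K + self.C * self.K * (self.K - 1) + (self.C - 1)

    def deltas(self) -> np.ndarray:
        """Per-context initial distributions (stationary of each TPM)."""
        return np.stack([stationary_distribution(self.tpms[c]) for c in range(self.C)])

    def state_params(self, k: int) -> dict:
        return {
            "mu": float(self.mu[k]),
            "sd": float(self.sd[k]),
            "beta_a": self.beta_a[k].copy(),
            "beta_b": self.beta_b[k].copy(),
            "bern_p": float(self.bern_p[k]),
        }

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "C": self.C,
            "tpms": self.tpms.tolist(),
            "weights": self.weights.tolist(),
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "beta_a": self.beta_a.tolist(),
            "beta_b": self.beta_b.tolist(),
            "bern_p": self.bern_p.tolist(),
            "state_names": self.state_names,
            "metrics": METRIC_COLUMNS,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixedHMM":
        return cls(
            K=d["K"],
            C=d["C"],
            tpms=np.array(d["tpms"]),
            weights=np.array(d["weights"]),
            mu=np.array(d["mu"]),
            sd=np.array(d["sd"]),
            beta_a=np.array(d["beta_a"]),
            beta_b=np.array(d["beta_b"]),
            bern_p=np.array(d["bern_p"]),
            state_names=d.get("state_names"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MixedHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    model: MixedHMM
    loglik: float
    n_params: int
    aic: float
    n_restarts: int
    converged: bool
    seed: int
    restart_logliks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
            "restart_logliks": self.restart_logliks,
        }


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution via the linear system delta' (I - G + 11') = 1'."""
    tpm = np.asarray(tpm, dtype=float)
    K = tpm.shape[0]
    A = np.eye(K) - tpm + np.ones((K, K))
    return np.linalg.solve(A.T, np.ones(K))


# ---------------------------------------------------------------------------
# emission densities


def _as_matrix(seq) -> np.ndarray:
    if isinstance(seq, pd.DataFrame):
        return seq[METRIC_COLUMNS].to_numpy(dtype=float)
    arr = np.asarray(seq, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(METRIC_COLUMNS):
        raise ValueError(f"sequence must be (T, {len(METRIC_COLUMNS)})")
    return arr


def _check_support(X: np.ndarray) -> None:
    beta_block = X[:, 1:7]
    finite = np.isfinite(beta_block)
    if np.any((beta_block[finite] <= 0) | (beta_block[finite] >= 1)):
        bad = [
            METRIC_COLUMNS[1 + j]
            for j in range(_N_BETA)
            if np.any(
                (beta_block[:, j][np.isfinite(beta_block[:, j])] <= 0)
                | (beta_block[:, j][np.isfinite(beta_block[:, j])] >= 1)
            )
        ]
        raise ValueError(
            f"beta metrics outside (0,1) (apply the unit-interval squeeze): {bad}"
        )
    bern = X[:, 7]
    ok = np.isfinite(bern)
    if np.any((bern[ok] != 0) & (bern[ok] != 1)):
        raise ValueError("buzz_present must be 0/1")


def _emission_logB(X: np.ndarray, model_arrays, floored_out: dict | None = None) -> np.ndarray:
    """(N, K) summed per-metric log densities with missing-value omission.

    Each metric's contribution is floored at -700 nats; if ``floored_out``
    is given it receives, per metric name, the boolean floored array (rows
    restricted to non-missing samples) so gradients can be zeroed there.
    """
    mu, sd, beta_a, beta_b, bern_p = model_arrays
    N = X.shape[0]
    K = mu.shape[0]
    logB = np.zeros((N, K))
    x0 = X[:, 0]
    m0 = np.isfinite(x0)
    z = (x0[m0, None] - mu[None, :]) / sd[None, :]
    lp = -0.5 * _LOG2PI - np.log(sd)[None, :] - 0.5 * z * z
    if floored_out is not None:
        floored_out["gauss"] = lp < _LOG_FLOOR
    logB[m0] += np.maximum(lp, _LOG_FLOOR)
    for j in range(_N_BETA):
        xj = X[:, 1 + j]
        mj = np.isfinite(xj)
        if not mj.any():
            if floored_out is not None:
                floored_out[f"beta{j}"] = np.zeros((0, K), dtype=bool)
            continue
        a = beta_a[:, j]
        b = beta_b[:, j]
        lx = np.log(xj[mj, None])
        l1x = np.log1p(-xj[mj, None])
        lp = (a - 1.0)[None, :] * lx + (b - 1.0)[None, :] * l1x - betaln(a, b)[None, :]
        if floored_out is not None:
            floored_out[f"beta{j}"] = lp < _LOG_FLOOR
        logB[mj] += np.maximum(lp, _LOG_FLOOR)
    x7 = X[:, 7]
    m7 = np.isfinite(x7)
    p = np.clip(bern_p, 1e-300, 1.0)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.where(p < 1.0, np.log1p(-np.minimum(p, 1.0 - 1e-300)), -np.inf)
    # select the branch rather than multiply (avoids 0 * -inf)
    lp = np.where(x7[m7, None] > 0.5, logp[None, :], log1mp[None, :])
    if floored_out is not None:
        floored_out["bern"] = lp < _LOG_FLOOR
    logB[m7] += np.maximum(lp, _LOG_FLOOR)
    return logB


def emission_logdensity(theta: dict, metric_vector) -> float:
    """Summed log density of one metric vector under one state's emissions.

    ``theta`` as returned by :meth:`MixedHMM.state_params`; NaN entries are
    skipped (missing-at-random marginalization); each metric's contribution
    is floored at -700 nats.
    """
    vec = np.asarray(metric_vector, dtype=float).reshape(1, -1)
    _check_support(vec)
    arrays = (
        np.atleast_1d(np.asarray(theta["mu"], dtype=float)),
        np.atleast_1d(np.asarray(theta["sd"], dtype=float)),
        np.asarray(theta["beta_a"], dtype=float).reshape(1, _N_BETA),
        np.asarray(theta["beta_b"], dtype=float).reshape(1, _N_BETA),
        np.atleast_1d(np.asarray(theta["bern_p"], dtype=float)),
    )
    return float(_emission_logB(vec, arrays)[0, 0])


# ---------------------------------------------------------------------------
# marginal likelihood


def _prepare_sequences(sequences) -> list[np.ndarray]:
    seqs = [_as_matrix(s) for s in sequences]
    if len(seqs) == 0 or any(s.shape[0] == 0 for s in seqs):
        raise ValueError("need at least one nonempty sequence per animal")
    for s in seqs:
        _check_support(s)
    return seqs


def sequence_loglik(model: MixedHMM, sequences) -> float:
    """Sum over animals of log sum_c pi_c L(sequence | TPM_c, emissions)."""
    seqs = _prepare_sequences(sequences)
    arrays = (model.mu, model.sd, model.beta_a, model.beta_b, model.bern_p)
    deltas = model.deltas()
    logpi = np.log(np.clip(model.weights, 1e-300, None))
    total = 0.0
    for X in seqs:
        logB = _emission_logB(X, arrays)
        shift = logB.max(axis=1)
        b = np.exp(logB - shift[:, None])
        lls = np.array(
            [
                forward_loglik(b, model.tpms[c], deltas[c]) + shift.sum()
                for c in range(model.C)
            ]
        )
        total += logsumexp(logpi + lls)
    return float(total)


# ---------------------------------------------------------------------------
# working-scale packing


def _n_free(K: int, C: int) -> int:
    return 15 * K + C * K * (K - 1) + (C - 1)


def _unpack(w: np.ndarray, K: int, C: int):
    i = 0
    mu = w[i : i + K]
    i += K
    log_sd = w[i : i + K]
    i += K
    log_a = w[i : i + 6 * K].reshape(K, _N_BETA)
    i += 6 * K
    log_b = w[i : i + 6 * K].reshape(K, _N_BETA)
    i += 6 * K
    eta = w[i : i + K]
    i += K
    z = w[i : i + C * K * (K - 1)].reshape(C, K, K - 1)
    i += C * K * (K - 1)
    zw = w[i : i + C - 1]
    sd = np.exp(log_sd)
    a = np.exp(log_a)
    b = np.exp(log_b)
    p = 1.0 / (1.0 + np.exp(-eta))
    full = np.concatenate([z, np.zeros((C, K, 1))], axis=2)
    full -= full.max(axis=2, keepdims=True)
    tpms = np.exp(full)
    tpms /= tpms.sum(axis=2, keepdims=True)
    zw_full = np.concatenate([zw, [0.0]])
    zw_full -= zw_full.max()
    weights = np.exp(zw_full)
    weights /= weights.sum()
    return mu, sd, a, b, p, eta, tpms, weights


def _pack(model: MixedHMM) -> np.ndarray:
    z = np.log(np.clip(model.tpms, 1e-300, None))
    z = z[:, :, :-1] - z[:, :, -1:]
    zw = np.log(np.clip(model.weights, 1e-300, None))
    zw = zw[:-1] - zw[-1]
    eta = np.log(model.bern_p / (1.0 - model.bern_p))
    return np.concatenate(
        [
            model.mu,
            np.log(model.sd),
            np.log(model.beta_a).ravel(),
            np.log(model.beta_b).ravel(),
            eta,
            z.ravel(),
            zw,
        ]
    )


def _model_from_working(w: np.ndarray, K: int, C: int) -> MixedHMM:
    mu, sd, a, b, p, _, tpms, weights = _unpack(w, K, C)
    return MixedHMM(
        K=K, C=C, tpms=tpms, weights=weights, mu=mu.copy(), sd=sd, beta_a=a,
        beta_b=b, bern_p=p,
    )


# ---------------------------------------------------------------------------
# objective with analytic gradient


def _bounds(K: int, C: int) -> list[tuple]:
    """Box bounds on the working scale.

    They keep scale/shape parameters inside a numerically safe range and,
    importantly, bound the beta concentrations and Gaussian sd away from
    the density spikes that make the likelihood unbounded when a metric is
    nearly constant within a state (the mixture-variance-collapse analog).
    """
    bounds = [(-50.0, 50.0)] * K  # mu
    bounds += [(-10.0, 10.0)] * K  # log sd
    bounds += [(-10.0, 12.0)] * (12 * K)  # log beta shapes
    bounds += [(-30.0, 30.0)] * K  # logit p
    bounds += [(-30.0, 30.0)] * (C * K * (K - 1))  # TPM logits
    bounds += [(-30.0, 30.0)] * (C - 1)  # weight logits
    return bounds


def _nll_and_grad(w: np.ndarray, seqs: list[np.ndarray], K: int, C: int):
    mu, sd, a, b, p, eta, tpms, weights = _unpack(w, K, C)
    arrays = (mu, sd, a, b, p)

    deltas = np.empty((C, K))
    Ainvs = np.empty((C, K, K))
    for c in range(C):
        A = np.eye(K) - tpms[c] + np.ones((K, K))
        Ainvs[c] = np.linalg.inv(A)
        deltas[c] = np.ones(K) @ Ainvs[c]

    logpi = np.log(np.clip(weights, 1e-300, None))
    X_all = np.concatenate(seqs, axis=0)
    floored: dict = {}
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        logB_all = _emission_logB(X_all, arrays, floored_out=floored)
    if not np.all(np.isfinite(logB_all)):
        return 1e12, np.zeros_like(w)
    offsets = np.cumsum([0] + [s.shape[0] for s in seqs])

    nll = 0.0
    G_all = np.zeros_like(logB_all)  # d loglik / d logB
    Gg = np.zeros((C, K, K))  # d loglik / d TPM entries
    W = np.zeros(C)  # summed context posteriors
    for ai in range(len(seqs)):
        sl = slice(offsets[ai], offsets[ai + 1])
        logB = logB_all[sl]
        shift = logB.max(axis=1)
        bmat = np.exp(logB - shift[:, None])
        lls = np.empty(C)
        gammas = []
        xis = []
        for c in range(C):
            ll_c, gam, xi = forward_backward(bmat, tpms[c], deltas[c])
            lls[c] = ll_c + shift.sum()
            gammas.append(gam)
            xis.append(xi)
        ll_a = logsumexp(logpi + lls)
        nll -= ll_a
        wpost = np.exp(logpi + lls - ll_a)
        W += wpost
        for c in range(C):
            if wpost[c] < 1e-300:
                continue
            G_all[sl] += wpost[c] * gammas[c]
            with np.errstate(divide="ignore", invalid="ignore"):
                dGamma = np.where(tpms[c] > 0, xis[c] / tpms[c], 0.0)
            u = gammas[c][0] / np.clip(deltas[c], 1e-300, None)
            dGamma += np.outer(deltas[c], Ainvs[c] @ u)
            Gg[c] += wpost[c] * dGamma

    grad = np.zeros_like(w)
    i = 0
    # Gaussian
    x0 = X_all[:, 0]
    m0 = np.isfinite(x0)
    z0 = (x0[m0, None] - mu[None, :]) / sd[None, :]
    G0 = np.where(floored["gauss"], 0.0, G_all[m0])
    grad[i : i + K] = -(G0 * z0 / sd[None, :]).sum(axis=0)
    i += K
    grad[i : i + K] = -(G0 * (z0 * z0 - 1.0)).sum(axis=0)
    i += K
    # betas (log a, log b)
    ga = np.empty((K, _N_BETA))
    gb = np.empty((K, _N_BETA))
    for j in range(_N_BETA):
        xj = X_all[:, 1 + j]
        mj = np.isfinite(xj)
        if not mj.any():
            ga[:, j] = 0.0
            gb[:, j] = 0.0
            continue
        Gj = np.where(floored[f"beta{j}"], 0.0, G_all[mj])
        lx = np.log(xj[mj, None])
        l1x = np.log1p(-xj[mj, None])
        psi_ab = digamma(a[:, j] + b[:, j])
        da = lx - digamma(a[:, j])[None, :] + psi_ab[None, :]
        db = l1x - digamma(b[:, j])[None, :] + psi_ab[None, :]
        ga[:, j] = -(Gj * da).sum(axis=0) * a[:, j]
        gb[:, j] = -(Gj * db).sum(axis=0) * b[:, j]
    grad[i : i + 6 * K] = ga.ravel()
    i += 6 * K
    grad[i : i + 6 * K] = gb.ravel()
    i += 6 * K
    # Bernoulli (logit p)
    x7 = X_all[:, 7]
    m7 = np.isfinite(x7)
    G7 = np.where(floored["bern"], 0.0, G_all[m7])
    grad[i : i + K] = -(G7 * (x7[m7, None] - p[None, :])).sum(axis=0)
    i += K
    # TPM logits (pivot-softmax rows)
    gz = np.empty((C, K, K - 1))
    for c in range(C):
        row_dot = (tpms[c] * Gg[c]).sum(axis=1, keepdims=True)
        full = tpms[c] * (Gg[c] - row_dot)
        gz[c] = -full[:, :-1]
    grad[i : i + C * K * (K - 1)] = gz.ravel()
    i += C * K * (K - 1)
    # context weight logits
    if C > 1:
        n_animals = len(seqs)
        grad[i : i + C - 1] = -(W[:-1] - weights[:-1] * n_animals)
    if not np.isfinite(nll):
        return 1e12, np.zeros_like(w)
    return nll, grad


# ---------------------------------------------------------------------------
# initialization and fitting


def _init_working(seqs, K: int, C: int, rng: np.random.Generator) -> np.ndarray:
    X = np.concatenate(seqs, axis=0)
    perm = rng.permutation(K)

    def block_stats(col):
        vals = np.sort(col[np.isfinite(col)])
        if vals.size < K:
            vals = np.repeat(vals, K) if vals.size else np.array([0.5])
        blocks = np.array_split(vals, K)
        return np.array([blk.mean() for blk in blocks]), np.array(
            [blk.std() + 1e-3 for blk in blocks]
        )

    mu_blocks, sd_blocks = block_stats(X[:, 0])
    mu = mu_blocks[np.argsort(perm)] + rng.normal(0, 0.1, K) * (sd_blocks.mean() + 1e-3)
    log_sd = np.log(np.clip(sd_blocks[np.argsort(perm)], 1e-2, None)) + rng.normal(
        0, 0.1, K
    )
    log_a = np.empty((K, _N_BETA))
    log_b = np.empty((K, _N_BETA))
    for j in range(_N_BETA):
        m_blk, s_blk = block_stats(X[:, 1 + j])
        m_blk = np.clip(m_blk[np.argsort(perm)], 0.02, 0.98)
        v_blk = np.clip(s_blk[np.argsort(perm)] ** 2, 1e-5, None)
        s = np.clip(m_blk * (1 - m_blk) / v_blk - 1.0, 0.5, 200.0)
        log_a[:, j] = np.log(np.clip(m_blk * s, 0.05, 500.0)) + rng.normal(0, 0.2, K)
        log_b[:, j] = np.log(np.clip((1 - m_blk) * s, 0.05, 500.0)) + rng.normal(
            0, 0.2, K
        )
    x7 = X[:, 7]
    p_blocks, _ = block_stats(x7)
    p0 = np.clip(p_blocks[np.argsort(perm)], 0.02, 0.98)
    eta = np.log(p0 / (1 - p0)) + rng.normal(0, 0.3, K)
    z = np.empty((C, K, K - 1))
    for c in range(C):
        for irow in range(K):
            alpha = np.ones(K)
            alpha[irow] += 5.0
            row = rng.dirichlet(alpha)
            lz = np.log(row)
            z[c, irow] = lz[:-1] - lz[-1]
    if C > 1:
        wgt = rng.dirichlet(np.ones(C))
        lw = np.log(wgt)
        zw = lw[:-1] - lw[-1]
    else:
        zw = np.empty(0)
    return np.concatenate([mu, log_sd, log_a.ravel(), log_b.ravel(), eta, z.ravel(), zw])


def fit_mixed_hmm(
    sequences,
    K: int,
    C: int = 1,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> FitResult:
    """Best-of-restarts maximum marginal likelihood fit.

    Each restart draws perturbed quantile-split emission initials and
    diagonal-dominant Dirichlet TPMs, then runs L-BFGS-B on the working
    scale (relative tolerance 1e-8, gradient tolerance 1e-5, up to
    ``max_iter`` iterations). Deterministic given ``seed``.
    """
    if not 1 <= K <= 4 or not 1 <= C <= 4:
        raise ValueError("K and C must lie in 1..4")
    seqs = _prepare_sequences(sequences)
    n_obs = sum(s.shape[0] for s in seqs)
    n_params = _n_free(K, C)
    if n_obs < 10 * n_params:
        warnings.warn(
            f"only {n_obs} dives for {n_params} parameters; fit may be unstable"
        )
    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_restarts)]
    best = None
    restart_lls = []
    failures = []
    for r, rng in enumerate(child_rngs):
        w0 = _init_working(seqs, K, C, rng)
        try:
            res = scipy.optimize.minimize(
                _nll_and_grad,
                w0,
                args=(seqs, K, C),
                jac=True,
                method="L-BFGS-B",
                bounds=_bounds(K, C),
                options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
            )
        except (np.linalg.LinAlgError, FloatingPointError) as exc:
            failures.append(f"restart {r}: {exc}")
            continue
        ll = -res.fun
        restart_lls.append(float(ll))
        if not np.isfinite(ll):
            failures.append(f"restart {r}: non-finite loglik")
            continue
        if best is None or ll > best[0]:
            best = (ll, res.x, bool(res.success))
    if best is None:
        raise RuntimeError("all restarts failed: " + "; ".join(failures))
    ll, w_best, converged = best
    model = _model_from_working(w_best, K, C)
    return FitResult(
        model=model,
        loglik=float(ll),
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * float(ll),
        n_restarts=n_restarts,
        converged=converged,
        seed=seed,
        restart_logliks=restart_lls,
    )


def select_model(fits: list[FitResult]) -> FitResult:
    """Minimum-AIC fit; exact ties broken toward smaller K, then smaller C."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.model.K, f.model.C))


# ---------------------------------------------------------------------------
# decoding and naming


def decode_states(model: MixedHMM, sequences, method: str = "viterbi"):
    """Per-animal state paths and context posteriors.

    The context posterior is proportional to pi_c * L_animal(c); decoding
    runs under each animal's maximum-posterior context. ``method`` is
    ``viterbi`` (joint most probable path, default) or ``smoothing``
    (per-dive maximum of the local state posterior).

    Returns (list of state-index arrays, (n_animals, C) context posterior).
    """
    seqs = _prepare_sequences(sequences)
    arrays = (model.mu, model.sd, model.beta_a, model.beta_b, model.bern_p)
    deltas = model.deltas()
    logpi = np.log(np.clip(model.weights, 1e-300, None))
    paths = []
    ctx_post = np.empty((len(seqs), model.C))
    for ai, X in enumerate(seqs):
        logB = _emission_logB(X, arrays)
        shift = logB.max(axis=1)
        bmat = np.exp(logB - shift[:, None])
        lls = np.array(
            [
                forward_loglik(bmat, model.tpms[c], deltas[c]) + shift.sum()
                for c in range(model.C)
            ]
        )
        post = logpi + lls
        post -= logsumexp(post)
        ctx_post[ai] = np.exp(post)
        c_star = int(np.argmax(ctx_post[ai]))
        log_gamma = np.log(np.clip(model.tpms[c_star], 1e-300, None))
        log_delta = np.log(np.clip(deltas[c_star], 1e-300, None))
        if method == "viterbi":
            path = viterbi(logB, log_gamma, log_delta)
        elif method == "smoothing":
            _, gam, _ = forward_backward(bmat, model.tpms[c_star], deltas[c_star])
            path = gam.argmax(axis=1)
        else:
            raise ValueError("method must be 'viterbi' or 'smoothing'")
        paths.append(np.asarray(path))
    return paths, ctx_post


def name_states(model: MixedHMM) -> list[str]:
    """Map state indices to behavioral names.

    Nonfeeding is the state with the lowest buzz-presence probability; of
    the rest, bottom feeding has the higher mean of the relative-buzz-depth
    beta (buzzes concentrated near the maximum depth), pelagic feeding is
    the remainder. With fewer than three states the leftover names are
    assigned by the same ordering.
    """
    K = model.K
    names = [""] * K
    order = list(np.argsort(model.bern_p))
    nonfeed = order[0]
    names[nonfeed] = "nonfeeding"
    rest = [k for k in range(K) if k != nonfeed]
    rel_mean = model.beta_a[:, 0] / (model.beta_a[:, 0] + model.beta_b[:, 0])
    rest.sort(key=lambda k: rel_mean[k])
    labels = ["pelagic", "bottom"]
    extra = 0
    for idx, k in enumerate(rest):
        if idx < len(labels):
            names[k] = labels[idx] if len(rest) >= 2 else "feeding"
        else:
            extra += 1
            names[k] = f"feeding_{extra}"
    return names
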
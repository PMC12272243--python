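"""Hidden Markov model with zero-mean multivariate-Gaussian states.

Applied to time-delay-embedded data (the "TDE-HMM"), each state's
covariance matrix encodes a frequency-resolved functional network, and
the mutual-exclusivity assumption — exactly one state active per sample —
yields a hard temporal parcellation of the recording into network
regimes.  The observation mean is fixed at zero (the data are
standardised), so states differ only in covariance.

Inference is exact expectation-maximisation (Baum-Welch) with the
forward-backward recursions in scaled form.  Model selection over random
initialisations keeps the run with the lowest final loss (negative
log-likelihood per sample): a set of seeded short runs is trained first
and the best is continued to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = [
    "HmmModel",
    "StateTimeCourse",
    "fit_hmm",
    "viterbi_decode",
    "posterior",
    "fractional_occupancy",
]


class NumericalFailure(RuntimeError):
    pass


@dataclass
class HmmModel:
    covariances: np.ndarray  # [K x d x d]
    transition: np.ndarray  # [K x K], row stochastic
    initial: np.ndarray  # [K]
    loss_history: np.ndarray  # negative log-likelihood per sample, per epoch

    @property
    def n_states(self):
        return self.covariances.shape[0]


@dataclass
class StateTimeCourse:
    gamma: np.ndarray  # [time x K] posterior state probabilities
    viterbi: np.ndarray  # [time x K] one-hot most-probable path


def _log_emissions(y, covariances):
    """Log N(y_t; 0, C_k) for every sample and state."""
    T, d = y.shape
    K = covariances.shape[0]
    logb = np.empty((T, K))
    for k in range(K):
        L = cholesky(covariances[k], lower=True)
        half = solve_triangular(L, y.T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        logb[:, k] = -0.5 * (
            d * np.log(2.0 * np.pi) + logdet + np.einsum("dt,dt->t", half, half)
        )
    return logb


def _forward_backward(logb, transition, initial):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    T, K = logb.shape
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])  # per-row rescaled emissions

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * b[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise NumericalFailure(f"forward scaling failed at sample {t}")
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = transition * (alpha[:-1].T @ (b[1:] * beta[1:] / c[1:, None]))
    loglik = np.log(c).sum() + shift.sum()
    return gamma, xi_sum, loglik


def _m_step(y, gamma, xi_sum, reg):
    T, d = y.shape
    K = gamma.shape[1]
    weights = gamma.sum(axis=0)
    covs = np.empty((K, d, d))
    for k in range(K):
        wy = y * gamma[:, k : k + 1]
        C = (wy.T @ y) / weights[k]
        C = 0.5 * (C + C.T)
        C += reg * np.mean(np.diag(C)) * np.eye(d)
        covs[k] = C
    transition = xi_sum / xi_sum.sum(axis=1, keepdims=True)
    initial = gamma[0] / gamma[0].sum()
    return covs, transition, initial


def _init_params(y, n_states, rng, reg):
    T, d = y.shape
    K = n_states
    gamma0 = rng.dirichlet(np.ones(K), size=T)
    weights = gamma0.sum(axis=0)
    covs = np.empty((K, d, d))
    for k in range(K):
        wy = y * gamma0[:, k : k + 1]
        C = (wy.T @ y) / weights[k]
        C = 0.5 * (C + C.T)
        C += reg * np.mean(np.diag(C)) * np.eye(d)
        covs[k] = C
    transition = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.8)
    transition /= transition.sum(axis=1, keepdims=True)
    initial = np.full(K, 1.0 / K)
    return covs, transition, initial


def _run_em(y, covs, transition, initial, max_epochs, tol, reg):
    T = y.shape[0]
    losses = []
    prev = np.inf
    for epoch in range(max_epochs):
        logb = _log_emissions(y, covs)
        gamma, xi_sum, loglik = _forward_backward(logb, transition, initial)
        if not np.isfinite(loglik):
            raise NumericalFailure(f"non-finite objective at epoch {epoch}")
        loss = -loglik / T
        losses.append(loss)
        covs, transition, initial = _m_step(y, gamma, xi_sum, reg)
        if abs(prev - loss) < tol * max(abs(loss), 1.0):
            prev = loss
            break
        prev = loss
    return covs, transition, initial, np.array(losses)


def fit_hmm(
    y,
    n_states,
    n_init=10,
    n_init_epochs=3,
    max_epochs=40,
    tol=1e-6,
    reg=1e-6,
    seed=None,
):
    """Fit the HMM by EM with best-of-``n_init`` seeded initialisation.

    ``n_init`` short runs of ``n_init_epochs`` EM iterations are trained
    from independent random initialisations; the one with the lowest loss
    is continued for up to ``max_epochs`` further iterations (relative
    objective change below ``tol`` stops early).  Covariances are
    regularised by adding ``reg * mean-diagonal-variance * I`` at every
    M-step so they stay positive definite.

    Returns ``(HmmModel, StateTimeCourse)`` where the state time course
    holds both the smoothed posteriors (gamma) and the Viterbi path.
    """
    if hasattr(y, "y"):  # PreparedData
        y = y.y
    y = np.asarray(y, dtype=float)
    T, d = y.shape
    K = int(n_states)
    if K < 1 or K > T:
        raise ValueError(f"n_states must lie in [1, {T}]")

    if K == 1:
        C = (y.T @ y) / T
        C = 0.5 * (C + C.T)
        C += reg * np.mean(np.diag(C)) * np.eye(d)
        model = HmmModel(
            covariances=C[None],
            transition=np.ones((1, 1)),
            initial=np.ones(1),
            loss_history=np.array(
                [-_log_emissions(y, C[None]).sum() / T]
            ),
        )
        stc = StateTimeCourse(gamma=np.ones((T, 1)), viterbi=np.ones((T, 1)))
        return model, stc

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(int(n_init), 1))
    best = None
    for child in children:
        rng = np.random.default_rng(child)
        params = _init_params(y, K, rng, reg)
        covs, A, pi, losses = _run_em(
            y, *params, max_epochs=max(int(n_init_epochs), 1), tol=tol, reg=reg
        )
        if best is None or losses[-1] < best[3][-1]:
            best = (covs, A, pi, losses)

    covs, A, pi, init_losses = best
    covs, A, pi, losses = _run_em(
        y, covs, A, pi, max_epochs=max_epochs, tol=tol, reg=reg
    )
    model = HmmModel(
        covariances=covs,
        transition=A,
        initial=pi,
        loss_history=np.concatenate([init_losses, losses]),
    )
    gamma = posterior(model, y)
    vit = viterbi_decode(model, y)
    return model, StateTimeCourse(gamma=gamma, viterbi=vit)


def posterior(model: HmmModel, y):
    """Smoothed state probabilities (forward-backward) under the model."""
    y = np.asarray(y, dtype=float)
    if y.shape[1] != model.covariances.shape[1]:
        raise ValueError("dimensionality mismatch between model and data")
    logb = _log_emissions(y, model.covariances)
    gamma, _, _ = _forward_backward(logb, model.transition, model.initial)
    return gamma


def viterbi_decode(model: HmmModel, y):
    """Most probable joint state path, as a one-hot [time x K] matrix."""
    y = np.asarray(y, dtype=float)
    if y.shape[1] != model.covariances.shape[1]:
        raise ValueError("dimensionality mismatch between model and data")
    logb = _log_emissions(y, model.covariances)
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logpi = np.log(model.initial)
    delta = logpi + logb[0]
    back = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    onehot = np.zeros((T, K))
    onehot[np.arange(T), path] = 1.0
    return onehot


def fractional_occupancy(stc: StateTimeCourse):
    """Fraction of samples each state is active on the Viterbi path."""
    return stc.viterbi.mean(axis=0)
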
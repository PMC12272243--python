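"""DyNeMo: dynamic mixture of mode covariances with simplex mixing.

The generative model assumes the observation at time t is zero-mean
multivariate Gaussian with instantaneous covariance

    Sigma_t = sum_j alpha_jt D_j,      alpha_t = softmax(theta_t),

where the J mode covariances D_j are static network patterns and the
mixing coefficients alpha_t move on the probability simplex, so modes can
overlap in time — the key difference from an HMM's mutually exclusive
states.  The logits theta_t follow a learned first-order autoregressive
Gaussian sequence prior, theta_t ~ N(rho * theta_{t-1}, sigma_p^2 I).

Inference is stochastic variational: a mean-field Gaussian posterior
q(theta_t) = N(m_t, diag(s_t^2)) is optimised jointly with the mode
covariances (parameterised by their Cholesky factors, so they stay
positive definite) by maximising the evidence lower bound with the KL
term annealed from 0 to 1 over the first half of training.  Gradients
are analytic and the optimiser is Adam with a post-annealing learning
rate decay.  Training is warm-started from the best of ``n_init`` seeded
static mixture-model fits (zero-mean Gaussian mixture EM on a data
subset), which gives well-separated initial covariances; the model is
then selected and refined by the variational loss.  The reported mode
time course is the posterior mean logits passed through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky as sp_cholesky, solve_triangular

__all__ = [
    "DynemoConfig",
    "DynemoModel",
    "ModeTimeCourse",
    "fit_dynemo",
    "renormalise_alpha",
    "mode_state_overlap",
]


class NumericalFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class DynemoConfig:
    batch_size: int = 1024  # samples per gradient step
    max_epochs: int = 15
    n_init: int = 10  # seeded warm-start runs; best by loss is kept
    n_init_rounds: int = 8  # EM rounds per warm-start run
    n_init_samples: int = 8192  # subset length used for the warm starts
    kl_annealing_epochs: int = None  # default: half of max_epochs
    lr_logits: float = 0.2
    lr_covs: float = 0.02
    lr_scalars: float = 0.01
    lr_decay: float = 0.8  # per-epoch decay applied once KL annealing ends
    loss_eval_samples: int = 8192  # strided subset for per-epoch loss
    dtype: str = "float32"  # training precision for the heavy linear algebra


@dataclass
class DynemoModel:
    mode_covariances: np.ndarray  # [J x d x d]
    rho: float  # AR coefficient of the logit prior
    sigma_p: float  # innovation std of the logit prior
    posterior_logits: np.ndarray  # [time x J] posterior mean logits
    posterior_logstd: np.ndarray  # [time x J]
    loss_history: np.ndarray  # variational free energy per sample, per epoch

    @property
    def n_modes(self):
        return self.mode_covariances.shape[0]


@dataclass
class ModeTimeCourse:
    alpha: np.ndarray  # [time x J], rows on the simplex
    alpha_renorm: np.ndarray  # trace-weighted renormalisation


def _softmax(theta):
    z = theta - theta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    """Ascent Adam supporting sparse row updates for per-sample params."""

    def __init__(self, shapes_lrs, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lrs = {k: lr for k, (shape, lr) in shapes_lrs.items()}
        self.m = {k: np.zeros(shape) for k, (shape, _) in shapes_lrs.items()}
        self.v = {k: np.zeros(shape) for k, (shape, _) in shapes_lrs.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.step_count = {k: 0 for k in shapes_lrs}

    def step(self, key, param, grad, idx=None):
        self.step_count[key] += 1
        t = self.step_count[key]
        b1, b2 = self.b1, self.b2
        if idx is None:
            self.m[key] = b1 * self.m[key] + (1 - b1) * grad
            self.v[key] = b2 * self.v[key] + (1 - b2) * grad ** 2
            mhat = self.m[key] / (1 - b1 ** t)
            vhat = self.v[key] / (1 - b2 ** t)
            param += self.lrs[key] * mhat / (np.sqrt(vhat) + self.eps)
        else:
            self.m[key][idx] = b1 * self.m[key][idx] + (1 - b1) * grad
            self.v[key][idx] = b2 * self.v[key][idx] + (1 - b2) * grad ** 2
            mhat = self.m[key][idx] / (1 - b1 ** t)
            vhat = self.v[key][idx] / (1 - b2 ** t)
            param[idx] += self.lrs[key] * mhat / (np.sqrt(vhat) + self.eps)


class _State:
    """All trainable quantities of one DyNeMo run."""

    def __init__(self, n_samples, n_modes, d, config):
        dtype = np.dtype(config.dtype)
        self.L = np.zeros((n_modes, d, d), dtype=dtype)
        self.m = np.zeros((n_samples, n_modes))
        self.log_s = np.full((n_samples, n_modes), np.log(0.1))
        self.raw_rho = np.asarray(np.arctanh(0.95), dtype=float)
        self.log_sigma_p = np.asarray(np.log(0.2), dtype=float)
        self.opt = _Adam(
            {
                "m": ((n_samples, n_modes), config.lr_logits),
                "log_s": ((n_samples, n_modes), config.lr_logits),
                "L": (self.L.shape, config.lr_covs),
                "raw_rho": ((), config.lr_scalars),
                "log_sigma_p": ((), config.lr_scalars),
            }
        )

    @property
    def rho(self):
        return float(np.tanh(self.raw_rho))

    @property
    def sigma_p(self):
        return float(np.exp(self.log_sigma_p))

    def covariances(self):
        L = np.tril(self.L).astype(float)
        return np.einsum("jde,jfe->jdf", L, L)


def _zero_mean_gaussian_logpdf(y, covariances):
    """log N(y_t; 0, C_j) for each sample and component."""
    T, d = y.shape
    J = covariances.shape[0]
    out = np.empty((T, J))
    for j in range(J):
        Lc = sp_cholesky(covariances[j], lower=True)
        half = solve_triangular(Lc, y.T, lower=True)
        logdet = 2.0 * np.log(np.diag(Lc)).sum()
        out[:, j] = -0.5 * (
            d * np.log(2 * np.pi) + logdet + np.einsum("dt,dt->t", half, half)
        )
    return out


def _mixture_em(y, n_modes, rng, n_rounds, reg=1e-4):
    """Zero-mean Gaussian mixture EM warm start.

    Ignores temporal structure; returns component covariances, mixing
    proportions and the final per-sample average log-likelihood (the
    warm-start score).
    """
    T, d = y.shape
    W = min(T, max(2 * d, 500))
    covs = np.empty((n_modes, d, d))
    for j in range(n_modes):
        start = rng.integers(0, T - W + 1)
        seg = y[start : start + W]
        C = (seg.T @ seg) / W
        covs[j] = 0.5 * (C + C.T) + reg * np.mean(np.diag(C)) * np.eye(d)
    pi = np.full(n_modes, 1.0 / n_modes)
    score = -np.inf
    for _ in range(n_rounds):
        logp = _zero_mean_gaussian_logpdf(y, covs) + np.log(pi)[None]
        shift = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - shift)
        norm = w.sum(axis=1, keepdims=True)
        score = float((np.log(norm[:, 0]) + shift[:, 0]).mean())
        w /= norm
        wsum = w.sum(axis=0)
        pi = np.clip(wsum / T, 1e-6, None)
        pi /= pi.sum()
        for j in range(n_modes):
            C = ((y * w[:, j : j + 1]).T @ y) / max(wsum[j], 1e-8)
            covs[j] = 0.5 * (C + C.T) + reg * np.mean(np.diag(C)) * np.eye(d)
    return covs, pi, score


def _grad_step(y_b, theta, D, dtype):
    """Likelihood gradients for one batch (no log-det needed).

    Returns (alpha, d/d alpha [B x J], mode-accumulated d/d D [J x d x d]).
    """
    B, d = y_b.shape
    alpha = _softmax(theta)
    Sigma = np.einsum("bj,jde->bde", alpha.astype(dtype), D)
    jitter = 1e-6 * np.einsum("bdd->b", Sigma) / d
    Sigma[:, np.arange(d), np.arange(d)] += jitter[:, None]
    inv = np.linalg.inv(Sigma)
    v = np.einsum("bde,be->bd", inv, y_b)
    if not np.all(np.isfinite(v)):
        raise NumericalFailure("divergent likelihood gradients")
    # dloglik / dSigma = 0.5 (v v^T - Sigma^{-1})
    G = 0.5 * (v[:, :, None] * v[:, None, :] - inv)
    g_alpha = np.einsum("bde,jde->bj", G, D).astype(float)
    G_mode = np.einsum("bj,bde->jde", alpha.astype(dtype), G)
    return alpha, g_alpha, G_mode


def _mean_loglik(y_b, theta, D, dtype):
    """Mean Gaussian log-likelihood of a batch (slogdet + solve path)."""
    B, d = y_b.shape
    alpha = _softmax(theta)
    Sigma = np.einsum("bj,jde->bde", alpha.astype(dtype), D)
    jitter = 1e-6 * np.einsum("bdd->b", Sigma) / d
    Sigma[:, np.arange(d), np.arange(d)] += jitter[:, None]
    sign, logdet = np.linalg.slogdet(Sigma)
    if np.any(sign <= 0):
        raise NumericalFailure("instantaneous covariance not PD")
    sol = np.linalg.solve(Sigma, y_b[:, :, None])[:, :, 0]
    quad = np.einsum("bd,bd->b", y_b, sol)
    ll = -0.5 * (d * np.log(2 * np.pi) + logdet.astype(float) + quad)
    return float(ll.mean())


def _kl_terms(m, log_s, rho, sigma_p):
    """KL of the mean-field posterior from the AR(1) logit prior.

    The prior for t = 0 is N(0, 1); for t >= 1 it is
    N(rho * m_{t-1}, sigma_p^2), conditioning on the posterior mean of the
    previous step (structured approximation).
    Returns (kl_total, dm, dlog_s, dlog_sigma_p, drho).
    """
    s2 = np.exp(2.0 * log_s)
    r = m.copy()
    r[1:] = m[1:] - rho * m[:-1]
    sig2 = np.full(m.shape[0], sigma_p ** 2)
    sig2[0] = 1.0
    sig2 = sig2[:, None]
    kl = (
        0.5 * np.log(sig2) - log_s + (s2 + r ** 2) / (2.0 * sig2) - 0.5
    ).sum()
    dm = r / sig2
    dm[:-1] -= rho * r[1:] / sig2[1:]
    dlog_s = -1.0 + s2 / sig2
    dlog_sigma_p = (1.0 - (s2[1:] + r[1:] ** 2) / sig2[1:]).sum()
    drho = -(r[1:] * m[:-1] / sig2[1:]).sum()
    return float(kl), dm, dlog_s, dlog_sigma_p, drho


def _full_loss(y, state, config):
    """Free energy per sample at the posterior mean (KL at full weight).

    The likelihood term is evaluated on an evenly strided subsample of at
    most ``config.loss_eval_samples`` points and scaled up, keeping the
    per-epoch evaluation cheap while remaining comparable across runs.
    """
    T = y.shape[0]
    dtype = np.dtype(config.dtype)
    stride = max(1, int(np.ceil(T / config.loss_eval_samples)))
    idx = np.arange(0, T, stride)
    D = state.covariances().astype(dtype)
    total, n = 0.0, 0
    for start in range(0, idx.size, 4096):
        sub = idx[start : start + 4096]
        total += _mean_loglik(
            y[sub].astype(dtype), state.m[sub], D, dtype
        ) * sub.size
        n += sub.size
    mean_ll = total / n
    kl, *_ = _kl_terms(state.m, state.log_s, state.rho, state.sigma_p)
    return -(mean_ll - kl / T)


def _train(y, state, config, rng, n_epochs, beta_schedule):
    T, d = y.shape
    dtype = np.dtype(config.dtype)
    B = min(config.batch_size, T)
    n_batches = int(np.ceil(T / B))
    losses = []
    y_t = y.astype(dtype)
    for epoch in range(n_epochs):
        beta = beta_schedule(epoch)
        if epoch > 0 and beta >= 1.0 and beta_schedule(epoch - 1) >= 1.0:
            for k in state.opt.lrs:
                state.opt.lrs[k] *= config.lr_decay
        for b in rng.permutation(n_batches):
            idx = slice(b * B, min((b + 1) * B, T))
            nb = idx.stop - idx.start
            eps = rng.standard_normal((nb, state.L.shape[0]))
            s = np.exp(state.log_s[idx])
            theta = state.m[idx] + s * eps
            D = np.tril(state.L) @ np.transpose(np.tril(state.L), (0, 2, 1))
            alpha, g_alpha, G_mode = _grad_step(y_t[idx], theta, D, dtype)
            # softmax jacobian: dloglik/dtheta
            inner = (alpha * g_alpha).sum(axis=1, keepdims=True)
            g_theta = alpha * (g_alpha - inner)
            kl, dm_kl, dls_kl, dlsp, drho = _kl_terms(
                state.m, state.log_s, state.rho, state.sigma_p
            )
            # per-row parameters take their own (unscaled) ELBO terms
            g_m = g_theta - beta * dm_kl[idx]
            g_ls = g_theta * (s * eps) - beta * dls_kl[idx]
            state.opt.step("m", state.m, g_m, idx=idx)
            state.opt.step("log_s", state.log_s, g_ls, idx=idx)
            # shared parameters take full-data-scaled likelihood gradients
            scale = T / nb
            g_L = scale * 2.0 * np.einsum(
                "jde,jef->jdf", G_mode.astype(float), np.tril(state.L)
            )
            state.opt.step("L", state.L, np.tril(g_L).astype(state.L.dtype))
            g_rho = -beta * drho * (1.0 - np.tanh(state.raw_rho) ** 2)
            state.opt.step("raw_rho", state.raw_rho, np.asarray(g_rho))
            state.opt.step("log_sigma_p", state.log_sigma_p, np.asarray(-beta * dlsp))
        losses.append(_full_loss(y, state, config))
    return losses


def fit_dynemo(y, n_modes, config: DynemoConfig = None, seed=None):
    """Fit DyNeMo by stochastic variational inference.

    ``config.n_init`` seeded warm-start runs (zero-mean Gaussian mixture
    EM on the first ``n_init_samples`` samples) are fitted first and the
    best by warm-start likelihood initialises the mode covariances and
    mixing logits; full variational training then runs for ``max_epochs``
    epochs with the KL weight annealed linearly from 0 to 1 over the
    first ``kl_annealing_epochs`` epochs.  Returns
    ``(DynemoModel, ModeTimeCourse)``.
    """
    if hasattr(y, "y"):  # PreparedData
        y = y.y
    y = np.asarray(y, dtype=float)
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    config = config or DynemoConfig()
    T, d = y.shape
    anneal = config.kl_annealing_epochs
    if anneal is None:
        anneal = max(config.max_epochs // 2, 1)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(config.n_init, 1) + 1)

    y_init = y[: min(config.n_init_samples, T)]
    best = None
    for child in children[:-1]:
        rng = np.random.default_rng(child)
        covs, pi, score = _mixture_em(
            y_init, n_modes, rng, config.n_init_rounds
        )
        if best is None or score > best[2]:
            best = (covs, pi, score)

    covs, pi, _ = best
    rng = np.random.default_rng(children[-1])
    state = _State(T, n_modes, d, config)
    for j in range(n_modes):
        state.L[j] = np.linalg.cholesky(covs[j]).astype(state.L.dtype)
    # initial logits from the static mixture responsibilities
    logp = _zero_mean_gaussian_logpdf(y, covs) + np.log(pi)[None]
    logw = logp - logp.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    m0 = np.log(w + 1e-2)
    state.m = m0 - m0.mean(axis=1, keepdims=True)

    beta_schedule = lambda e: min(1.0, (e + 1) / anneal)  # noqa: E731
    losses = _train(y, state, config, rng, config.max_epochs, beta_schedule)

    covariances = state.covariances()
    model = DynemoModel(
        mode_covariances=covariances,
        rho=state.rho,
        sigma_p=state.sigma_p,
        posterior_logits=state.m.copy(),
        posterior_logstd=state.log_s.copy(),
        loss_history=np.asarray(losses),
    )
    alpha = _softmax(state.m)
    mtc = ModeTimeCourse(
        alpha=alpha, alpha_renorm=renormalise_alpha(alpha, covariances)
    )
    return model, mtc


def renormalise_alpha(alpha, covariances):
    """Trace-weighted mixing coefficients.

    alpha~_jt = alpha_jt tr(D_j) / sum_k alpha_kt tr(D_k): the share of
    the instantaneous covariance's total variance carried by each mode,
    which corrects for modes whose covariances differ in overall
    magnitude.
    """
    alpha = np.asarray(alpha, dtype=float)
    traces = np.trace(np.asarray(covariances), axis1=-2, axis2=-1)
    weighted = alpha * traces[None, :]
    denom = weighted.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("all-zero trace-weighted row in alpha")
    return weighted / denom


def mode_state_overlap(alpha_renorm, viterbi):
    """Mean (renormalised) mode coefficients during each HMM state, minus
    the all-time mean — how much each mode contributes to each state.

    Rows of the returned [K x J] matrix for states with zero occupancy
    are NaN.
    """
    alpha_renorm = np.asarray(alpha_renorm, dtype=float)
    viterbi = np.asarray(viterbi, dtype=float)
    if alpha_renorm.shape[0] != viterbi.shape[0]:
        raise ValueError("alpha and state path must have equal length")
    K = viterbi.shape[1]
    grand = alpha_renorm.mean(axis=0)
    out = np.full((K, alpha_renorm.shape[1]), np.nan)
    for k in range(K):
        mask = viterbi[:, k] > 0.5
        if mask.any():
            out[k] = alpha_renorm[mask].mean(axis=0) - grand
    return out
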
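"""Data preparation for dynamic-network modelling.

Time-delay embedding (TDE) augments each channel with lagged copies so
that the covariance of the embedded data encodes the auto- and
cross-correlation functions of the original channels out to the embedding
window — and hence their spectra and phase coupling.  PCA then reduces
the embedded dimensionality, and the final step standardises (z-scores)
each retained component.

Defaults follow the pipeline conventions: a lag half-width of 2 samples
with 120 components for the simulation study, and a half-width of 7 with
80 components for real source-space data at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ParcelData

__all__ = ["PrepConfig", "PreparedData", "time_delay_embed", "pca_reduce",
           "standardise", "prepare"]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PrepConfig:
    n_lags: int = 2  # symmetric lag half-width L
    n_components: int = 120
    standardise: bool = True

    def __post_init__(self):
        if self.n_lags < 0:
            raise ValueError("n_lags must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class PreparedData:
    """Embedded, PCA-reduced (and optionally standardised) data.

    ``y`` is [time' x components] with time' = time - 2 L.  ``pca_weights``
    maps embedded channels to components and allows back-projection of
    component-space covariances to embedded-channel space.  ``trim`` is
    the number of samples removed at *each* edge (= L); downstream stages
    use it to re-align inferred time courses with the original clock.
    """

    y: np.ndarray
    explained_variance_ratio: np.ndarray
    pca_weights: np.ndarray  # [embedded channels x components]
    mean: np.ndarray  # per-component mean removed by standardisation
    std: np.ndarray  # per-component std divided out
    trim: int
    fs: float = 0.0
    n_parcels: int = 0
    standardised: bool = False

    @property
    def n_samples(self):
        return self.y.shape[0]

    @property
    def n_components(self):
        return self.y.shape[1]


def time_delay_embed(x, n_lags):
    """Augment channels with lagged copies.

    Embedded channels are ordered parcel-major: all lags (-L..+L) of
    parcel 0, then parcel 1, and so on.  Row ``t`` of the output aligns
    lag 0 with original sample ``t + L``; the first and last L samples
    are trimmed.
    """
    if isinstance(x, ParcelData):
        x = x.x
    x = np.asarray(x, dtype=float)
    T, P = x.shape
    L = int(n_lags)
    if T <= 2 * L:
        raise InsufficientDataError(
            f"need more than {2 * L} samples for lag half-width {L}, got {T}"
        )
    if L == 0:
        return x.copy()
    W = 2 * L + 1
    out = np.empty((T - 2 * L, P * W), dtype=float)
    for p in range(P):
        for i in range(W):  # i = lag + L, lag in -L..+L
            out[:, p * W + i] = x[i : T - 2 * L + i, p]
    return out


def pca_reduce(y, n_components, fs=0.0, n_parcels=0, n_lags=0):
    """Project embedded data onto its leading principal components.

    Components are eigenvectors of the channel covariance sorted by
    descending eigenvalue; ``explained_variance_ratio`` holds each kept
    component's share of the total variance.
    """
    y = np.asarray(y, dtype=float)
    T, C = y.shape
    if not (1 <= n_components <= min(T, C)):
        raise ValueError(
            f"n_components must lie in [1, {min(T, C)}], got {n_components}"
        )
    mu = y.mean(axis=0)
    yc = y - mu
    cov = (yc.T @ yc) / (T - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    weights = evecs[:, :n_components]
    ratio = evals[:n_components] / evals.sum()
    proj = yc @ weights
    return PreparedData(
        y=proj,
        explained_variance_ratio=ratio,
        pca_weights=weights,
        mean=np.zeros(n_components),
        std=np.ones(n_components),
        trim=int(n_lags),
        fs=float(fs),
        n_parcels=int(n_parcels),
    )


def standardise(y):
    """Z-transform each column; returns ``(z, mean, std)``.

    Raises on zero-variance columns rather than dividing by zero.
    """
    y = np.asarray(y, dtype=float)
    mu = y.mean(axis=0)
    sd = y.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance columns: {bad}")
    return (y - mu) / sd, mu, sd


def prepare(data: ParcelData, config: PrepConfig = PrepConfig()):
    """TDE -> PCA -> (optional) standardisation, in that order."""
    emb = time_delay_embed(data.x, config.n_lags)
    prepped = pca_reduce(
        emb,
        config.n_components,
        fs=data.fs,
        n_parcels=data.n_parcels,
        n_lags=config.n_lags,
    )
    if config.standardise:
        z, mu, sd = standardise(prepped.y)
        prepped.y = z
        prepped.mean = mu
        prepped.std = sd
        prepped.standardised = True
    return prepped
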
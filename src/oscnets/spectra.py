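"""Post-hoc frequency-resolved network descriptions.

After a dynamic network model has been fitted, the inferred state or mode
time courses are combined with the *original* parcel data to give each
network a spectral fingerprint:

- HMM states: occupancy-weighted multitaper power/cross spectra.
- DyNeMo modes: GLM spectra — a sliding-window multitaper spectrogram is
  regressed on the (window-averaged, demeaned) mode time courses, and a
  mode's spectrum is its regression coefficient plus the intercept, i.e.
  the spectrum when that mode is fully active.
- Coherence: normalised cross-spectral magnitude per parcel pair.
- Power maps: band-averaged PSD per parcel (absolute or relative to the
  across-network mean).
- NNMF band selection: a two-component non-negative factorisation of
  stacked coherence spectra; the first (lowest-spectral-centroid)
  component is the canonical band profile for HMM maps.
- Edge thresholding: keep the top fraction of edges by absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .simulate import ParcelData

__all__ = [
    "SpectraResult",
    "multitaper_state_spectra",
    "glm_mode_spectra",
    "coherence",
    "band_coherence",
    "power_map",
    "nnmf_bands",
    "threshold_edges",
    "align_time_course",
]


@dataclass
class SpectraResult:
    """Per-entity (state or mode) spectra.

    ``psd``: [entities x parcels x freqs] in signal^2/Hz.
    ``csd``: [entities x parcels x parcels x freqs], complex, Hermitian in
    the parcel-pair sense.  ``undefined`` lists entities whose spectra
    could not be estimated (zero total weight); their values are NaN.
    """

    freqs: np.ndarray
    psd: np.ndarray
    csd: np.ndarray
    undefined: tuple = ()


def align_time_course(tc, trim, n_samples):
    """Re-align a model time course to the original data clock.

    Time-delay embedding trims ``trim`` samples at each edge; the trimmed
    edges are padded back by replicating the first/last row so that the
    time course has ``n_samples`` rows again.
    """
    tc = np.asarray(tc, dtype=float)
    if trim == 0:
        pad = tc
    else:
        pad = np.concatenate(
            [np.repeat(tc[:1], trim, axis=0), tc, np.repeat(tc[-1:], trim, axis=0)]
        )
    if pad.shape[0] != n_samples:
        raise ValueError(
            f"aligned length {pad.shape[0]} != expected {n_samples}"
        )
    return pad


def _taper_bank(n_win, fs, bandwidth):
    """DPSS tapers for a half-bandwidth product NW = n_win*bw/(2*fs)."""
    nw = n_win * bandwidth / (2.0 * fs)
    n_tapers = max(int(2 * nw) - 1, 1)
    tapers = dpss(n_win, nw, Kmax=n_tapers)
    return np.atleast_2d(tapers)


def _window_cross_spectra(seg, tapers, fs):
    """Multitaper cross-spectra of one [n_win x parcels] segment.

    Returns [parcels x parcels x freqs(full rfft grid)] with density
    scaling (signal^2/Hz, one-sided except DC/Nyquist).
    """
    n_win = seg.shape[0]
    # taper, FFT: [tapers x freqs x parcels]
    tapered = tapers[:, :, None] * seg[None, :, :]
    fx = np.fft.rfft(tapered, axis=1)
    csd = np.einsum("kfp,kfq->pqf", fx, np.conj(fx)) / tapers.shape[0]
    scale = 2.0 / fs  # tapers have unit energy; one-sided density
    csd = csd * scale
    csd[..., 0] /= 2.0
    if n_win % 2 == 0:
        csd[..., -1] /= 2.0
    return csd


def multitaper_state_spectra(
    x,
    gamma,
    window_s=2.0,
    bandwidth=4.0,
    frange=(1.0, 45.0),
    keep_csd=True,
):
    """Occupancy-weighted multitaper spectra per HMM state.

    The data are cut into non-overlapping ``window_s``-second windows;
    DPSS-tapered cross-spectra are computed per window and averaged with
    weights equal to each state's mean posterior probability in that
    window, normalised by the state's total weight.  States with zero
    total weight are flagged in ``undefined`` and returned as NaN.

    ``gamma`` must be aligned to ``x`` (see :func:`align_time_course`).
    """
    if isinstance(x, ParcelData):
        fs, xmat = x.fs, x.x
    else:
        raise TypeError("x must be ParcelData")
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] != xmat.shape[0]:
        raise ValueError("gamma must be aligned to the data in time")
    T, P = xmat.shape
    K = gamma.shape[1]
    n_win = int(round(window_s * fs))
    n_windows = T // n_win
    if n_windows < 1:
        raise ValueError("data shorter than one window")
    tapers = _taper_bank(n_win, fs, bandwidth)
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    fmask = (freqs >= frange[0]) & (freqs <= frange[1])

    num = np.zeros((K, P, P, fmask.sum()), dtype=complex)
    wsum = np.zeros(K)
    for w in range(n_windows):
        sl = slice(w * n_win, (w + 1) * n_win)
        seg = xmat[sl] - xmat[sl].mean(axis=0)
        csd_w = _window_cross_spectra(seg, tapers, fs)[..., fmask]
        gbar = gamma[sl].mean(axis=0)
        num += gbar[:, None, None, None] * csd_w[None]
        wsum += gbar

    undefined = tuple(np.flatnonzero(wsum <= 1e-12).tolist())
    if undefined:
        warnings.warn(
            f"states {list(undefined)} have zero occupancy; spectra undefined"
        )
    csd = np.full_like(num, np.nan)
    ok = wsum > 1e-12
    csd[ok] = num[ok] / wsum[ok, None, None, None]
    psd = np.real(np.einsum("kppf->kpf", csd))
    if not keep_csd:
        csd = None
    return SpectraResult(
        freqs=freqs[fmask], psd=psd, csd=csd, undefined=undefined
    )


def glm_mode_spectra(
    x,
    alpha,
    window_s=2.0,
    bandwidth=4.0,
    frange=(1.0, 45.0),
    step_s=None,
    keep_csd=True,
):
    """GLM spectra per DyNeMo mode.

    A sliding-window multitaper spectrogram (step ``step_s``, default half
    a window) is regressed, per frequency and parcel(-pair), on the
    demeaned window-mean mode coefficients plus an intercept.  The mode-j
    spectrum is coefficient_j + intercept: the model's spectrum when mode
    j is fully active relative to its average contribution.

    A warning is raised and the pseudo-inverse used if the mode
    regressors are nearly collinear.
    """
    if not isinstance(x, ParcelData):
        raise TypeError("x must be ParcelData")
    fs, xmat = x.fs, x.x
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape[0] != xmat.shape[0]:
        raise ValueError("alpha must be aligned to the data in time")
    T, P = xmat.shape
    J = alpha.shape[1]
    n_win = int(round(window_s * fs))
    step = n_win // 2 if step_s is None else int(round(step_s * fs))
    starts = np.arange(0, T - n_win + 1, step)
    if starts.size <= J:
        raise ValueError("not enough windows for the regression")
    tapers = _taper_bank(n_win, fs, bandwidth)
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    fmask = (freqs >= frange[0]) & (freqs <= frange[1])
    F = int(fmask.sum())

    # design: demeaned window-mean alphas + intercept.  Simplex-constrained
    # coefficients make the demeaned columns sum to zero, so the design has
    # rank J, not J+1; the pseudo-inverse gives the minimum-norm solution,
    # which shares the redundant direction equally across modes.  Warn only
    # if the rank drops below J (modes collinear beyond that constraint).
    abar = np.stack([alpha[s : s + n_win].mean(axis=0) for s in starts])
    design = np.column_stack([abar - abar.mean(axis=0), np.ones(len(starts))])
    rank = np.linalg.matrix_rank(design)
    if rank < J:
        warnings.warn(
            f"mode regressors are collinear (rank {rank} < {J} modes); "
            "using the minimum-norm pseudo-inverse solution"
        )
    pinv = np.linalg.pinv(design)  # [(J+1) x windows]

    # stream windows, accumulating pinv @ spectrogram
    coef = np.zeros((J + 1, P, P, F), dtype=complex)
    for i, s in enumerate(starts):
        seg = xmat[s : s + n_win] - xmat[s : s + n_win].mean(axis=0)
        csd_w = _window_cross_spectra(seg, tapers, fs)[..., fmask]
        coef += pinv[:, i][:, None, None, None] * csd_w[None]

    csd = coef[:J] + coef[J][None]  # coefficient + intercept
    psd = np.real(np.einsum("jppf->jpf", csd))
    if not keep_csd:
        csd = None
    return SpectraResult(freqs=freqs[fmask], psd=psd, csd=csd)


def coherence(spectra: SpectraResult):
    """Coherence spectra C_xy(f) = |P_xy| / sqrt(P_xx P_yy).

    Returns [entities x parcels x parcels x freqs] with zero diagonal.
    Entries with a non-positive PSD denominator are NaN.
    """
    if spectra.csd is None:
        raise ValueError("spectra were computed without cross-spectra")
    psd = spectra.psd
    denom = np.sqrt(
        np.abs(psd[:, :, None, :] * psd[:, None, :, :])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(spectra.csd) / denom
    coh = np.where(denom > 0, coh, np.nan)
    idx = np.arange(psd.shape[1])
    coh[:, idx, idx, :] = 0.0
    return coh


def band_coherence(coh, freqs, weights):
    """Average coherence over a band (mask or non-negative profile)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[-1] != len(freqs):
        raise ValueError("weights must match the frequency grid")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive mass")
    return np.tensordot(coh, weights, axes=([-1], [0])) / wsum


def power_map(spectra: SpectraResult, weights=None, relative=False):
    """Band-averaged power per parcel for each state/mode.

    ``weights`` is a non-negative spectral profile (or band mask) over the
    frequency grid; the default is uniform over the whole grid.  With
    ``relative=True`` the across-entity mean map is subtracted.
    """
    psd = spectra.psd
    if weights is None:
        weights = np.ones(len(spectra.freqs))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if weights.sum() == 0:
        raise ValueError("weights must not be all zero")
    maps = np.tensordot(psd, weights, axes=([-1], [0])) / weights.sum()
    if relative:
        maps = maps - maps.mean(axis=0, keepdims=True)
    return maps


def nnmf_bands(coherence_spectra, n_components=2, seed=None, n_init=10):
    """Data-driven spectral bands by non-negative matrix factorisation.

    ``coherence_spectra`` is a non-negative [observations x freqs] stack
    (e.g. subject-and-state coherence spectra).  Factorised with
    multiplicative updates from ``n_init`` seeded restarts; the best
    reconstruction is kept and components are sorted by ascending
    spectral centroid, so the first component is the canonical
    low-frequency band profile.
    """
    from sklearn.decomposition import NMF

    X = np.asarray(coherence_spectra, dtype=float)
    if np.any(X < 0):
        raise ValueError("coherence spectra must be non-negative")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(n_init, 1)):
        rs = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        nmf = NMF(
            n_components=n_components,
            init="random",
            solver="mu",
            max_iter=1000,
            random_state=rs,
        )
        W = nmf.fit_transform(X)
        err = nmf.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, nmf.components_.copy())
    H = best[1]
    grid = np.arange(H.shape[1])
    centroids = (H * grid).sum(axis=1) / np.maximum(H.sum(axis=1), 1e-12)
    return H[np.argsort(centroids)]


def threshold_edges(values, top_fraction=0.02):
    """Binary mask keeping the strongest edges of a symmetric network.

    Retains the ``ceil(top_fraction * n_edges)`` upper-triangle edges of
    largest absolute value (ties broken deterministically by (row, col)
    lexicographic order); the mask is returned symmetric.
    """
    values = np.asarray(values, dtype=float)
    P = values.shape[0]
    if values.shape != (P, P):
        raise ValueError("values must be square")
    iu, ju = np.triu_indices(P, k=1)
    n_edges = iu.size
    n_keep = int(np.ceil(top_fraction * n_edges))
    n_keep = min(n_keep, n_edges)
    order = np.lexsort((ju, iu, -np.abs(values[iu, ju])))
    mask = np.zeros((P, P), dtype=bool)
    keep = order[:n_keep]
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    return mask
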
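"""Task-evoked analyses: epoching, network responses, Morlet TF maps.

Two complementary views of a task response:

- Network view: epoch the inferred state/mode time courses around events,
  baseline-correct, and average across trials.  Projecting the epoched
  responses through each network's power spectrum gives a model-derived
  time-frequency map.
- Conventional view: Morlet-wavelet time-frequency decomposition of the
  parcel data, split into the total (single-trial) response, the
  phase-locked evoked response (TF of the trial average), and the
  non-phase-locked induced response (their difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import ParcelData

log = logging.getLogger("oscnets")


def _round_half_away(x):
    """Round to the nearest integer, halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


__all__ = [
    "EpochedResponse",
    "TFResult",
    "epoch",
    "network_response",
    "morlet_tf",
    "baseline_correct",
    "baseline_correct_tf",
    "project_tf",
]


@dataclass
class EpochedResponse:
    """Trials cut around events.

    ``data``: [trials x time x channels]; ``times``: seconds relative to
    the event, one per epoch sample.
    """

    data: np.ndarray
    times: np.ndarray

    @property
    def n_trials(self):
        return self.data.shape[0]


@dataclass
class TFResult:
    """Time-frequency power, [freqs x times(decimated) x channels]."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray


def epoch(x, events, fs, tmin=-0.1, tmax=1.0):
    """Cut a continuous [time x channels] array into event-locked trials.

    The window covers ``[tmin, tmax)`` seconds relative to each event
    sample (inclusive start, exclusive end).  Events whose window falls
    outside the recording are dropped; at least one must survive.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    start_off = _round_half_away(tmin * fs)
    stop_off = _round_half_away(tmax * fs)
    if stop_off <= start_off:
        raise ValueError("tmax must exceed tmin")
    trials = []
    dropped = 0
    for ev in np.asarray(events, dtype=int):
        a, b = ev + start_off, ev + stop_off
        if a < 0 or b > T:
            dropped += 1
            continue
        trials.append(x[a:b])
    if dropped:
        log.info("dropped %d events whose epoch window leaves the recording", dropped)
    if not trials:
        raise ValueError("no events with a complete epoch window")
    times = (np.arange(start_off, stop_off)) / fs
    return EpochedResponse(data=np.stack(trials), times=times)


def baseline_correct(ep: EpochedResponse, window=(-0.1, 0.0)):
    """Subtract each trial/channel's mean over the baseline window."""
    mask = (ep.times >= window[0]) & (ep.times < window[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = ep.data[:, mask].mean(axis=1, keepdims=True)
    return EpochedResponse(data=ep.data - base, times=ep.times)


def network_response(tc, events, fs, tmin=-0.1, tmax=1.0, baseline=(-0.1, 0.0)):
    """Trial-averaged, baseline-corrected network time course per event.

    ``tc`` is an aligned [time x networks] state/mode time course.
    Returns (epoched, average) where ``average`` is [time x networks].
    """
    ep = epoch(tc, events, fs, tmin=tmin, tmax=tmax)
    ep = baseline_correct(ep, window=baseline)
    return ep, ep.data.mean(axis=0)


def morlet_tf(
    ep: EpochedResponse,
    fs,
    freqs=None,
    n_cycles=4,
    decim=3,
    mode="full",
):
    """Morlet-wavelet time-frequency power of epoched data.

    ``mode`` selects the quantity (all are wavelet-amplitude maps, the
    magnitude of the complex transform, with shape [freqs x times x
    channels]):

    - ``"full"``: trial-average of single-trial amplitude (total response).
    - ``"evoked"``: amplitude of the trial-averaged signal (phase-locked
      part).
    - ``"induced"``: full minus evoked (non-phase-locked part), so
      full - evoked - induced = 0 exactly.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = np.arange(6.0, 30.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)

    if np.any(freqs >= fs / 2):
        raise ValueError("freqs must lie below the Nyquist frequency")

    def _amplitude(data):  # data: [trials x channels x time]
        w = tfr_array_morlet(
            data,
            sfreq=fs,
            freqs=freqs,
            n_cycles=n_cycles,
            decim=decim,
            output="complex",
            verbose="error",
        )
        return np.abs(w)  # [trials x channels x freqs x time]

    data = np.transpose(ep.data, (0, 2, 1))  # trials x channels x time
    if mode == "full":
        power = _amplitude(data).mean(axis=0)
    elif mode == "evoked":
        power = _amplitude(data.mean(axis=0, keepdims=True))[0]
    elif mode == "induced":
        power = _amplitude(data).mean(axis=0) - _amplitude(
            data.mean(axis=0, keepdims=True)
        )[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    power = np.transpose(power, (1, 2, 0))  # freqs x times x channels
    times = ep.times[::decim][: power.shape[1]]
    return TFResult(power=power, freqs=freqs, times=times)


def baseline_correct_tf(tf: TFResult, window=(-0.1, 0.0)):
    """Subtract the baseline-window mean per frequency and channel."""
    mask = (tf.times >= window[0]) & (tf.times < window[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = tf.power[:, mask].mean(axis=1, keepdims=True)
    return TFResult(power=tf.power - base, freqs=tf.freqs, times=tf.times)


def project_tf(response, psd, freqs, times=None):
    """Model-derived time-frequency map from network responses.

    ``response`` is a trial-averaged [time x networks] network response
    and ``psd`` the corresponding [networks x freqs] power spectra (e.g.
    parcel-averaged state spectra); the projection

        P(f, t) = sum_k response_k(t) * psd_k(f)

    shows when and at which frequencies each network's spectral content
    waxes and wanes around the event.
    """
    response = np.asarray(response, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if response.shape[1] != psd.shape[0]:
        raise ValueError("response and psd disagree on the number of networks")
    if psd.shape[1] != len(freqs):
        raise ValueError("psd and freqs disagree on the frequency grid")
    power = psd.T @ response.T  # freqs x time
    return TFResult(
        power=power[:, :, None],
        freqs=np.asarray(freqs, dtype=float),
        times=np.arange(response.shape[0]) if times is None else np.asarray(times),
    )
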
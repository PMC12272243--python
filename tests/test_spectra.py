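import numpy as np
import pytest

from oscnets.simulate import ParcelData
from oscnets.spectra import (
    align_time_course,
    band_coherence,
    coherence,
    glm_mode_spectra,
    multitaper_state_spectra,
    nnmf_bands,
    power_map,
    threshold_edges,
)


def _sine_data(rng, T=10000, fs=250.0, f=10.0, n=3):
    t = np.arange(T) / fs
    x = np.stack(
        [np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for _ in range(n)],
        axis=1,
    )
    x = x + 0.1 * rng.standard_normal((T, n))
    return ParcelData(x=x, fs=fs)


def test_psd_peaks_at_signal_frequency(rng):
    data = _sine_data(rng, f=10.0)
    gamma = np.ones((data.x.shape[0], 1))
    res = multitaper_state_spectra(data, gamma)
    peak = res.freqs[np.argmax(res.psd[0, 0])]
    assert abs(peak - 10.0) <= 0.5


def test_parseval_band_limited(rng):
    data = _sine_data(rng, f=10.0, n=1)
    gamma = np.ones((data.x.shape[0], 1))
    res = multitaper_state_spectra(data, gamma, frange=(0.0, 125.0))
    df = res.freqs[1] - res.freqs[0]
    integral = res.psd[0, 0].sum() * df
    var = data.x[:, 0].var()
    assert abs(integral - var) / var < 0.1


def test_coherence_properties(rng):
    t = np.arange(8000) / 250.0
    base = np.sin(2 * np.pi * 10 * t)
    x = np.stack(
        [
            base + 0.2 * rng.standard_normal(len(t)),
            np.roll(base, 3) + 0.2 * rng.standard_normal(len(t)),
            rng.standard_normal(len(t)),
        ],
        axis=1,
    )
    data = ParcelData(x=x, fs=250.0)
    gamma = np.ones((len(t), 1))
    res = multitaper_state_spectra(data, gamma)
    coh = coherence(res)
    i10 = np.argmin(np.abs(res.freqs - 10.0))
    # coupled pair coherent at 10 Hz, independent channel not
    assert coh[0, 0, 1, i10] > 0.8
    assert coh[0, 0, 2, i10] < 0.5
    assert np.all((coh[np.isfinite(coh)] >= 0) & (coh[np.isfinite(coh)] <= 1 + 1e-9))

    # invariant to per-channel rescaling
    data3 = ParcelData(x=x * np.array([3.0, 1.0, 1.0]), fs=250.0)
    coh3 = coherence(multitaper_state_spectra(data3, gamma))
    np.testing.assert_allclose(coh, coh3, atol=1e-9)


def test_occupancy_weighting_separates_states(rng):
    # 10 Hz in the first half, 20 Hz in the second; two "states"
    T, fs = 10000, 250.0
    t = np.arange(T) / fs
    x = np.where(
        (t < T / fs / 2)[:, None],
        np.sin(2 * np.pi * 10 * t)[:, None],
        np.sin(2 * np.pi * 20 * t)[:, None],
    ) + 0.05 * rng.standard_normal((T, 1))
    data = ParcelData(x=x, fs=fs)
    gamma = np.zeros((T, 2))
    gamma[: T // 2, 0] = 1.0
    gamma[T // 2 :, 1] = 1.0
    res = multitaper_state_spectra(data, gamma)
    assert abs(res.freqs[np.argmax(res.psd[0, 0])] - 10.0) <= 0.5
    assert abs(res.freqs[np.argmax(res.psd[1, 0])] - 20.0) <= 0.5


def test_zero_occupancy_state_flagged(rng):
    data = _sine_data(rng, T=2000, n=1)
    gamma = np.column_stack([np.ones(2000), np.zeros(2000)])
    with pytest.warns(UserWarning):
        res = multitaper_state_spectra(data, gamma)
    assert res.undefined == (1,)
    assert np.all(np.isnan(res.psd[1]))


def test_glm_mode_spectra_recovers_modulated_frequency(rng):
    # mode coefficient modulates 10 Hz amplitude; constant 20 Hz background
    T, fs = 20000, 250.0
    t = np.arange(T) / fs
    alpha1 = 0.5 + 0.5 * np.sin(2 * np.pi * t / 8.0)  # slow modulation
    x = (
        alpha1 * np.sin(2 * np.pi * 10 * t)
        + 0.5 * np.sin(2 * np.pi * 20 * t)
        + 0.1 * rng.standard_normal(T)
    )[:, None]
    data = ParcelData(x=x, fs=fs)
    alpha = np.column_stack([alpha1, 1.0 - alpha1])
    res = glm_mode_spectra(data, alpha)
    peak = res.freqs[np.argmax(res.psd[0, 0])]
    assert abs(peak - 10.0) <= 0.5


def test_power_map_and_relative(rng):
    data = _sine_data(rng, n=2)
    gamma = np.ones((data.x.shape[0], 1))
    res = multitaper_state_spectra(data, gamma)
    maps = power_map(res)
    assert maps.shape == (1, 2) and np.all(maps > 0)
    rel = power_map(res, relative=True)
    np.testing.assert_allclose(rel.mean(axis=0), 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        power_map(res, weights=np.zeros(len(res.freqs)))


def test_band_coherence_weighting(rng):
    data = _sine_data(rng, n=2)
    gamma = np.ones((data.x.shape[0], 1))
    res = multitaper_state_spectra(data, gamma)
    coh = coherence(res)
    mask = (res.freqs >= 8) & (res.freqs <= 12)
    bc = band_coherence(coh, res.freqs, mask.astype(float))
    assert bc.shape == coh.shape[:-1]
    np.testing.assert_allclose(
        bc[0, 0, 1], coh[0, 0, 1, mask].mean(), atol=1e-12
    )


def test_nnmf_bands_orders_by_centroid(rng):
    freqs = np.arange(45)
    low = np.exp(-0.5 * ((freqs - 10) / 2.0) ** 2)
    high = np.exp(-0.5 * ((freqs - 30) / 2.0) ** 2)
    w = rng.uniform(0.2, 1.0, size=(40, 2))
    X = w @ np.stack([low, high]) + 0.01 * rng.uniform(size=(40, 45))
    comps = nnmf_bands(X, n_components=2, seed=0)
    # first component has the lower spectral centroid
    centroid = lambda h: (h * freqs).sum() / h.sum()
    assert centroid(comps[0]) < centroid(comps[1])
    assert abs(np.argmax(comps[0]) - 10) <= 2
    assert abs(np.argmax(comps[1]) - 30) <= 2


def test_threshold_edges_count_and_ties():
    P = 38
    vals = np.zeros((P, P))
    iu, ju = np.triu_indices(P, k=1)
    vals[iu, ju] = np.linspace(1, 0, iu.size)
    vals = vals + vals.T
    mask = threshold_edges(vals, top_fraction=0.02)
    n_expected = int(np.ceil(0.02 * iu.size))  # 15 of 703
    assert np.triu(mask, 1).sum() == n_expected == 15
    assert np.array_equal(mask, mask.T)
    # deterministic under ties
    tied = np.ones((5, 5)) - np.eye(5)
    m1 = threshold_edges(tied, 0.2)
    m2 = threshold_edges(tied, 0.2)
    np.testing.assert_array_equal(m1, m2)
    assert np.triu(m1, 1).sum() == 2  # ceil(0.2 * 10)


def test_align_time_course():
    tc = np.arange(10.0).reshape(5, 2)
    out = align_time_course(tc, 2, 9)
    assert out.shape == (9, 2)
    np.testing.assert_array_equal(out[0], tc[0])
    np.testing.assert_array_equal(out[-1], tc[-1])
    np.testing.assert_array_equal(out[2:7], tc)
    with pytest.raises(ValueError):
        align_time_course(tc, 1, 9)
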
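import numpy as np
import pytest

from oscnets.taskresp import (
    EpochedResponse,
    baseline_correct,
    baseline_correct_tf,
    epoch,
    morlet_tf,
    network_response,
    project_tf,
)


def test_epoch_window_arithmetic():
    x = np.arange(2000.0)[:, None]
    ep = epoch(x, [1000], fs=250.0, tmin=-0.1, tmax=1.0)
    assert ep.data.shape == (1, 275, 1)
    assert ep.data[0, 0, 0] == 975.0
    assert ep.data[0, -1, 0] == 1249.0
    assert ep.times[0] == pytest.approx(-0.1)


def test_epoch_drops_out_of_bounds_and_errors_when_empty():
    x = np.zeros((500, 1))
    ep = epoch(x, [10, 250], fs=250.0)
    assert ep.n_trials == 1  # the event at 10 cannot fit tmin=-0.1
    with pytest.raises(ValueError):
        epoch(x, [10], fs=250.0)


def test_epoch_count_matches_in_bounds_events(rng):
    x = rng.standard_normal((5000, 2))
    events = [500, 1500, 2500, 3500]
    ep = epoch(x, events, fs=250.0)
    assert ep.n_trials == len(events)


def test_baseline_correction_zero_mean():
    rng = np.random.default_rng(0)
    ep = epoch(rng.standard_normal((3000, 2)) + 5.0, [1000, 1500], fs=250.0)
    bc = baseline_correct(ep)
    mask = (bc.times >= -0.1) & (bc.times < 0.0)
    np.testing.assert_allclose(
        bc.data[:, mask].mean(axis=1), 0.0, atol=1e-9
    )


def test_network_response_peak_location():
    # one-hot state switching on 200 ms (50 samples) after each event
    T, fs = 20000, 250.0
    events = np.arange(1000, 19000, 1000)
    tc = np.zeros((T, 2))
    for ev in events:
        tc[ev + 50 : ev + 60, 0] = 1.0
    ep, avg = network_response(tc, events, fs)
    peak_t = ep.times[np.argmax(avg[:, 0])]
    assert abs(peak_t - 0.2) <= 1.0 / fs + 1e-9


def test_constant_time_course_gives_zero_response():
    tc = np.full((5000, 3), 0.25)
    _, avg = network_response(tc, [1000, 2000, 3000], 250.0)
    np.testing.assert_allclose(avg, 0.0, atol=1e-12)


def _sine_trials(rng, n_trials=120, phase_locked=True, f=10.0, fs=250.0):
    n = 275
    t = np.arange(-25, 250) / fs
    trials = []
    for _ in range(n_trials):
        ph = 0.0 if phase_locked else rng.uniform(0, 2 * np.pi)
        trials.append(np.sin(2 * np.pi * f * t + ph)[:, None])
    return EpochedResponse(data=np.array(trials), times=t)


def test_morlet_phase_locked_mostly_evoked(rng):
    ep = _sine_trials(rng, phase_locked=True)
    full = morlet_tf(ep, 250.0, mode="full")
    induced = morlet_tf(ep, 250.0, mode="induced")
    assert np.max(np.abs(induced.power)) < 0.05 * np.max(full.power)


def test_morlet_phase_random_mostly_induced(rng):
    ep = _sine_trials(rng, n_trials=400, phase_locked=False)
    full = morlet_tf(ep, 250.0, mode="full")
    evoked = morlet_tf(ep, 250.0, mode="evoked")
    i10 = np.argmin(np.abs(full.freqs - 10.0))
    assert evoked.power[i10].max() < 0.15 * full.power[i10].max()


def test_morlet_identity_full_minus_evoked(rng):
    ep = _sine_trials(rng, n_trials=10, phase_locked=False)
    full = morlet_tf(ep, 250.0, mode="full")
    evoked = morlet_tf(ep, 250.0, mode="evoked")
    induced = morlet_tf(ep, 250.0, mode="induced")
    np.testing.assert_allclose(
        full.power - evoked.power - induced.power, 0.0, atol=1e-10
    )


def test_morlet_peak_frequency(rng):
    ep = _sine_trials(rng, n_trials=5, f=20.0)
    full = morlet_tf(ep, 250.0, mode="full")
    centre = full.power[:, full.power.shape[1] // 2, 0]
    assert abs(full.freqs[np.argmax(centre)] - 20.0) <= 0.5


def test_morlet_rejects_frequencies_above_nyquist(rng):
    ep = _sine_trials(rng, n_trials=3)
    with pytest.raises(ValueError):
        morlet_tf(ep, 250.0, freqs=np.array([100.0, 130.0]))


def test_baseline_correct_tf_idempotent(rng):
    ep = _sine_trials(rng, n_trials=5)
    tf = morlet_tf(ep, 250.0)
    c1 = baseline_correct_tf(tf)
    c2 = baseline_correct_tf(c1)
    mask = (c1.times >= -0.1) & (c1.times < 0.0)
    np.testing.assert_allclose(c1.power[:, mask].mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(c1.power, c2.power, atol=1e-12)


def test_project_tf_delta_response():
    psd = np.array([[1.0, 2.0, 3.0]])
    response = np.zeros((10, 1))
    response[4, 0] = 1.0
    proj = project_tf(response, psd, freqs=[5.0, 10.0, 15.0])
    np.testing.assert_allclose(proj.power[:, 4, 0], psd[0])
    assert np.all(proj.power[:, [0, 1, 2, 3, 5, 6, 7, 8, 9]] == 0)
    with pytest.raises(ValueError):
        project_tf(response, np.vstack([psd, psd]), freqs=[5.0, 10.0, 15.0])
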
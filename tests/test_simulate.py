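import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscnets.simulate import (
    DegeneracyError,
    NetworkSpec,
    SimulationConfig,
    default_networks,
    sample_burst_time_course,
    simulate_parcels,
    symmetric_orthogonalise,
)


def test_default_networks_match_design():
    nets = default_networks()
    assert [n.freq for n in nets] == [10.0, 20.0]
    assert len(nets[0].parcels) == 6
    assert len(nets[1].parcels) == 4
    assert set(nets[0].parcels).isdisjoint(nets[1].parcels)


def test_network_spec_validation():
    with pytest.raises(ValueError):
        NetworkSpec(name="bad", parcels=(), freq=10.0)
    with pytest.raises(ValueError):
        NetworkSpec(name="bad", parcels=(0,), freq=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_parcels=4, networks=(
            NetworkSpec(name="big", parcels=(0, 9), freq=10.0),
        ))


def test_simulation_shapes_and_determinism():
    cfg = SimulationConfig(n_samples=2000, seed=5)
    d1, t1 = simulate_parcels(cfg)
    d2, t2 = simulate_parcels(cfg)
    assert d1.x.shape == (2000, 38)
    assert t1.on.shape == (2000, 2)
    np.testing.assert_array_equal(d1.x, d2.x)
    np.testing.assert_array_equal(t1.on, t2.on)
    d3, _ = simulate_parcels(SimulationConfig(n_samples=2000, seed=6))
    assert not np.array_equal(d1.x, d3.x)


def test_burst_time_course_statistics():
    on = sample_burst_time_course(0.95, 200_000, seed=0)
    occ = on.mean()
    assert abs(occ - 0.5) < 0.02
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], on, [0]]))))[::2]
    # geometric dwell with continue-probability 0.95 has mean 20 samples
    assert abs(runs.mean() - 20.0) / 20.0 < 0.05


@settings(max_examples=10, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_burst_time_course_is_binary_and_deterministic(seed):
    a = sample_burst_time_course(0.9, 500, seed=seed)
    b = sample_burst_time_course(0.9, 500, seed=seed)
    assert set(np.unique(a)) <= {0, 1}
    np.testing.assert_array_equal(a, b)


def test_bursts_tile_the_indicator():
    _, truth = simulate_parcels(SimulationConfig(n_samples=3000, seed=1))
    for j in range(truth.on.shape[1]):
        rebuilt = np.zeros(3000, dtype=np.int8)
        for b in truth.bursts:
            if b.network == j:
                rebuilt[b.start : b.end] = 1
        np.testing.assert_array_equal(rebuilt, truth.on[:, j])


def test_amplitudes_alternate_low_high():
    _, truth = simulate_parcels(SimulationConfig(n_samples=6000, seed=2))
    for j in range(2):
        labels = [b.amp_label for b in truth.bursts if b.network == j]
        amps = [b.amplitude for b in truth.bursts if b.network == j]
        assert labels[:4] == ["low", "high", "low", "high"]
        assert amps[:2] == [1.0, 2.0]


def test_oscillation_present_during_bursts(small_sim):
    data, truth = small_sim
    # visual parcels should carry much more 10 Hz power during bursts
    x = data.x[:, 0]
    on = truth.on[:, 0].astype(bool)
    var_on = x[on].var()
    var_off = x[~on].var()
    assert var_on > 1.5 * var_off


def test_orthogonalisation_removes_zero_lag_correlation(small_sim):
    data, _ = small_sim
    c = np.corrcoef(data.x.T)
    off = c[~np.eye(c.shape[0], dtype=bool)]
    assert np.max(np.abs(off)) < 1e-6


def test_orthogonalise_preserves_scale_and_rejects_rank_deficiency(rng):
    x = rng.standard_normal((500, 4))
    y = symmetric_orthogonalise(x)
    # per-column norms preserved
    np.testing.assert_allclose(
        np.linalg.norm(y - y.mean(0), axis=0),
        np.linalg.norm(x - x.mean(0), axis=0),
        rtol=1e-6,
    )
    bad = x.copy()
    bad[:, 3] = bad[:, 0] * 2.0
    with pytest.raises(DegeneracyError):
        symmetric_orthogonalise(bad)


def test_noise_floor_variance():
    cfg = SimulationConfig(n_samples=20000, seed=9, orthogonalise=False)
    data, truth = simulate_parcels(cfg)
    # a parcel in no network is pure noise with variance 0.2
    quiet = data.x[:, 20]
    assert abs(quiet.var() - 0.2) / 0.2 < 0.1


def test_config_roundtrip():
    cfg = SimulationConfig(n_samples=1000, seed=3)
    cfg2 = SimulationConfig.from_dict(cfg.to_dict())
    assert cfg2 == cfg
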
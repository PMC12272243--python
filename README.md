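# oscnets

Dynamic network analysis of oscillatory electrophysiological data.

Brain activity in M/EEG recordings organises into transient functional
networks: sets of regions that switch on together for tens of
milliseconds, oscillate at characteristic frequencies, and disband.
`oscnets` provides a tested pipeline for studying such dynamics:

- **Simulate** bursting oscillatory networks in parcel space — Markov
  on/off switching, per-burst random phases, alternating burst
  amplitudes, symmetric orthogonalisation (source-leakage correction).
- **Prepare** data by time-delay embedding (so covariances encode
  spectra and phase coupling), PCA, and standardisation.
- **Infer networks** two ways:
  - a **TDE-HMM** — mutually exclusive states, each a zero-mean Gaussian
    covariance pattern, fitted by exact Baum-Welch EM;
  - **DyNeMo** — a mixture of covariance *modes* whose simplex-weighted
    contributions vary continuously, so networks can overlap in time;
    fitted by stochastic variational inference (pure numpy).
- **Describe** each network in frequency space: multitaper state
  spectra or GLM mode spectra, coherence networks, band-limited power
  maps (NNMF-derived band for HMM states, full range for DyNeMo modes),
  top-2%-edge thresholded graphs.
- **Quantify task responses**: epoched, baseline-corrected network time
  courses; model-projected time-frequency maps; conventional Morlet
  full/evoked/induced decomposition; and max-statistic permutation GLM
  tests with family-wise error control.

See `docs/methods.md` for the models and numerical choices.

## Worked example

The default simulation contains a 10 Hz "visual" network on six parcels
(0-5) and a 20 Hz "motor" network on four parcels (30-33), each bursting
under a Markov chain with 80 ms mean lifetime and amplitudes alternating
between 1 and 2:

```python
import numpy as np
from oscnets import SimulationConfig, simulate_parcels, prepare, PrepConfig
from oscnets import fit_dynemo, DynemoConfig
from oscnets import spectra as sp
from oscnets.pipeline import match_networks
from oscnets.simulate import default_networks

data, truth = simulate_parcels(SimulationConfig(seed=7))
prepped = prepare(data, PrepConfig(n_lags=2, n_components=120))
print(f"{100 * prepped.explained_variance_ratio.sum():.2f}")
# 80.98   (percent of embedded variance kept by 120 components)

model, mtc = fit_dynemo(prepped, 3, DynemoConfig(max_epochs=12, n_init=10), seed=1)
print(np.round(model.loss_history, 3))
# [186.513 177.178 172.324 169.604 167.937 166.962 166.341 166.092
#  165.867 165.588 165.431 165.316]

alpha = sp.align_time_course(mtc.alpha_renorm, prepped.trim, len(data.x))
res = sp.glm_mode_spectra(data, alpha)
maps = sp.power_map(res)
masks = truth.member_mask(default_networks(), 38)
assign = match_networks(maps, masks.astype(float))

for i, name in enumerate(["visual", "motor"]):
    mode = assign[i]
    peak = res.freqs[np.argmax(res.psd[mode].mean(axis=0))]
    top = np.argsort(maps[mode])[::-1][: masks[i].sum()]
    print(name, "mode", mode, "peak", peak, "Hz, top parcels", sorted(top))
# visual mode 2 peak 10.0 Hz, top parcels [0, 1, 2, 3, 4, 5]
# motor mode 0 peak 20.0 Hz, top parcels [30, 31, 32, 33]
```

Both networks are recovered exactly: the matched modes peak at the
simulated frequencies and their strongest power-map parcels are the true
member sets. The visual mode also tracks burst *amplitude*: its mean
mixing coefficient is higher during high-amplitude than low-amplitude
bursts (paired difference ≈ 0.37, sign-flip permutation p ≈ 2e-4 over
335 burst pairs).

The same analysis runs from the command line:

```bash
oscnets simulate --seed 7 --out sim.h5
oscnets prep --in sim.h5 --lags 2 --pca 120
oscnets train-dynemo --in sim.h5 --modes 3 --seed 1
oscnets spectra --in sim.h5 --model dynemo
oscnets respond --in sim.h5 --model dynemo
oscnets test --in sim.h5
```

or as one configured pipeline (`oscnets run --config pipeline.yaml`)
whose YAML lists a global seed, the container path, and per-stage
parameters; re-running an identical configuration reproduces every
stochastic stage bitwise.

## Analysis scripts

The numbered scripts under `analysis/` run the full simulation study and
write summary tables to `results/`:

```bash
python analysis/01_simulate.py        # container + ground-truth summary
python analysis/02_prepare.py         # explained variance
python analysis/03_train_hmm.py       # state occupancies, lifetimes
python analysis/04_train_dynemo.py    # mode coefficients
python analysis/05_spectra.py         # peak frequencies, maps, networks
python analysis/06_task_response.py   # evoked responses + Morlet TF
python analysis/07_permutation_stats.py
```

## Reproduction

```bash
pip install --no-build-isolation --no-deps -e .
python -m pytest -q tests/                      # full suite incl. acceptance
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline numbers from scratch:
`t1` (embedded-PCA explained variance, % averaged over three derived
seeds) and `t2`/`t3` (peak GLM-spectrum frequencies, Hz, of the DyNeMo
modes matched to the occipital and motor networks). All randomness
derives from the single `--seed`. The spectra live on a 0.5 Hz grid
with a 4 Hz multitaper bandwidth, so `t2`/`t3` can land one grid step
off the simulated frequency on some seeds (e.g. `--seed 1` yields
t2 = 10.5, t3 = 20.0; `--seed 2` yields 10.0 and 20.0).

One acceptance test is expected to fail: the embedded-PCA explained
variance computed under the documented generator settings is ≈ 80.7%,
which falls outside the 85 ± 3 percentage-point band that test asserts
(see `docs/methods.md` for the preparation details; the remaining suite
passes).
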
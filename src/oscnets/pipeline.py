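"""Configuration-driven orchestration of the analysis stages.

A pipeline configuration is a mapping with a global ``seed``, an output
``container`` path, and a ``stages`` mapping whose keys come from the
fixed stage order::

    simulate -> prep -> (hmm | dynemo) -> spectra -> respond -> test

Each stage reads its inputs from the container, writes its products
under its own group, and logs what it did.  Stage seeds are derived
deterministically from the global seed, so re-running an identical
configuration reproduces every stochastic stage bitwise.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import io
from .dynemo import DynemoConfig, fit_dynemo
from .hmm import fit_hmm
from .prep import PrepConfig, prepare
from .simulate import SimulationConfig, simulate_parcels
from . import spectra as spectra_mod
from . import taskresp
from .stats import one_sample_max_stat_test

__all__ = [
    "STAGE_ORDER",
    "run_pipeline",
    "stage_seed",
    "match_networks",
]

STAGE_ORDER = ("simulate", "prep", "hmm", "dynemo", "spectra", "respond", "test")

log = logging.getLogger("oscnets")


def stage_seed(seed, stage):
    """Deterministic per-stage seed below 2**31, derived from the global one."""
    idx = STAGE_ORDER.index(stage)
    child = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(np.random.default_rng(child).integers(0, 2**31 - 1))


def match_networks(maps, truth_masks):
    """Match inferred networks to ground-truth ones by power-map correlation.

    ``maps`` is [networks x parcels] (inferred power maps), ``truth_masks``
    [truth-networks x parcels] (membership indicators).  Returns an array
    ``assign`` with ``assign[i]`` = index of the inferred network matched
    to truth network i, by maximising total Pearson correlation.
    """
    maps = np.asarray(maps, dtype=float)
    masks = np.asarray(truth_masks, dtype=float)
    corr = np.zeros((masks.shape[0], maps.shape[0]))
    for i in range(masks.shape[0]):
        for j in range(maps.shape[0]):
            a = masks[i] - masks[i].mean()
            b = maps[j] - maps[j].mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            corr[i, j] = (a @ b) / denom if denom > 0 else 0.0
    rows, cols = linear_sum_assignment(-corr)
    assign = np.empty(masks.shape[0], dtype=int)
    assign[rows] = cols
    return assign


def _stage_simulate(container, params, seed):
    cfg = SimulationConfig(**{**params, "seed": seed})
    data, truth = simulate_parcels(cfg)
    io.save_simulation(container, data, truth)
    return {"n_samples": data.x.shape[0], "n_parcels": data.x.shape[1]}


def _stage_prep(container, params, seed):
    data = io.load_parcel_data(container)
    cfg = PrepConfig(
        n_lags=params.get("n_lags", 2),
        n_components=params.get("n_components", 120),
        standardise=params.get("standardise", True),
    )
    prepped = prepare(data, cfg)
    io.save_group(
        container,
        "prep",
        {
            "y": prepped.y,
            "explained_variance_ratio": prepped.explained_variance_ratio,
            "pca_weights": prepped.pca_weights,
            "mean": prepped.mean,
            "std": prepped.std,
        },
        attrs={
            "trim": prepped.trim,
            "fs": prepped.fs,
            "n_parcels": prepped.n_parcels,
            "standardised": prepped.standardised,
            "n_lags": cfg.n_lags,
        },
    )
    return {"evr": float(prepped.explained_variance_ratio.sum())}


def _load_prepped(container):
    g = io.load_group(container, "prep", stage="prep")
    from .prep import PreparedData

    return PreparedData(
        y=g["y"],
        explained_variance_ratio=g["explained_variance_ratio"],
        pca_weights=g["pca_weights"],
        mean=g["mean"],
        std=g["std"],
        trim=int(g["_attrs"]["trim"]),
        fs=float(g["_attrs"]["fs"]),
        n_parcels=int(g["_attrs"]["n_parcels"]),
        standardised=bool(g["_attrs"]["standardised"]),
    )


def _stage_hmm(container, params, seed):
    prepped = _load_prepped(container)
    model, stc = fit_hmm(
        prepped,
        n_states=params.get("n_states", 3),
        n_init=params.get("n_init", 10),
        max_epochs=params.get("max_epochs", 40),
        seed=seed,
    )
    io.save_group(
        container,
        "hmm",
        {
            "covariances": model.covariances,
            "transition": model.transition,
            "initial": model.initial,
            "loss_history": model.loss_history,
            "gamma": stc.gamma,
            "viterbi": stc.viterbi,
        },
        attrs={"n_states": model.n_states, "seed": seed},
    )
    return {"loss": float(model.loss_history[-1])}


def _stage_dynemo(container, params, seed):
    prepped = _load_prepped(container)
    kwargs = {k: v for k, v in params.items() if k != "n_modes"}
    cfg = DynemoConfig(**kwargs)
    model, mtc = fit_dynemo(prepped, params.get("n_modes", 3), cfg, seed=seed)
    io.save_group(
        container,
        "dynemo",
        {
            "mode_covariances": model.mode_covariances,
            "loss_history": model.loss_history,
            "alpha": mtc.alpha,
            "alpha_renorm": mtc.alpha_renorm,
        },
        attrs={
            "n_modes": model.mode_covariances.shape[0],
            "rho": model.rho,
            "sigma_p": model.sigma_p,
            "seed": seed,
        },
    )
    return {"loss": float(model.loss_history[-1])}


def _aligned_time_course(container, model):
    data = io.load_parcel_data(container)
    prep_attrs = io.load_group(container, "prep", stage="prep")["_attrs"]
    trim = int(prep_attrs["trim"])
    if model == "hmm":
        g = io.load_group(container, "hmm", stage="hmm")
        tc = g["gamma"]
    elif model == "dynemo":
        g = io.load_group(container, "dynemo", stage="dynemo")
        tc = g["alpha_renorm"]
    else:
        raise ValueError(f"unknown model {model!r}")
    return data, spectra_mod.align_time_course(tc, trim, data.x.shape[0])


def _stage_spectra(container, params, seed):
    model = params.get("model", "dynemo")
    data, tc = _aligned_time_course(container, model)
    frange = tuple(params.get("frange", (1.0, 45.0)))
    common = dict(
        window_s=params.get("window_s", 2.0),
        bandwidth=params.get("bandwidth", 4.0),
        frange=frange,
    )
    if model == "hmm":
        res = spectra_mod.multitaper_state_spectra(data, tc, **common)
    else:
        res = spectra_mod.glm_mode_spectra(data, tc, **common)
    coh = spectra_mod.coherence(res)

    # band selection: HMM maps use the first (low-centroid) NNMF component
    # of the stacked coherence spectra; DyNeMo maps use the full range
    if model == "hmm":
        iu, ju = np.triu_indices(res.psd.shape[1], k=1)
        stacked = coh[:, iu, ju, :].reshape(-1, len(res.freqs))
        stacked = stacked[np.isfinite(stacked).all(axis=1)]
        bands = spectra_mod.nnmf_bands(stacked, n_components=2, seed=seed)
        weights = bands[0]
    else:
        bands = None
        weights = np.ones(len(res.freqs))
    maps = spectra_mod.power_map(res, weights=weights)
    band_coh = spectra_mod.band_coherence(coh, res.freqs, weights)
    edges = np.stack(
        [spectra_mod.threshold_edges(band_coh[k]) for k in range(len(maps))]
    )
    io.save_group(
        container,
        "spectra",
        {
            "freqs": res.freqs,
            "psd": res.psd,
            "coherence": coh,
            "power_maps": maps,
            "band_weights": weights,
            "nnmf_components": bands,
            "band_coherence": band_coh,
            "edges": edges.astype(np.int8),
        },
        attrs={
            "model": model,
            "band": "nnmf-first" if model == "hmm" else "full-range",
            "frange_lo": frange[0],
            "frange_hi": frange[1],
        },
    )
    # CSV exports
    root = str(container) + "_tables"
    for k in range(len(maps)):
        io.export_csv(
            f"{root}/power_map_{model}_{k}.csv",
            pd.DataFrame(
                {"parcel": data.parcel_names, "value": maps[k]}
            ),
        )
        ii, jj = np.nonzero(np.triu(edges[k], k=1))
        io.export_csv(
            f"{root}/network_{model}_{k}.csv",
            pd.DataFrame(
                {
                    "parcel_i": ii,
                    "parcel_j": jj,
                    "value": band_coh[k][ii, jj],
                }
            ),
        )
    return {"n_networks": int(len(maps))}


def _get_events(container, params):
    if "events_file" in params:
        df = io.read_events(params["events_file"])
        return df["onset_sample"].to_numpy()
    truth = io.load_ground_truth(container)
    if truth is None:
        raise io.DependencyError(
            "respond stage: no events_file given and no simulation ground "
            "truth in the container to derive burst onsets from"
        )
    network = params.get("event_network", truth.network_names[0])
    return truth.onsets(network)


def _stage_respond(container, params, seed):
    model = params.get("model", "dynemo")
    data, tc = _aligned_time_course(container, model)
    events = _get_events(container, params)
    tmin = params.get("tmin", -0.1)
    tmax = params.get("tmax", 1.0)
    ep, avg = taskresp.network_response(
        tc, events, data.fs, tmin=tmin, tmax=tmax
    )
    spec = io.load_group(container, "spectra", stage="spectra")
    proj = taskresp.project_tf(avg, spec["psd"].mean(axis=1), spec["freqs"], ep.times)
    io.save_group(
        container,
        "respond",
        {
            "epochs": ep.data,
            "times": ep.times,
            "response": avg,
            "events": events,
            "projected_tf": proj.power[:, :, 0],
            "projected_freqs": proj.freqs,
        },
        attrs={"model": model, "tmin": tmin, "tmax": tmax},
    )
    io.export_csv(
        str(container) + "_tables/response_" + model + ".csv",
        pd.DataFrame(
            avg, columns=[f"network_{k}" for k in range(avg.shape[1])]
        ).assign(time=ep.times),
    )
    return {"n_trials": int(ep.n_trials)}


def _stage_test(container, params, seed):
    g = io.load_group(container, "respond", stage="respond")
    epochs = g["epochs"]  # trials x time x networks
    res = one_sample_max_stat_test(
        epochs,
        n_perm=params.get("n_perm", 1000),
        alpha=params.get("alpha", 0.05),
        seed=seed,
    )
    io.save_group(
        container,
        "test",
        {
            "copes": res.copes,
            "pvalues": res.pvalues,
            "null": res.null,
            "significant": res.significant.astype(np.int8),
        },
        attrs={"alpha": res.alpha, "n_perm": params.get("n_perm", 1000)},
    )
    t_idx, n_idx = np.nonzero(np.ones_like(res.copes, dtype=bool))
    io.export_csv(
        str(container) + "_tables/test.csv",
        pd.DataFrame(
            {
                "time_index": t_idx,
                "network": n_idx,
                "cope": res.copes[t_idx, n_idx],
                "p_value": res.pvalues[t_idx, n_idx],
                "significant": res.significant[t_idx, n_idx],
            }
        ),
    )
    return {"n_significant": int(res.significant.sum())}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "hmm": _stage_hmm,
    "dynemo": _stage_dynemo,
    "spectra": _stage_spectra,
    "respond": _stage_respond,
    "test": _stage_test,
}


def run_pipeline(config):
    """Execute the configured stages in the fixed order.

    ``config`` is a mapping with keys ``seed`` (int), ``container``
    (output path) and ``stages`` (mapping of stage name to parameter
    mapping; an empty mapping uses defaults).  Returns the container
    path.  A stage whose upstream products are missing raises
    :class:`oscnets.io.DependencyError` naming the missing stage.
    """
    seed = config.get("seed")
    container = config["container"]
    stages = config["stages"]
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    io.write_sidecar(container, config, seed=seed)
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        params = dict(stages[stage] or {})
        t0 = time.time()
        info = _STAGE_FUNCS[stage](container, params, stage_seed(seed, stage))
        log.info("stage %s done in %.1f s: %s", stage, time.time() - t0, info)
    return container
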
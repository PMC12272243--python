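"""Analysis container: one HDF5 file per analysis, plus a JSON sidecar.

Every pipeline stage writes its products under its own group (``x``/``fs``
and ``ground_truth/`` at the root, then ``prep/``, ``hmm/``, ``dynemo/``,
``spectra/``, ``respond/``, ``test/``).  The sidecar ``<container>.json``
records the full configuration, seeds and software version so a run can
be reproduced bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .simulate import Burst, GroundTruth, ParcelData

__all__ = [
    "save_simulation",
    "load_parcel_data",
    "load_ground_truth",
    "save_group",
    "load_group",
    "write_sidecar",
    "read_sidecar",
    "read_events",
    "export_csv",
]


class DependencyError(RuntimeError):
    """A stage's upstream product is missing from the container."""


def _open_readonly(path):
    if not Path(path).exists():
        raise DependencyError(
            f"{path}: container does not exist (run an upstream stage first)"
        )
    return h5py.File(path, "r")


def save_simulation(path, data: ParcelData, truth: GroundTruth = None):
    """Write parcel data (and optionally ground truth) to a container."""
    with h5py.File(path, "a") as f:
        for key in ("x", "fs", "parcel_names", "ground_truth"):
            if key in f:
                del f[key]
        f.create_dataset("x", data=data.x.astype(np.float64))
        f.create_dataset("fs", data=float(data.fs))
        f.create_dataset(
            "parcel_names",
            data=np.array(data.parcel_names, dtype=h5py.string_dtype()),
        )
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("on", data=truth.on.astype(np.int8))
            g.create_dataset(
                "network_names",
                data=np.array(truth.network_names, dtype=h5py.string_dtype()),
            )
            # phases are ragged (one array per burst, sized by network
            # membership), so use a variable-length dataset
            vlen = h5py.vlen_dtype(np.float64)
            ph = g.create_dataset("phases", (len(truth.phases),), dtype=vlen)
            for i, p in enumerate(truth.phases):
                ph[i] = np.asarray(p, dtype=np.float64)
            rows = [
                (b.network, b.start, b.end, b.amp_label, b.amplitude)
                for b in truth.bursts
            ]
            dt = np.dtype(
                [
                    ("network", np.int64),
                    ("start", np.int64),
                    ("end", np.int64),
                    ("amp_label", h5py.string_dtype()),
                    ("amplitude", np.float64),
                ]
            )
            g.create_dataset("bursts", data=np.array(rows, dtype=dt))


def load_parcel_data(path):
    """Read ``x``/``fs`` (and parcel names if present) from a container."""
    with _open_readonly(path) as f:
        if "x" not in f or "fs" not in f:
            raise DependencyError(
                f"{path}: no simulated/imported data (run the simulate stage "
                "or supply a container with datasets 'x' and 'fs')"
            )
        x = f["x"][()]
        fs = float(f["fs"][()])
        if "parcel_names" in f:
            names = tuple(s.decode() for s in f["parcel_names"][()])
        else:
            names = tuple(f"parcel_{i}" for i in range(x.shape[1]))
    return ParcelData(x=x, fs=fs, parcel_names=names)


def load_ground_truth(path):
    """Read the simulation ground truth, or None if absent."""
    with _open_readonly(path) as f:
        if "ground_truth" not in f:
            return None
        g = f["ground_truth"]
        names = tuple(s.decode() for s in g["network_names"][()])
        bursts = [
            Burst(
                network=int(r["network"]),
                start=int(r["start"]),
                end=int(r["end"]),
                amp_label=r["amp_label"].decode(),
                amplitude=float(r["amplitude"]),
            )
            for r in g["bursts"][()]
        ]
        phases = [np.asarray(p) for p in g["phases"][()]]
        return GroundTruth(
            on=g["on"][()],
            bursts=bursts,
            phases=phases,
            network_names=names,
        )


def save_group(path, group, arrays, attrs=None):
    """Replace ``group`` in the container with the given arrays.

    ``arrays`` maps dataset names to array-likes (None values skipped);
    ``attrs`` maps attribute names to scalars/strings.
    """
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name, arr in arrays.items():
            if arr is None:
                continue
            g.create_dataset(name, data=np.asarray(arr))
        for name, val in (attrs or {}).items():
            g.attrs[name] = val


def load_group(path, group, stage=None):
    """Read every dataset in ``group`` into a dict (attrs under '_attrs')."""
    with _open_readonly(path) as f:
        if group not in f:
            raise DependencyError(
                f"{path}: missing '{group}' "
                f"(run the {stage or group} stage first)"
            )
        g = f[group]
        out = {name: g[name][()] for name in g}
        out["_attrs"] = dict(g.attrs)
    return out


def write_sidecar(path, config, seed=None):
    """Write the JSON config snapshot next to the container."""
    sidecar = Path(str(path) + ".json")
    payload = {
        "config": config,
        "seed": seed,
        "software": {"package": "oscnets", "version": __version__},
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def read_sidecar(path):
    sidecar = Path(str(path) + ".json")
    return json.loads(sidecar.read_text())


def read_events(path):
    """Read a tab-separated events table with onsets in samples.

    Expected header columns: ``onset_sample``, ``duration``,
    ``trial_type`` (a sample-indexed dialect of the BIDS events layout).
    Returns a DataFrame; onsets must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: events file missing columns {sorted(missing)}"
        )
    onsets = df["onset_sample"].to_numpy()
    if not np.issubdtype(onsets.dtype, np.integer):
        if not np.allclose(onsets, np.round(onsets)):
            raise ValueError("onset_sample must contain integers (samples)")
        df["onset_sample"] = onsets.astype(int)
    if (df["onset_sample"] < 0).any():
        raise ValueError("onset_sample must be non-negative")
    return df


def export_csv(path, df: pd.DataFrame):
    """Write a results table as CSV (no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return Path(path)
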
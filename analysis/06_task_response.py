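"""Task-evoked network responses around visual burst onsets.

Epochs the DyNeMo mode time course from -0.1 s to 1.0 s around each
visual-network burst onset, baseline-corrects on the pre-onset window,
and projects the trial-averaged response through the mode spectra to a
model-derived time-frequency map.  Also computes the conventional
Morlet decomposition (full / evoked / induced) of an occipital parcel.

Run 05_spectra.py first: its final (DyNeMo) spectra stay in the
container and are reused here for the projection.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from common import CONTAINER, RESULTS, setup_logging

from oscnets import io, taskresp
from oscnets.pipeline import _stage_respond

setup_logging()
info = _stage_respond(CONTAINER, {"model": "dynemo"}, None)

g = io.load_group(CONTAINER, "respond")
resp, times = g["response"], g["times"]
rows = [
    {
        "network": k,
        "peak_time_s": float(times[np.argmax(np.abs(resp[:, k]))]),
        "peak_response": float(resp[np.argmax(np.abs(resp[:, k])), k]),
    }
    for k in range(resp.shape[1])
]
io.export_csv(RESULTS / "response_summary.csv", pd.DataFrame(rows))

# conventional Morlet time-frequency view on an occipital parcel
data = io.load_parcel_data(CONTAINER)
ep = taskresp.epoch(data.x[:, :1], g["events"], data.fs)
out = {}
for mode in ("full", "evoked", "induced"):
    tf = taskresp.morlet_tf(ep, data.fs, mode=mode)
    tf = taskresp.baseline_correct_tf(tf)
    out[mode] = tf
    io.export_csv(
        RESULTS / f"tf_{mode}_parcel0.csv",
        pd.DataFrame(tf.power[:, :, 0], index=tf.freqs, columns=tf.times)
        .rename_axis("freq_hz")
        .reset_index(),
    )

fi, ti = np.unravel_index(
    np.argmax(out["full"].power[:, :, 0]), out["full"].power[:, :, 0].shape
)
print(pd.DataFrame(rows).to_string(index=False))
print("morlet peak (full):", float(out["full"].freqs[fi]), "Hz at",
      float(out["full"].times[ti]), "s")
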
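"""Permutation GLM test of the evoked network response.

One-sample max-|COPE| sign-flipping test across trials: which
(time, network) elements of the baseline-corrected evoked response
differ from zero, controlling family-wise error at alpha = 0.05.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from common import CONTAINER, RESULTS, SEED, setup_logging

from oscnets import io
from oscnets.pipeline import _stage_test, stage_seed

setup_logging()
info = _stage_test(
    CONTAINER, {"n_perm": 1000, "alpha": 0.05}, stage_seed(SEED, "test")
)

g = io.load_group(CONTAINER, "test")
sig = g["significant"].astype(bool)
rows = [
    {
        "network": k,
        "n_significant_timepoints": int(sig[:, k].sum()),
        "min_p": float(g["pvalues"][:, k].min()),
        "max_abs_cope": float(np.abs(g["copes"][:, k]).max()),
    }
    for k in range(sig.shape[1])
]
table = pd.DataFrame(rows)
io.export_csv(RESULTS / "stats_summary.csv", table)
print(table.to_string(index=False))
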
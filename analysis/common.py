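"""Shared paths and seed for the numbered analysis scripts."""

import logging
import pathlib

ROOT = pathlib.Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CONTAINER = RESULTS / "analysis.h5"
SEED = 1


def setup_logging():
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )
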
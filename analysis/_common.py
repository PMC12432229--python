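"""Shared run directory and configurations for the numbered analyses.

The imagery-scale scripts (01-04, 06) operate on one desk-scale coastal
tile and pass intermediate artifacts through ``results/desk/``; script 05
runs the vector-scale macro study.  Everything is deterministic in SEED.
"""

from pathlib import Path

from driftwood.studies import desk_pipeline_config, macro_landscape_config

SEED = 11

RESULTS = Path(__file__).resolve().parent.parent / "results"
DESK_DIR = RESULTS / "desk"
MACRO_DIR = RESULTS / "macro"


def desk_config():
    return desk_pipeline_config(SEED)


def macro_config():
    return macro_landscape_config(SEED)
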
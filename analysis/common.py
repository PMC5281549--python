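"""Shared paths and configuration for the analysis scripts.

The scripts run the desk-scale synthetic experiment in numbered stages;
each stage reads its inputs from the artifact directory written by the
previous one, so any stage can be re-run in isolation. Binary artifacts
(HDF5 bundles, decoder banks) live under ``scratch/analysis``; the tables
of results go to ``results/``.
"""

from __future__ import annotations

import sys
from pathlib import Path

from dreamdecode.presets import desk_config

ROOT = Path(__file__).resolve().parent.parent
ARTIFACTS = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20


def config():
    return desk_config(seed=SEED)


def ensure_dirs() -> None:
    ARTIFACTS.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def say(msg: str) -> None:
    print(msg, file=sys.stderr, flush=True)
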
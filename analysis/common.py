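"""Shared setup for the numbered analysis drivers.

All drivers operate on one deterministic study run under results/study
(seed 42, demo profile).  Each driver rebuilds the in-memory objects it
needs from the same config, so the scripts can be run in any order; the
tables they write land in the run directory.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mcinet import cohort as ch
from mcinet import connectivity as cn
from mcinet import pipeline as pl


REPO_ROOT = Path(__file__).resolve().parent.parent


def study_config(seed: int = 42, out_dir: str = "results/study") -> pl.RunConfig:
    out = Path(out_dir)
    if not out.is_absolute():
        out = REPO_ROOT / out
    return pl.RunConfig(out_dir=str(out), seed=seed)


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=str, default="results/study")
    return ap.parse_args()


def load_study(config: pl.RunConfig):
    """(subjects, truth, per-subject FCs, group FCs); deterministic."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, truth = pl.stage_simulate(config, out)
    fcs, group_fc = pl.stage_connectivity(subjects, out)
    return subjects, truth, fcs, group_fc
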
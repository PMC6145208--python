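"""Shared bits for the analysis drivers: argument parsing and output paths."""

from __future__ import annotations

import argparse
from pathlib import Path

from methval.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1,
                        help="seed for all synthetic data (default 1)")
    return parser.parse_args()


def default_config(seed: int) -> SimConfig:
    RESULTS.mkdir(exist_ok=True)
    return SimConfig(seed=seed)
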
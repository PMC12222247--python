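"""Shared argument handling for the numbered analysis drivers.

Every driver operates on one run directory (default ``scratch/run``)
so the steps can be executed in sequence, inspected, and re-run
individually.  Summary tables land under ``results/``.
"""

from __future__ import annotations

import argparse
import logging
from pathlib import Path

from grainfluor import RunConfig

RESULTS = Path("results")


def make_parser(description: str) -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--run-dir", default="scratch/run",
                        help="pipeline run directory")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--shape", type=int, nargs=2, default=(384, 512),
                        metavar=("H", "W"))
    return parser


def make_config(args: argparse.Namespace) -> RunConfig:
    logging.basicConfig(
        level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    RESULTS.mkdir(exist_ok=True)
    return RunConfig(
        out_dir=args.run_dir,
        seed=args.seed,
        shape=tuple(args.shape),
        write_score_tiffs=False,
    )
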
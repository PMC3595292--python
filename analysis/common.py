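"""Shared settings for the numbered analysis drivers.

One output directory and one seed so the drivers compose into a single
reproducible analysis; individual drivers accept ``--seed`` overrides.
Problem sizes (40x40 parameter grid, 20,000 posterior draws, 20 m kriged
maps) are chosen so the full chain runs in a couple of minutes on one CPU
while leaving the posterior summaries stable to well under the credible
interval widths.
"""

import argparse
from pathlib import Path

from ecokrige.pipeline import RunConfig

OUTDIR = str(Path(__file__).resolve().parent.parent / "results" / "analysis")


def run_config(seed: int, stages: tuple[str, ...]) -> RunConfig:
    return RunConfig(
        outdir=OUTDIR,
        seed=seed,
        stages=stages,
        n_phi=40,
        n_nu=40,
        n_draws=20_000,
        prediction_cell=20.0,
    )


def parse_seed(description: str) -> int:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    return ap.parse_args().seed
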
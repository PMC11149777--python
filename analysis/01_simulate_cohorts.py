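#!/usr/bin/env python
"""Generate every synthetic input set the downstream analyses consume.

Writes one directory per preset under scratch/sim/ (regenerable, multi-MB),
each with its truth sidecar, using the same artifacts the CLI `simulate`
subcommand produces.
"""

from pathlib import Path

from click.testing import CliRunner

from denovostruct.cli import main

OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"

PRESETS = [
    "denovo-isd",
    "duplicate-isd",
    "denovo-morf",
    "denovo-hydro",
    "denovo-full-isd",
    "denovo-ss",
    "denovo-aa",
    "toy-complex",
    "synteny",
    "expression",
]


def run() -> None:
    runner = CliRunner()
    for preset in PRESETS:
        out = OUT / preset
        res = runner.invoke(
            main,
            ["simulate", "--preset", preset, "--seed", "1", "--out", str(out)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0, res.output
        print(f"simulated {preset} -> {out}")


if __name__ == "__main__":
    run()
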
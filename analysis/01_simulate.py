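#!/usr/bin/env python
"""Generate the default synthetic ageing experiment.

Writes the four data streams (redox amounts, germination counts, qPCR
fluorescence curves, array spot tables) plus their pre-noise truth tables to
results/simulated/.  All downstream analysis scripts read from there.
"""

from pathlib import Path

from click.testing import CliRunner

from seedage.cli import main

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 0


def run():
    res = CliRunner().invoke(main, ["simulate", "--seed", str(SEED), "--out", str(OUT)])
    if res.exit_code != 0:
        raise SystemExit(res.output)
    print(f"Simulated ageing time course (seed {SEED}) written to {OUT}")
    for f in sorted(OUT.glob("*.csv")):
        print(f"  {f.name}: {sum(1 for _ in open(f)) - 1} rows")


if __name__ == "__main__":
    run()
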
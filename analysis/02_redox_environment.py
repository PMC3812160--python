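#!/usr/bin/env python
"""Half-cell reduction potentials and the summed redox environment.

Converts the simulated thiol/disulphide amounts to molar concentrations
(12% moisture content -> 0.1364 mL water per g DW), computes the Nernst
potential of each couple per replicate, and sums E x [thiol] over couples into
the redox environment.  The glutathione couple dominates the sum; ageing
drives every summary towards less negative (more oxidising) values.
"""

from pathlib import Path

import pandas as pd

from seedage.io import PipelineConfig
from seedage.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "redox"


def run():
    cfg = PipelineConfig(
        redox_table=str(SIM / "redox.csv"),
        output_dir=str(OUT),
        hydration_mL_per_gDW=0.12 / 0.88,
        seed=0,
    )
    report = run_pipeline(cfg, stages=("redox",))
    env = pd.read_csv(OUT / "redox_environment_summary.csv")
    e_gsh = pd.read_csv(OUT / "redox_potentials_summary.csv")
    e_gsh = e_gsh[e_gsh["couple"] == "GSSG/2GSH"]
    print("Glutathione half-cell potential and redox environment by ageing time:")
    merged = e_gsh.merge(env, on="time_days", suffixes=("_E", "_env"))
    for r in merged.itertuples():
        print(
            f"  {r.time_days:5.0f} d   E_GSSG/2GSH = {r.mean_E:8.2f} mV"
            f"   redox environment = {r.mean_env:7.3f} mV M"
        )
    first, last = merged.iloc[0], merged.iloc[-1]
    print(
        f"Ageing shifted E_GSSG/2GSH by {last.mean_E - first.mean_E:+.1f} mV and the"
        f" redox environment by {last.mean_env - first.mean_env:+.2f} mV M"
        " (towards oxidising)."
    )
    print(f"Tables in {OUT}")


if __name__ == "__main__":
    run()
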
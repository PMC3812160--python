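#!/usr/bin/env python
"""Probit estimate of the redox zone of viability loss.

Fits P(germinate) = Phi(alpha + beta * E) to the simulated germination counts,
with the glutathione half-cell potential as the dose, and reports the
potential at which 50% of seeds have lost viability together with its 95%
confidence zone (the generator's truth is -185 mV).
"""

import json
from pathlib import Path

from seedage.io import PipelineConfig
from seedage.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "viability"


def run():
    cfg = PipelineConfig(
        germination_table=str(SIM / "germination.csv"),
        output_dir=str(OUT),
        probit_level=0.95,
        seed=0,
    )
    report = run_pipeline(cfg, stages=("viability",))
    s = report.stages["viability"]
    print(f"Probit fit on {s['n_obs']} germination tests: "
          f"alpha = {s['alpha']:.2f}, beta = {s['beta']:.4f} per mV (converged: {s['converged']})")
    z = s["zone"]
    print(f"50% viability loss at E_GSSG/2GSH = {z['dose50']:.1f} mV; "
          f"{z['level']:.0%} zone {z['lower']:.1f} to {z['upper']:.1f} mV ({z['method']} method)")
    truth = json.load(open(SIM / "truth" / "germination_truth.json"))
    print(f"Generator truth: dose50 = {truth['dose50']:.1f} mV")


if __name__ == "__main__":
    run()
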
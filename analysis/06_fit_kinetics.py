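#!/usr/bin/env python
"""Two-stage rate fit on noiseless simulated traces.

Stage 1 fits the lumped activation rate k_ON,T and the trans-cleavage rate
k2 to a background-free Model 1 trace; those are then fixed and stage 2
fits the background binding/unbinding rates (k_ON,B, k_OFF,B) to a Model 2
trace with 200 nM background.  On noiseless self-generated data this is a
closure check: the fit must return the generating constants.  Also scans
the residual along the constant-K_D,eff valley to show how strongly the
absolute background rates (vs their ratio) are constrained.  Writes
results/fitted_rates.json and results/kd_valley_profile.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from caskinetics.kinetics_model import (AssayMix, RateParameters,
                                        effective_kd, fit_stage1, fit_stage2,
                                        ratio_profile, rates_to_dict,
                                        simulate_model1, simulate_model2)

OUT = Path(__file__).resolve().parents[1] / "results"

GENERATING = RateParameters(k_on_t=1.8e4, k2=1.0e4, k_on_b=1.1e6, k_off_b=0.026)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    mix0 = AssayMix()
    mix_bg = AssayMix(background_0=200.0)
    trace0 = simulate_model1(GENERATING, mix0)
    trace_bg = simulate_model2(GENERATING, mix_bg)

    stage1 = fit_stage1(trace0, mix0, seed=args.seed)
    print(f"stage 1: k_ON,T = {stage1.params.k_on_t:.4g} M^-1 s^-1, "
          f"k2 = {stage1.params.k2:.4g} M^-1 s^-1 "
          f"(RMS residual {stage1.residual_rms:.2g} nM)")

    stage2 = fit_stage2(trace_bg, stage1.params, mix_bg, seed=args.seed)
    kd_nM = effective_kd(stage2.params) * 1e9
    print(f"stage 2: k_ON,B = {stage2.params.k_on_b:.4g} M^-1 s^-1, "
          f"k_OFF,B = {stage2.params.k_off_b:.4g} s^-1 "
          f"(RMS residual {stage2.residual_rms:.2g} nM)")
    print(f"effective K_D = k_OFF,B / k_ON,B = {kd_nM:.1f} nM")

    for name, fitted, truth in (("k_ON,T", stage1.params.k_on_t, GENERATING.k_on_t),
                                ("k_OFF,B", stage2.params.k_off_b, GENERATING.k_off_b)):
        print(f"closure: {name} recovered to "
              f"{abs(fitted - truth) / truth * 100:.3g}% of the generating value")

    OUT.mkdir(exist_ok=True)
    doc = rates_to_dict(stage2.params)
    doc["K_D_eff_nM"] = kd_nM
    doc["stage1_residual_rms_nM"] = stage1.residual_rms
    doc["stage2_residual_rms_nM"] = stage2.residual_rms
    (OUT / "fitted_rates.json").write_text(json.dumps(doc, indent=2) + "\n")

    grid = GENERATING.k_on_b * np.logspace(-1, 1, 9)
    rms = ratio_profile(trace_bg, stage1.params, effective_kd(GENERATING),
                        grid, mix_bg)
    pd.DataFrame({"k_on_b_M_per_s": grid, "rms_residual_nM": rms}).to_csv(
        OUT / "kd_valley_profile.csv", index=False)
    print("constant-K_D valley: RMS residual stays below "
          f"{rms.max():.2f} nM across a 100-fold k_ON,B range "
          "(the ratio is far better constrained than the absolute rates)")
    print(f"wrote {OUT / 'fitted_rates.json'} and {OUT / 'kd_valley_profile.csv'}")


if __name__ == "__main__":
    main()
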
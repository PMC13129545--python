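#!/usr/bin/env python
"""Kinetic ratios from the simulated plate.

Runs the full trace-analysis chain on results/plate.csv (negative-control
subtraction, normalization to the 200 nM reporter scale, per-well t0.5,
all pairwise with/without half-time ratios) and writes one row per
(gRNA, background) condition to results/kinetic_ratios.csv.
Run 04_simulate_plate.py first.
"""

from pathlib import Path

from caskinetics.trace_analysis import (analyze_plate, read_plate_csv,
                                        read_sample_sheet)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plate = read_plate_csv(OUT / "plate.csv")
    sheet = read_sample_sheet(OUT / "sample_sheet.csv")
    result = analyze_plate(plate, sheet)
    result.to_csv(OUT / "kinetic_ratios.csv", index=False)

    for row in result.itertuples():
        print(f"{row.grna} + {row.background} ({row.background_conc_nM:g} nM): "
              f"r = {row.r_mean:.3f} +/- {row.r_sd:.3f} "
              f"({row.n_pairs} pairwise ratios; "
              f"t0.5 with = [{row.t05_with_min}] min, "
              f"without = [{row.t05_without_min}] min)")
    print(f"wrote {OUT / 'kinetic_ratios.csv'}")


if __name__ == "__main__":
    main()
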
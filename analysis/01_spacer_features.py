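#!/usr/bin/env python
"""Composition features of the 17 benchmark gRNA spacers.

Computes seed (first 8 nt) and full-spacer purine/pyrimidine and AU/GC
counts and fractions for the benchmark panel and writes them to
results/spacer_features.csv.  These features are the predictors the
slowdown expression consumes (see 07_slowdown_expression.py).
"""

from pathlib import Path

from caskinetics.sequence_features import feature_table
from caskinetics.synthetic_data import table1_fixtures

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    records = table1_fixtures()
    table = feature_table(records)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "spacer_features.csv", index=False)

    print(f"computed composition features for {len(table)} spacers")
    extremes = table.sort_values("seed_f_R")
    low, high = extremes.iloc[0], extremes.iloc[-1]
    print(f"most purine-poor seed:  {low['name']} (f_R={low['seed_f_R']:.3f}, "
          f"f_U={low['seed_f_U']:.3f})")
    print(f"most purine-rich seed:  {high['name']} (f_R={high['seed_f_R']:.3f}, "
          f"f_U={high['seed_f_U']:.3f})")
    print(f"wrote {OUT / 'spacer_features.csv'}")


if __name__ == "__main__":
    main()
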
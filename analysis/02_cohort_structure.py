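"""Summarise length-at-age structure per age cohort.

Reads the age-at-length dataset and prints/writes the per-cohort table
(n, min, max, range, mean, SD of length).  The interesting feature of
River-Inn-like data is the very wide within-cohort length range from
age 2 on, which is what ultimately destabilises the frequentist
age-based growth fit.
"""

import argparse
from pathlib import Path

from fishgrowth import cohort_summary, read_age_length_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/age_length.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort_summary.csv"))
    args = ap.parse_args()

    records = read_age_length_csv(args.data)
    table = cohort_summary(records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.round(1).to_string(index=False))
    widest = table.loc[table["range"].idxmax()]
    print(
        f"\nwidest cohort: age {int(widest['age_class'])}+ spans "
        f"{widest['range']:.0f} mm ({widest['min']:.0f}-{widest['max']:.0f} mm)"
    )


if __name__ == "__main__":
    main()
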
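#!/usr/bin/env python
"""Classify sarcopenic obesity from within-sample SMM/FM quintiles.

SO = SMM in the two lowest quintiles AND fat mass in the two highest
quintiles AND BMI >= 30.  Prints the cutpoints and the prevalence, and
appends the classification flags to the scored cohort.
"""

import argparse
import json
from pathlib import Path

from hbiso import body_composition as bc
from hbiso.io import read_cohort, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scored", type=Path, default=Path("results/scored.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.scored, required=("smm", "fm", "bmi"))
    status = bc.classify_so(cohort)
    for col in ("smm_low2", "fm_high2", "bmi_ge30", "so"):
        cohort[col] = status.flags[col].astype(int)
    write_table(cohort, args.out_dir / "classified.csv")
    cutpoints = {"smm_p40": status.smm_p40, "smm_p60": status.smm_p60,
                 "fm_p40": status.fm_p40, "fm_p60": status.fm_p60}
    (args.out_dir / "so_cutpoints.json").write_text(json.dumps(cutpoints, indent=2, sort_keys=True))

    print(f"cutpoints: SMM P40 = {status.smm_p40:.2f} kg, FM P60 = {status.fm_p60:.2f} kg")
    print(f"low-muscle share: {100 * status.flags.smm_low2.mean():.1f}%  "
          f"high-fat share: {100 * status.flags.fm_high2.mean():.1f}%  "
          f"BMI>=30 share: {100 * status.flags.bmi_ge30.mean():.1f}%")
    print(f"SO cases: {int(status.flags.so.sum())}  "
          f"prevalence: {bc.so_prevalence(status):.1f}%")


if __name__ == "__main__":
    main()
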
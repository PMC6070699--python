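#!/usr/bin/env python
"""Determine screening and confirmatory cut points from the simulated
training set (written by 01_simulate_population.py).

Two screening cut points per antigen: the untreated-serum route
(parametric on log ODs with automatic nonparametric fallback when the
Shapiro-Wilk gate fails - which is expected here, since the drug-naive
training set genuinely contains pre-existing seropositives) and the
immune-inhibited route (95th percentile of antigen-preincubated ODs).
The confirmatory cut point is mean + 1.645 SD of the training percent
inhibitions after outlier removal.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from adatier import plates
from adatier.pipeline import training_cutpoints

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    plate_csv = RESULTS / "training_plate.csv"
    if not plate_csv.exists():
        raise SystemExit("run analysis/01_simulate_population.py first")
    frame = plates.as_frame(pd.read_csv(plate_csv))
    doc = {}
    for antigen in plates.ANTIGENS:
        cuts = training_cutpoints(frame[frame["antigen"] == antigen], antigen)
        doc[antigen] = {
            "screening_untreated": dataclasses.asdict(cuts.untreated),
            "screening_inhibited": dataclasses.asdict(cuts.inhibited),
            "confirmatory": dataclasses.asdict(cuts.confirmatory),
        }
        print(f"{antigen}:")
        print(
            f"  screening (untreated serum):  {cuts.untreated.cut_point:.4f} OD "
            f"[{cuts.untreated.method}, {cuts.untreated.n_outliers_removed} outliers removed"
            + (f"; {cuts.untreated.notes}" if cuts.untreated.notes else "")
            + "]"
        )
        print(
            f"  screening (immune-inhibited): {cuts.inhibited.cut_point:.4f} OD "
            f"[95th percentile, {cuts.inhibited.n_outliers_removed} outliers removed]"
        )
        print(
            f"  confirmatory:                 {cuts.confirmatory.cut_point:.2f} % inhibition "
            f"[{cuts.confirmatory.n_outliers_removed} outliers removed]"
        )
    with open(RESULTS / "cut_points.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    print(f"wrote {RESULTS/'cut_points.json'}")


if __name__ == "__main__":
    main()
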
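#!/usr/bin/env python
"""Classify the 200-donor survey population through the tiered cascade.

Screens every donor against both screening cut points (from
04_cut_points.py), confirms screen-positives by percent inhibition, and
titrates confirmed positives (immune-inhibition method) on the 4-fold
endpoint series 1:4 ... 1:1024.  Writes one outcomes CSV per method and
compares the confirmed rates with the generator's configured prevalences.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from adatier import plates
from adatier.cutpoints import CutPointResult
from adatier.pipeline import StudyCutPoints, classify_survey, titrate_confirmed
from adatier.report import WITH_INHIBITION
from adatier.simulate import DonorTruth, SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20180615


def main() -> None:
    for f in ("survey_plate.csv", "survey_truth.csv", "cut_points.json"):
        if not (RESULTS / f).exists():
            raise SystemExit("run analysis scripts 01 and 04 first")
    frame = plates.as_frame(pd.read_csv(RESULTS / "survey_plate.csv"))
    truth = pd.read_csv(RESULTS / "survey_truth.csv")
    with open(RESULTS / "cut_points.json") as fh:
        raw_cuts = json.load(fh)
    cuts = {
        antigen: StudyCutPoints(
            untreated=CutPointResult(**doc["screening_untreated"]),
            inhibited=CutPointResult(**doc["screening_inhibited"]),
            confirmatory=CutPointResult(**doc["confirmatory"]),
        )
        for antigen, doc in raw_cuts.items()
    }
    outcomes = classify_survey(frame, cuts)

    config = SimulationConfig(n_donors=200, seed=SEED)
    donors = [DonorTruth(**rec) for rec in truth.rename(columns={}).to_dict("records")]
    outcomes[WITH_INHIBITION] = titrate_confirmed(
        outcomes[WITH_INHIBITION], donors, config, rng=np.random.default_rng(SEED + 9)
    )

    for method, ocs in outcomes.items():
        df = pd.DataFrame([dataclasses.asdict(o) for o in ocs])
        df.to_csv(RESULTS / f"outcomes_{method}.csv", index=False)
        print(f"--- {method} ---")
        for antigen in plates.ANTIGENS:
            sub = df[df["antigen"] == antigen]
            n_screen = int(sub["screen_positive"].sum())
            n_conf = int((sub["confirmed_positive"] == True).sum())  # noqa: E712
            true_prev = truth[f"seropositive_{'sa' if antigen == 'SaCas9' else 'sp'}"].mean()
            print(
                f"  {antigen}: {n_screen}/200 screen-positive ({n_screen / 2:.1f}%), "
                f"{n_conf}/200 confirmed ({n_conf / 2:.1f}%); "
                f"true seroprevalence in this draw {100 * true_prev:.1f}%"
            )
    titered = [o for o in outcomes[WITH_INHIBITION] if o.titer is not None]
    print(f"titrated {len(titered)} confirmed-positive samples (inhibition method)")


if __name__ == "__main__":
    main()
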
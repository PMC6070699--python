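#!/usr/bin/env python
"""Produce the survey deliverable tables.

Two sources: (i) the simulated survey classified in 05 - demographics
summary, stratified prevalence per antigen/method/tier, endpoint-titer
distribution; (ii) the shipped synthetic reference cohort whose marginals
reproduce the published survey summary exactly, as a fixed point of
comparison.
"""

from pathlib import Path

import pandas as pd

from adatier.report import (
    WITH_INHIBITION,
    demographics_summary,
    prevalence_table,
    render_prevalence_markdown,
    titer_table,
)
from adatier.synthetic_reference import reference_demographics, reference_outcomes
from adatier.tiers import DonorOutcome

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def outcomes_from_csv(path) -> list[DonorOutcome]:
    out = []
    for _, r in pd.read_csv(path).iterrows():
        out.append(
            DonorOutcome(
                donor_id=str(r["donor_id"]), antigen=str(r["antigen"]),
                screen_od=float(r["screen_od"]), screen_positive=bool(r["screen_positive"]),
                percent_inhibition=None if pd.isna(r["percent_inhibition"]) else float(r["percent_inhibition"]),
                confirmed_positive=None if pd.isna(r["confirmed_positive"]) else bool(r["confirmed_positive"]),
                titer=None if pd.isna(r["titer"]) else int(r["titer"]),
            )
        )
    return out


def main() -> None:
    # --- simulated survey ---------------------------------------------------
    truth = pd.read_csv(RESULTS / "survey_truth.csv")
    demo = truth[["donor_id", "race", "gender", "age_band"]]
    outcomes = {
        m: outcomes_from_csv(RESULTS / f"outcomes_{m}.csv")
        for m in ("without_inhibition", "with_inhibition")
    }
    table = prevalence_table(outcomes, demo)
    table.frame.to_csv(RESULTS / "prevalence_simulated.csv", index=False)
    demographics_summary(demo).to_csv(RESULTS / "demographics_simulated.csv", index=False)
    titers = titer_table(outcomes[WITH_INHIBITION])
    print("simulated survey totals:")
    f = table.frame
    print(
        f[f["axis"] == "total"][["antigen", "method", "tier", "count", "percent"]]
        .to_string(index=False)
    )
    print(f"simulated titer distribution: {titers}")

    # --- reference cohort ---------------------------------------------------
    ref_table = prevalence_table(reference_outcomes(), reference_demographics())
    ref_table.frame.to_csv(RESULTS / "prevalence_reference.csv", index=False)
    (RESULTS / "prevalence_reference.md").write_text(
        render_prevalence_markdown(ref_table) + "\n"
    )
    ref_titers = titer_table(reference_outcomes()[WITH_INHIBITION])
    rf = ref_table.frame
    tot = rf[(rf["axis"] == "total")]
    print("\nreference cohort totals (match the published survey exactly):")
    print(tot[["antigen", "method", "tier", "count", "percent"]].to_string(index=False))
    print(f"reference titer distribution: {ref_titers} "
          f"({sum(sum(v.values()) for v in ref_titers.values())} titrated donors)")
    print(f"tables written to {RESULTS}/")


if __name__ == "__main__":
    main()
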
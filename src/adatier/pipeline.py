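"""End-to-end orchestration of the tiered ADA analysis.

Ties the stages together the way the study runs them: simulate (or load)
plate data, blank-correct and aggregate, estimate cut points on a
training set, classify a survey population through the screen -> confirm
cascade under both cut-point methods, titrate confirmed positives, and
tabulate prevalence.  Also hosts the Monte-Carlo calibration studies
(false-positive rate of the cut-point estimators; recovery of configured
prevalences by the full pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cutpoints, plates, report, simulate, tiers
from .cutpoints import CutPointParams, CutPointResult
from .simulate import SimulationConfig
from .tiers import DonorOutcome


def aggregate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised replicate aggregation (mean/SD/n per sample group)."""
    keys = list(plates.GROUP_KEYS)
    if frame["spiked_conc"].notna().any():
        keys.append("spiked_conc")
    g = frame.groupby(keys, dropna=False)["od450"].agg(["mean", "std", "count"])
    g = g.rename(columns={"mean": "mean_od", "std": "sd_od", "count": "n_replicates"})
    g["sd_od"] = g["sd_od"].fillna(0.0)
    return g.reset_index()


def corrected_sample_means(
    frame: pd.DataFrame, antigen: str, condition: str
) -> pd.Series:
    """Blank-corrected per-donor mean ODs for one antigen and condition."""
    corrected = plates.blank_correct(frame)
    agg = aggregate_frame(corrected)
    sel = agg[(agg["antigen"] == antigen) & (agg["condition"] == condition)]
    return sel.set_index("donor_id")["mean_od"]


@dataclass(frozen=True)
class StudyCutPoints:
    """Cut points of one antigen: both screening methods + confirmatory."""

    untreated: CutPointResult
    inhibited: CutPointResult
    confirmatory: CutPointResult


def training_cutpoints(
    training_frame: pd.DataFrame,
    antigen: str,
    params: CutPointParams = CutPointParams(),
) -> StudyCutPoints:
    """Estimate all three cut points from a training-set plate table.

    The untreated screening cut point comes from untreated-condition mean
    ODs (parametric route with automatic nonparametric fallback); the
    inhibited screening cut point from antigen-preincubated mean ODs
    (95th percentile); the confirmatory cut point from the per-donor
    percent inhibition between the paired conditions.
    """
    corrected = plates.blank_correct(training_frame)
    agg = aggregate_frame(corrected)
    sel = agg[agg["antigen"] == antigen].set_index(["condition", "donor_id"])["mean_od"]
    unt = sel.loc["untreated"]
    inh = sel.loc["inhibited"]
    pi = [
        cutpoints.percent_inhibition(unt[d], inh[d])
        for d in unt.index
        if d in inh.index
    ]
    return StudyCutPoints(
        untreated=cutpoints.screening_cutpoint_untreated(unt.to_numpy(), params),
        inhibited=cutpoints.screening_cutpoint_inhibited(inh.to_numpy(), params),
        confirmatory=cutpoints.confirmatory_cutpoint(np.asarray(pi), params),
    )


def classify_survey(
    survey_frame: pd.DataFrame,
    cuts_by_antigen: Mapping[str, StudyCutPoints],
) -> dict[str, list[DonorOutcome]]:
    """Run the survey population through both cut-point methods.

    Returns outcomes keyed by method (``without_inhibition`` uses the
    untreated-serum screening cut point, ``with_inhibition`` the
    immune-inhibited one); the confirmatory tier is shared.
    """
    corrected = plates.blank_correct(survey_frame)
    agg = aggregate_frame(corrected)
    out: dict[str, list[DonorOutcome]] = {m: [] for m in report.METHODS}
    for antigen, cuts in cuts_by_antigen.items():
        sel = agg[agg["antigen"] == antigen]
        samples = [
            plates.SampleResult(
                donor_id=str(r["donor_id"]),
                antigen=antigen,
                condition=str(r["condition"]),
                serum_dilution=int(r["serum_dilution"]),
                mean_od=float(r["mean_od"]),
                sd_od=float(r["sd_od"]),
                n_replicates=int(r["n_replicates"]),
            )
            for _, r in sel.iterrows()
        ]
        for method, screen_cut in (
            (report.WITHOUT_INHIBITION, cuts.untreated),
            (report.WITH_INHIBITION, cuts.inhibited),
        ):
            out[method].extend(
                tiers.classify_population(samples, screen_cut, cuts.confirmatory, antigen)
            )
    return out


def titrate_confirmed(
    outcomes: Sequence[DonorOutcome],
    donors: Sequence[simulate.DonorTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    dilutions: Sequence[int] = (4, 16, 64, 256, 1024),
) -> list[DonorOutcome]:
    """Attach simulated endpoint titers to confirmed-positive outcomes."""
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    truth = {d.donor_id: d for d in donors}
    out = []
    for o in outcomes:
        if not o.confirmed_positive:
            out.append(o)
            continue
        ods, blank = simulate.generate_titration_series(
            truth[o.donor_id], o.antigen, config, dilutions=dilutions, rng=rng
        )
        series = tiers.TiterSeries(dilutions=list(dilutions), ods=list(ods), blank=blank)
        out.append(tiers.with_titer(o, tiers.determine_titer(series)))
    return out


@dataclass(frozen=True)
class StudyResult:
    """Everything one simulated study produces."""

    donors: Sequence[simulate.DonorTruth]
    cuts: Mapping[str, StudyCutPoints]
    outcomes: Mapping[str, Sequence[DonorOutcome]]
    prevalence: report.PrevalenceTable
    titers: Mapping[str, Mapping[int, int]]


def run_study(
    config: SimulationConfig,
    n_training: int = 48,
    titrate: bool = True,
) -> StudyResult:
    """Simulate and analyse one full tiered study.

    A drug-naive training population of ``n_training`` donors (drawn from
    the same background as the survey population, at the configured
    prevalences) fixes the cut points; the survey population of
    ``config.n_donors`` donors is then classified under both methods, and
    confirmed positives under the inhibition method are titrated.
    """
    rng = np.random.default_rng(config.seed)
    training_cfg = replace(config, n_donors=n_training)
    training_donors = simulate.generate_donors(training_cfg, rng)
    training_frame = simulate.generate_measurements(training_donors, training_cfg, rng)
    survey_donors = simulate.generate_donors(config, rng)
    survey_frame = simulate.generate_measurements(survey_donors, config, rng)
    cuts = {
        antigen: training_cutpoints(
            training_frame[training_frame["antigen"] == antigen], antigen
        )
        for antigen in plates.ANTIGENS
    }
    outcomes = classify_survey(survey_frame, cuts)
    if titrate:
        outcomes[report.WITH_INHIBITION] = titrate_confirmed(
            outcomes[report.WITH_INHIBITION], survey_donors, config, rng
        )
    demo = simulate.donors_frame(survey_donors)[
        ["donor_id", "race", "gender", "age_band"]
    ]
    prevalence = report.prevalence_table(outcomes, demo)
    titers = report.titer_table(outcomes[report.WITH_INHIBITION])
    return StudyResult(
        donors=survey_donors,
        cuts=cuts,
        outcomes=outcomes,
        prevalence=prevalence,
        titers=titers,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo calibration studies


def _negative_training_frame(
    n: int, config: SimulationConfig, rng: np.random.Generator, condition: str
) -> pd.DataFrame:
    cfg = replace(config, n_donors=n, prevalence_sa=0.0, prevalence_sp=0.0)
    donors = simulate.generate_donors(cfg, rng)
    return simulate.generate_measurements(
        donors, cfg, rng, antigens=("SaCas9",), conditions=(condition,)
    )


def fpr_calibration(
    method: str,
    n_reps: int = 500,
    n_train: int = 48,
    n_test: int = 1000,
    config: SimulationConfig | None = None,
    seed: int = 0,
    params: CutPointParams = CutPointParams(),
) -> dict:
    """Empirical false-positive rate of a screening cut-point estimator.

    For each replication a fresh ADA-negative training set of ``n_train``
    donors fixes the cut point (``method`` = ``"parametric"`` for the
    untreated route, ``"nonparametric"`` for the immune-inhibited 95th-
    percentile route), and ``n_test`` independent negatives from the same
    null distribution are scored against it.  Returns the mean exceedance
    fraction across replications with its Monte-Carlo dispersion.
    """
    if method not in ("parametric", "nonparametric"):
        raise ValueError("method must be 'parametric' or 'nonparametric'")
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        train = _negative_training_frame(n_train, config, rng, "untreated")
        values = corrected_sample_means(train, "SaCas9", "untreated").to_numpy()
        if method == "parametric":
            cut = cutpoints.screening_cutpoint_untreated(values, params)
        else:
            cut = cutpoints.screening_cutpoint_inhibited(values, params)
        test = _negative_training_frame(n_test, config, rng, "untreated")
        test_values = corrected_sample_means(test, "SaCas9", "untreated").to_numpy()
        fractions[i] = float(np.mean(test_values > cut.cut_point))
    return {
        "method": method,
        "mean_fpr": float(fractions.mean()),
        "sd_fpr": float(fractions.std(ddof=1)),
        "se_mean": float(fractions.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
        "n_train": n_train,
        "n_test": n_test,
    }


def confirmed_rate_recovery(
    n_seeds: int = 200,
    config: SimulationConfig | None = None,
    seed: int = 0,
    method: str = report.WITH_INHIBITION,
) -> dict:
    """Mean confirmed-positive rate of the full pipeline over many studies.

    Each seeded study draws a fresh training set and survey population at
    the configured prevalences and runs the complete cascade.  Alongside
    the raw mean confirmed rate per antigen, the empirical screening and
    confirmatory false-call rates among true negatives are recorded, so
    the designed false-confirmation cascade (~alpha_screen x alpha_confirm
    of true negatives) can be accounted for when comparing against the
    configured prevalence.
    """
    config = SimulationConfig() if config is None else config
    rates: dict[str, list[float]] = {a: [] for a in plates.ANTIGENS}
    fp_screen: dict[str, list[float]] = {a: [] for a in plates.ANTIGENS}
    fp_confirm: dict[str, list[float]] = {a: [] for a in plates.ANTIGENS}
    sens: dict[str, list[float]] = {a: [] for a in plates.ANTIGENS}
    for k in range(n_seeds):
        cfg = replace(config, seed=seed + 1000 + k)
        result = run_study(cfg, titrate=False)
        truth = {
            d.donor_id: {"SaCas9": d.seropositive_sa, "SpCas9": d.seropositive_sp}
            for d in result.donors
        }
        for antigen in plates.ANTIGENS:
            oc = [o for o in result.outcomes[method] if o.antigen == antigen]
            confirmed = np.array([bool(o.confirmed_positive) for o in oc])
            screened = np.array([o.screen_positive for o in oc])
            is_pos = np.array([truth[o.donor_id][antigen] for o in oc])
            rates[antigen].append(float(confirmed.mean()))
            if (~is_pos).any():
                fp_screen[antigen].append(float(screened[~is_pos].mean()))
                fp_confirm[antigen].append(float(confirmed[~is_pos].mean()))
            if is_pos.any():
                sens[antigen].append(float(confirmed[is_pos].mean()))
    out = {"n_seeds": n_seeds, "n_donors": config.n_donors, "method": method}
    for antigen in plates.ANTIGENS:
        r = np.asarray(rates[antigen])
        out[antigen] = {
            "configured_prevalence": config.prevalence(antigen),
            "mean_confirmed_rate": float(r.mean()),
            "se_mean": float(r.std(ddof=1) / np.sqrt(n_seeds)),
            "mean_screen_fp_rate": float(np.mean(fp_screen[antigen])),
            "mean_false_confirm_rate": float(np.mean(fp_confirm[antigen])),
            "mean_sensitivity": float(np.mean(sens[antigen])) if sens[antigen] else float("nan"),
        }
    return out
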
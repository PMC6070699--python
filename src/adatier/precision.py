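"""Assay-precision evaluation and the fixed-vs-floating cut-point decision.

The validation design reads every training sample in triplicate under
every analyst x plate-reader combination (48 samples x 3 replicates x 2
analysts x 2 machines = 576 wells), with run and plate position assigned
in balanced blocks.  Two questions are asked of each nuisance factor:

* do its levels shift the mean OD (one-way ANOVA), and
* do its levels change the OD spread (Levene's test, Brown-Forsythe
  median-centred variant)?

If every factor passes both at alpha = 0.05, a single fixed cut point is
justified; any failure calls for a floating (per-run normalised) cut
point, whose arithmetic is outside this package's scope.

How each factor is tested depends on where it sits in the design.  A
factor crossed within samples (analyst, machine: every sample is read
under every level) is tested on sample-centred ODs - each well minus its
sample mean - because the factor contrast would otherwise drown in
sample-to-sample variation sitting in the error term.  A factor constant
within samples (run, plate position: each sample occupies one level) is
tested on per-sample mean ODs, the nested-design error term.  The sample
term itself is tested by one-way ANOVA on the raw replicate data.  This
keeps every per-factor test calibrated: under a null generator the
p-values are uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import plates

FACTOR_COLUMNS = ("analyst", "machine", "run", "plate_position")

FIXED = "fixed"
FLOATING = "floating"
DEFERRED = "deferred"


@dataclass(frozen=True)
class PrecisionDesign:
    """The balanced factorial layout of the precision experiment."""

    factors: Mapping[str, Sequence[str]]
    crossed: Sequence[str] = ("analyst", "machine")
    n_samples: int = 48
    n_replicates: int = 3

    @property
    def total_measurements(self) -> int:
        total = self.n_samples * self.n_replicates
        for f in self.crossed:
            total *= len(self.factors[f])
        return total


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of the balance check; lists any deficient design cells."""

    balanced: bool
    total_measurements: int
    expected_measurements: int
    deficient_cells: tuple = ()


@dataclass(frozen=True)
class PrecisionReport:
    """Per-factor test p-values and the resulting cut-point decision."""

    anova_p: Mapping[str, float]
    levene_p: Mapping[str, float]
    sample_p: float | None
    decision: str
    alpha: float = 0.05
    notes: str = ""

    def __post_init__(self) -> None:
        for p in list(self.anova_p.values()) + list(self.levene_p.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


def check_balance(
    measurements: pd.DataFrame | Iterable[plates.PlateMeasurement],
    design: PrecisionDesign,
) -> BalanceReport:
    """Verify that every sample x crossed-factor cell has equal replicates.

    Returns a structured report; deficient cells are named as
    (sample, *crossed levels, observed count).
    """
    frame = plates.as_frame(measurements)
    if len(frame) == 0:
        raise ValueError("cannot check balance of an empty measurement set")
    keys = ["donor_id", *design.crossed]
    counts = frame.groupby(keys, sort=True).size()
    expected_cells = design.n_samples
    for f in design.crossed:
        expected_cells *= len(design.factors[f])
    deficient = [
        (*k, int(c)) if isinstance(k, tuple) else (k, int(c))
        for k, c in counts.items()
        if c != design.n_replicates
    ]
    if len(counts) != expected_cells:
        deficient.append(("missing-cells", expected_cells - len(counts)))
    return BalanceReport(
        balanced=not deficient and len(frame) == design.total_measurements,
        total_measurements=int(len(frame)),
        expected_measurements=design.total_measurements,
        deficient_cells=tuple(deficient),
    )


def decide_cutpoint_strategy(
    anova_p: Mapping[str, float],
    levene_p: Mapping[str, float],
    alpha: float = 0.05,
) -> str:
    """Fixed cut point iff every factor passes both homogeneity tests.

    Equal means (all ANOVA p > alpha) and equal variances (all Levene
    p > alpha) across analyst, machine, run and plate position justify one
    constant threshold; otherwise a floating cut point is indicated.
    """
    all_p = list(anova_p.values()) + list(levene_p.values())
    if not all_p:
        raise ValueError("no factor tests available to decide on")
    return FIXED if all(p > alpha for p in all_p) else FLOATING


def precision_tests(
    measurements: pd.DataFrame | Iterable[plates.PlateMeasurement],
    alpha: float = 0.05,
    design: PrecisionDesign | None = None,
) -> PrecisionReport:
    """Run the per-factor ANOVA / Levene battery and decide the strategy.

    Factors with a single observed level are skipped with a warning.  If
    the data are degenerate (zero variance) the tests are undefined and
    the decision is deferred to the analyst.
    """
    frame = plates.as_frame(measurements)
    if len(frame) == 0:
        raise ValueError("precision_tests needs a non-empty measurement set")
    if design is not None:
        report = check_balance(frame, design)
        if not report.balanced:
            warnings.warn(
                f"design is unbalanced ({len(report.deficient_cells)} deficient cells); "
                "p-values may be distorted"
            )
    od = frame["od450"].to_numpy(float)
    if np.ptp(od) == 0:
        return PrecisionReport(
            anova_p={},
            levene_p={},
            sample_p=None,
            decision=DEFERRED,
            alpha=alpha,
            notes="degenerate input: zero variance, Levene/ANOVA undefined",
        )
    centred = frame.assign(
        od_centred=od - frame.groupby("donor_id")["od450"].transform("mean").to_numpy(float)
    )
    anova_p: dict[str, float] = {}
    levene_p: dict[str, float] = {}
    notes = []
    for factor in FACTOR_COLUMNS:
        n_levels_within = int(frame.groupby("donor_id")[factor].nunique().max())
        if n_levels_within > 1:
            # crossed within samples: compare sample-centred wells
            groups = [
                g["od_centred"].to_numpy(float)
                for _, g in centred.groupby(factor, sort=True)
            ]
        else:
            # one level per sample (nested): compare per-sample mean ODs
            sample_means = frame.groupby(["donor_id", factor], sort=True)["od450"].mean()
            groups = [
                g.to_numpy(float)
                for _, g in sample_means.groupby(level=factor, sort=True)
            ]
        if len(groups) < 2:
            notes.append(f"factor {factor!r} has a single level; skipped")
            warnings.warn(notes[-1])
            continue
        anova_p[factor] = float(stats.f_oneway(*groups).pvalue)
        levene_p[factor] = float(stats.levene(*groups, center="median").pvalue)
    sample_groups = [
        g["od450"].to_numpy(float) for _, g in frame.groupby("donor_id", sort=True)
    ]
    sample_p = (
        float(stats.f_oneway(*sample_groups).pvalue) if len(sample_groups) > 1 else None
    )
    decision = decide_cutpoint_strategy(anova_p, levene_p, alpha)
    return PrecisionReport(
        anova_p=anova_p,
        levene_p=levene_p,
        sample_p=sample_p,
        decision=decision,
        alpha=alpha,
        notes="; ".join(notes),
    )
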
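"""Tiered donor classification: screen -> confirm -> titer -> isotype.

Tier 1 (screen) flags a sample whose blank-corrected mean OD is strictly
above the screening cut point.  Tier 2 (confirm) establishes specificity:
the screen-positive sample is re-assayed with and without excess free
antigen, and is confirmed when the percent inhibition is strictly above
the confirmatory cut point.  Confirmed positives are serially titrated
(4-fold) and the endpoint titer is the highest reciprocal dilution whose
OD stays strictly above the titration plate's blank mean + 2 SD.  Isotype
calls (IgG1-IgG4) are annotations supplied with the data, summarised over
confirmed positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .cutpoints import (
    CONFIRMATORY_LINEAR,
    SCREENING_METHODS,
    CutPointResult,
    percent_inhibition,
)
from .plates import BlankSummary, SampleResult

ISOTYPES = ("IgG1", "IgG2", "IgG3", "IgG4")


class MethodMismatchError(ValueError):
    """A cut point of the wrong method was supplied to a tier."""


@dataclass(frozen=True)
class DonorOutcome:
    """Screen/confirm/titer/isotype status of one donor x antigen."""

    donor_id: str
    antigen: str
    screen_od: float
    screen_positive: bool
    percent_inhibition: float | None = None
    confirmed_positive: bool | None = None
    titer: int | None = None
    isotype: str | None = None

    def __post_init__(self) -> None:
        if self.confirmed_positive is not None and not self.screen_positive:
            raise ValueError("confirmation applies only to screen-positive donors")
        if self.titer is not None and not self.confirmed_positive:
            raise ValueError("titers apply only to confirmed-positive donors")
        if self.isotype is not None and self.isotype not in ISOTYPES:
            raise ValueError(f"unknown isotype {self.isotype!r}")


@dataclass(frozen=True)
class TiterSeries:
    """A 4-fold endpoint-titration series with its plate blank."""

    dilutions: Sequence[int]
    ods: Sequence[float]
    blank: BlankSummary

    def __post_init__(self) -> None:
        if len(self.dilutions) != len(self.ods):
            raise ValueError("dilutions and ods must have equal length")
        if len(self.dilutions) == 0:
            raise ValueError("empty titration series")
        d = list(self.dilutions)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("dilutions must be strictly increasing")


def screen(sample: SampleResult, cut_point: CutPointResult) -> bool:
    """Tier-1 call: positive iff mean OD is strictly above the cut point."""
    if cut_point.method not in SCREENING_METHODS:
        raise MethodMismatchError(
            f"screening requires a screening cut point, got {cut_point.method!r}"
        )
    return sample.mean_od > cut_point.cut_point


def confirm(
    untreated: SampleResult,
    inhibited: SampleResult,
    cut_point: CutPointResult,
) -> tuple[float, bool]:
    """Tier-2 call: percent inhibition and whether it exceeds the cut point.

    Both the untreated and the antigen-inhibited condition must belong to
    the same donor and antigen.
    """
    if cut_point.method != CONFIRMATORY_LINEAR:
        raise MethodMismatchError(
            f"confirmation requires a confirmatory cut point, got {cut_point.method!r}"
        )
    if (untreated.donor_id, untreated.antigen) != (inhibited.donor_id, inhibited.antigen):
        raise ValueError(
            f"paired conditions do not match: {untreated.donor_id}/{untreated.antigen} "
            f"vs {inhibited.donor_id}/{inhibited.antigen}"
        )
    pi = percent_inhibition(untreated.mean_od, inhibited.mean_od)
    return pi, pi > cut_point.cut_point


def determine_titer(series: TiterSeries) -> int | None:
    """Endpoint titer: highest dilution with OD strictly above blank + 2 SD.

    Returns ``None`` when no dilution clears the threshold (including when
    the first dilution already fails).
    """
    threshold = series.blank.mean_blank + 2.0 * series.blank.sd_blank
    qualifying = [
        int(d) for d, od in zip(series.dilutions, series.ods) if od > threshold
    ]
    return max(qualifying) if qualifying else None


def summarize_isotypes(outcomes: Iterable[DonorOutcome]) -> dict[str, float]:
    """Percentage of each IgG isotype among isotyped confirmed positives.

    All four isotypes are always reported, including 0% entries.  Returns
    an empty map (with a warning) when no donor carries an isotype call.
    """
    calls = [
        o.isotype for o in outcomes if o.confirmed_positive and o.isotype is not None
    ]
    if not calls:
        warnings.warn("no isotyped confirmed-positive donors; empty isotype summary")
        return {}
    n = len(calls)
    return {iso: 100.0 * calls.count(iso) / n for iso in ISOTYPES}


def classify_donor(
    untreated: SampleResult,
    inhibited: SampleResult | None,
    screening_cut: CutPointResult,
    confirmatory_cut: CutPointResult,
) -> DonorOutcome:
    """Run one donor x antigen through the screen -> confirm cascade.

    A screen-negative donor stops at tier 1.  A screen-positive donor
    requires the paired inhibited condition; its absence is an error
    naming the donor.
    """
    positive = screen(untreated, screening_cut)
    if not positive:
        return DonorOutcome(
            donor_id=str(untreated.donor_id),
            antigen=untreated.antigen,
            screen_od=untreated.mean_od,
            screen_positive=False,
        )
    if inhibited is None:
        raise ValueError(
            f"donor {untreated.donor_id} ({untreated.antigen}) is screen-positive "
            "but has no antigen-inhibited condition for confirmation"
        )
    pi, confirmed = confirm(untreated, inhibited, confirmatory_cut)
    return DonorOutcome(
        donor_id=str(untreated.donor_id),
        antigen=untreated.antigen,
        screen_od=untreated.mean_od,
        screen_positive=True,
        percent_inhibition=pi,
        confirmed_positive=confirmed,
    )


def classify_population(
    samples: Sequence[SampleResult],
    screening_cut: CutPointResult,
    confirmatory_cut: CutPointResult,
    antigen: str,
) -> list[DonorOutcome]:
    """Classify every donor of one antigen from aggregated sample results.

    ``samples`` holds the blank-corrected per-sample results of both the
    untreated and inhibited conditions at the screening dilution.
    """
    unt = {
        s.donor_id: s
        for s in samples
        if s.antigen == antigen and s.condition == "untreated"
    }
    inh = {
        s.donor_id: s
        for s in samples
        if s.antigen == antigen and s.condition == "inhibited"
    }
    return [
        classify_donor(unt[d], inh.get(d), screening_cut, confirmatory_cut)
        for d in sorted(unt)
    ]


def with_titer(outcome: DonorOutcome, titer: int | None) -> DonorOutcome:
    """Attach an endpoint titer to a confirmed-positive outcome."""
    return replace(outcome, titer=titer)
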
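"""Screening and confirmatory cut-point statistics.

A cut point is the assay threshold above which a sample is called
positive, set so that true negatives exceed it at a designed rate (5%
here).  Three estimators are implemented, mirroring tiered ADA practice:

* ``screening_cutpoint_untreated`` - parametric, on drug-naive sera:
  log-transform, check normality (Shapiro-Wilk), drop 1.5 x IQR outliers
  on the log scale, then exp(mean + 1.645 x SD) of the retained logs.
  When the transformed data still fail normality (p <= 0.10) the
  estimator falls back to the nonparametric 95th percentile and records
  that in the result notes.
* ``screening_cutpoint_inhibited`` - nonparametric, on sera pre-incubated
  with excess antigen so that pre-existing specific antibodies cannot
  inflate the threshold: 1.5 x IQR outlier removal on the raw scale, then
  the 95th percentile.
* ``confirmatory_cutpoint`` - on percent-inhibition values: outlier
  removal, then mean + 1.645 x SD without transformation.

Percentiles and quartiles use linear interpolation of order statistics at
position 1 + p(n-1); outlier removal is a single pass.  Ties at the cut
point classify as negative downstream (strictly-greater rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Methods a CutPointResult can carry.
PARAMETRIC_LOG = "parametric_log"
NONPARAMETRIC_P95 = "nonparametric_p95"
CONFIRMATORY_LINEAR = "confirmatory_linear"
SCREENING_METHODS = frozenset({PARAMETRIC_LOG, NONPARAMETRIC_P95})


@dataclass(frozen=True)
class CutPointParams:
    """Tunable constants of the cut-point estimators.

    ``z_multiplier`` = 1.645 targets a one-sided type-I error of 5% under
    normality; ``normality_alpha`` = 0.10 is the Shapiro-Wilk gate for the
    parametric route; ``outlier_fence`` = 1.5 is the IQR multiplier.
    """

    alpha: float = 0.05
    z_multiplier: float = 1.645
    normality_alpha: float = 0.10
    outlier_fence: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.outlier_fence <= 0:
            raise ValueError("outlier_fence must be positive")


@dataclass(frozen=True)
class CutPointResult:
    """A cut point with its method and diagnostics."""

    cut_point: float
    method: str
    n_input: int
    n_outliers_removed: int
    shapiro_p_raw: float | None = None
    shapiro_p_transformed: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.cut_point):
            raise ValueError("cut_point must be finite")
        if self.n_outliers_removed >= self.n_input:
            raise ValueError("cannot remove all input values as outliers")


def percentile(values, p: float) -> float:
    """Percentile by linear interpolation at position 1 + p(n-1)."""
    return float(np.quantile(np.asarray(values, float), p, method="linear"))


def remove_iqr_outliers(values, fence: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey-fence outlier removal.

    Removes x outside the closed interval [Q1 - fence*IQR, Q3 + fence*IQR],
    quartiles by linear interpolation of order statistics.  Requires >= 4
    values.  Returns (retained, removed).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"outlier removal needs >= 4 values, got {x.size}")
    if fence <= 0:
        raise ValueError("fence must be positive")
    q1, q3 = percentile(x, 0.25), percentile(x, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - fence * iqr, q3 + fence * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


def assess_normality(values) -> float:
    """Shapiro-Wilk p-value; raises on constant input (test undefined)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs >= 3 values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-n p-value accuracy warning
        return float(stats.shapiro(x).pvalue)


def _shapiro_or_none(x: np.ndarray) -> float | None:
    try:
        return assess_normality(x)
    except ValueError:
        return None


def _check_screening_input(x: np.ndarray) -> None:
    if x.size < 10:
        raise ValueError(f"cut-point estimation needs >= 10 samples, got {x.size}")
    if x.size < 48:
        warnings.warn(
            f"cut point estimated from only {x.size} samples; the validation "
            "design uses a 48-donor training set"
        )


def _nonparametric(x: np.ndarray, params: CutPointParams) -> tuple[float, int]:
    retained, removed = remove_iqr_outliers(x, params.outlier_fence)
    return percentile(retained, 1.0 - params.alpha), removed.size


def screening_cutpoint_untreated(
    values, params: CutPointParams = CutPointParams()
) -> CutPointResult:
    """Parametric screening cut point from untreated drug-naive sera.

    Pipeline: natural-log transform -> Shapiro-Wilk on the transformed
    data (recorded alongside the raw-scale p) -> single-pass IQR outlier
    removal on the log scale -> exp(mean + z x SD) of the retained logs.
    If the transformed data fail normality (p <= ``normality_alpha``) the
    nonparametric 95th-percentile estimator is used instead and the
    fallback is noted.  Values must be positive (blank-corrected ODs are
    floored upstream).
    """
    x = np.asarray(values, dtype=float)
    _check_screening_input(x)
    if np.any(x <= 0):
        raise ValueError("all ODs must be positive (flooring should precede this step)")
    logs = np.log(x)
    p_raw = _shapiro_or_none(x)
    p_log = _shapiro_or_none(logs)
    notes = []
    if p_log is None:
        notes.append("normality not assessable (constant input)")
    if p_log is not None and p_log <= params.normality_alpha:
        cut, n_removed = _nonparametric(x, params)
        notes.append(
            f"log-transform failed normality (Shapiro p={p_log:.4g} <= "
            f"{params.normality_alpha}); fell back to the 95th percentile"
        )
        return CutPointResult(
            cut_point=cut,
            method=NONPARAMETRIC_P95,
            n_input=x.size,
            n_outliers_removed=n_removed,
            shapiro_p_raw=p_raw,
            shapiro_p_transformed=p_log,
            notes="; ".join(notes),
        )
    retained, removed = remove_iqr_outliers(logs, params.outlier_fence)
    sd = float(np.std(retained, ddof=1)) if retained.size > 1 else 0.0
    cut = float(np.exp(np.mean(retained) + params.z_multiplier * sd))
    return CutPointResult(
        cut_point=cut,
        method=PARAMETRIC_LOG,
        n_input=x.size,
        n_outliers_removed=removed.size,
        shapiro_p_raw=p_raw,
        shapiro_p_transformed=p_log,
        notes="; ".join(notes),
    )


def screening_cutpoint_inhibited(
    values, params: CutPointParams = CutPointParams()
) -> CutPointResult:
    """Nonparametric screening cut point from immune-inhibited sera.

    Raw-scale IQR outlier removal, then the 95th percentile (linear
    interpolation of order statistics) of the retained values.
    """
    x = np.asarray(values, dtype=float)
    _check_screening_input(x)
    cut, n_removed = _nonparametric(x, params)
    return CutPointResult(
        cut_point=cut,
        method=NONPARAMETRIC_P95,
        n_input=x.size,
        n_outliers_removed=n_removed,
        shapiro_p_raw=_shapiro_or_none(x),
    )


def percent_inhibition(od_untreated: float, od_inhibited: float) -> float:
    """Percentage decrease in blank-corrected OD due to excess antigen.

    100 x (untreated - inhibited) / untreated.  Negative values (signal
    enhancement) are retained as negative; the untreated OD must be
    positive.
    """
    if od_untreated <= 0:
        raise ValueError("untreated OD must be positive (blank-corrected, floored)")
    return 100.0 * (od_untreated - od_inhibited) / od_untreated


def confirmatory_cutpoint(
    inhibitions, params: CutPointParams = CutPointParams()
) -> CutPointResult:
    """Confirmatory cut point on percent-inhibition values.

    IQR outlier removal on the percent scale, then mean + z x SD of the
    retained values - no transformation.
    """
    x = np.asarray(inhibitions, dtype=float)
    _check_screening_input(x)
    retained, removed = remove_iqr_outliers(x, params.outlier_fence)
    sd = float(np.std(retained, ddof=1)) if retained.size > 1 else 0.0
    cut = float(np.mean(retained) + params.z_multiplier * sd)
    return CutPointResult(
        cut_point=cut,
        method=CONFIRMATORY_LINEAR,
        n_input=x.size,
        n_outliers_removed=removed.size,
        shapiro_p_raw=_shapiro_or_none(x),
    )
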
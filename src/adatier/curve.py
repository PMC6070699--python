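"""Concentration-response modelling for the anti-Cas9 ELISA.

The response model is the four-parameter logistic (4PL) on log
concentration, the immunoassay standard:

    OD(c) = A + (D - A) / (1 + (C / c)^B)

with lower asymptote ``A``, upper asymptote ``D``, mid-response
concentration ``C`` (EC50, ng/mL) and Hill slope ``B``.  For ``B > 0`` the
curve rises monotonically from A (zero antibody) towards D (saturation).

Three questions are answered here:

* what are the curve parameters for a standard series (``fit_4pl``);
* which standards quantify reliably, i.e. the LLOQ/ULOQ and the OD span
  between them (``determine_loq``) - the LLOQ is the assay sensitivity;
* what is the minimum required serum dilution, the smallest dilution whose
  in-serum dynamic range retains at least 80% of the serum-free dynamic
  range (``determine_mrd``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .plates import SampleResult


class FitError(RuntimeError):
    """The 4PL optimiser failed to converge."""


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of the four-parameter logistic concentration-response."""

    lower_asymptote: float
    upper_asymptote: float
    ec50: float
    hill_slope: float

    def __post_init__(self) -> None:
        if not self.upper_asymptote > self.lower_asymptote:
            raise ValueError("upper_asymptote must exceed lower_asymptote")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")

    def __call__(self, conc) -> np.ndarray | float:
        """Evaluate the curve; conc may be scalar or array, zeros allowed."""
        c = np.asarray(conc, dtype=float)
        a, d, c50, b = self.lower_asymptote, self.upper_asymptote, self.ec50, self.hill_slope
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(c > 0, (c50 / np.where(c > 0, c, 1.0)) ** b, np.inf)
        out = a + (d - a) / (1.0 + ratio)
        return float(out) if np.isscalar(conc) else out

    def inverse(self, od) -> np.ndarray | float:
        """Back-calculate concentration from OD (defined strictly inside (A, D))."""
        y = np.asarray(od, dtype=float)
        a, d, c50, b = self.lower_asymptote, self.upper_asymptote, self.ec50, self.hill_slope
        frac = (d - a) / (y - a) - 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(frac > 0, c50 * frac ** (-1.0 / b), np.nan)
        return float(out) if np.isscalar(od) else out


@dataclass(frozen=True)
class CurveQC:
    """Quantitation limits and dynamic range of a fitted standard curve.

    ``lloq``/``uloq`` are the lowest/highest standards passing both QC
    rules (back-calculated recovery within the band, replicate CV within
    the limit); ``None`` when no standard qualifies.  ``dynamic_range_od``
    is the fitted OD span between the responses at ULOQ and LLOQ - the
    quantity the 80% matrix-interference rule compares.
    """

    lloq: float | None
    uloq: float | None
    dynamic_range_od: float | None
    residual_rms: float

    def __post_init__(self) -> None:
        if self.lloq is not None and self.uloq is not None and self.lloq > self.uloq:
            raise ValueError("lloq must not exceed uloq")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    @property
    def qualified(self) -> bool:
        return self.lloq is not None and self.uloq is not None


@dataclass(frozen=True)
class MRDResult:
    """Outcome of the minimum-required-dilution rule."""

    mrd: int | None
    retention_by_dilution: Mapping[int, float]
    retention_threshold: float
    monotone: bool
    note: str = ""


def _standards_arrays(standards: Sequence[SampleResult]):
    recs = sorted(
        (s for s in standards if s.spiked_conc is not None and s.spiked_conc > 0),
        key=lambda s: s.spiked_conc,
    )
    if not recs:
        raise ValueError("no standards with a positive spiked concentration")
    conc = np.array([s.spiked_conc for s in recs], float)
    od = np.array([s.mean_od for s in recs], float)
    return recs, conc, od


def fit_4pl(standards: Sequence[SampleResult]) -> tuple[FourPLParams, CurveQC]:
    """Least-squares 4PL fit of a standard series, plus curve QC.

    Fitting is on untransformed OD against log-spaced concentrations.
    Starting values come from the data extremes and the mid-response point;
    the EC50 is bounded inside the tested concentration range x [0.01, 100]
    so the optimum stays identifiable.

    Requires >= 5 distinct concentrations.  Raises :class:`FitError` with
    diagnostics on non-convergence; non-monotone points are tolerated as
    noise.
    """
    recs, conc, od = _standards_arrays(standards)
    if len(np.unique(conc)) < 5:
        raise ValueError(
            f"4PL fit needs >= 5 distinct concentrations, got {len(np.unique(conc))}"
        )

    a0 = float(od.min())
    d0 = float(od.max())
    mid_od = (a0 + d0) / 2.0
    c0 = float(conc[np.argmin(np.abs(od - mid_od))])
    p0 = [a0, d0, np.log(c0), 1.0]
    lo = [-1.0, a0, np.log(conc.min() * 0.01), 0.05]
    hi = [d0, d0 * 10 + 1.0, np.log(conc.max() * 100.0), 20.0]

    def model(c, a, d, log_c50, b):
        return a + (d - a) / (1.0 + (np.exp(log_c50) / c) ** b)

    try:
        popt, _ = curve_fit(model, conc, od, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - hard to force with valid input
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    params = FourPLParams(
        lower_asymptote=float(popt[0]),
        upper_asymptote=float(popt[1]),
        ec50=float(np.exp(popt[2])),
        hill_slope=float(popt[3]),
    )
    qc = determine_loq(recs, params)
    return params, qc


def determine_loq(
    standards: Sequence[SampleResult],
    fit: FourPLParams,
    recovery_band: tuple[float, float] = (0.80, 1.20),
    cv_limit: float = 0.20,
) -> CurveQC:
    """Find the LLOQ/ULOQ and the OD dynamic range of a fitted curve.

    A standard qualifies when its back-calculated concentration recovers
    within ``recovery_band`` (default 80-120%) of nominal and its replicate
    CV is <= ``cv_limit`` (default 20%).  The LLOQ is the lowest qualifying
    standard scanning upward; the ULOQ the highest scanning downward.  When
    nothing qualifies, both are ``None`` and a warning is emitted.
    """
    recs, conc, od = _standards_arrays(standards)
    back = fit.inverse(od)
    with np.errstate(invalid="ignore"):
        recovery = back / conc
    cvs = np.array(
        [s.sd_od / s.mean_od if s.mean_od else np.inf for s in recs], float
    )
    ok = (
        np.isfinite(recovery)
        & (recovery >= recovery_band[0])
        & (recovery <= recovery_band[1])
        & (cvs <= cv_limit)
    )
    resid = od - np.asarray(fit(conc))
    rms = float(np.sqrt(np.mean(resid**2)))
    if not ok.any():
        warnings.warn("no standard passes the LOQ qualification rules; LLOQ undefined")
        return CurveQC(lloq=None, uloq=None, dynamic_range_od=None, residual_rms=rms)
    lloq = float(conc[np.argmax(ok)])
    uloq = float(conc[len(ok) - 1 - np.argmax(ok[::-1])])
    dr = float(fit(uloq) - fit(lloq))
    return CurveQC(lloq=lloq, uloq=uloq, dynamic_range_od=dr, residual_rms=rms)


def determine_mrd(
    serum_curves: Mapping[int, CurveQC],
    buffer_curve: CurveQC,
    retention: float = 0.80,
) -> MRDResult:
    """Apply the 80%-of-dynamic-range rule to per-dilution serum curves.

    The MRD is the smallest reciprocal serum dilution whose in-serum OD
    dynamic range is at least ``retention`` of the serum-free (buffer)
    dynamic range.  Retention is expected to increase with dilution as the
    matrix is diluted out; if it does not, the smallest qualifying dilution
    is still returned, with a warning note.  When no dilution qualifies the
    result carries ``mrd=None``.
    """
    if len(serum_curves) < 2:
        raise ValueError("determine_mrd needs >= 2 tested dilutions")
    if buffer_curve.dynamic_range_od is None or buffer_curve.dynamic_range_od <= 0:
        raise ValueError("buffer curve has no usable dynamic range")
    ratios: dict[int, float] = {}
    for d in sorted(serum_curves):
        qc = serum_curves[d]
        dr = qc.dynamic_range_od if qc.dynamic_range_od is not None else 0.0
        ratios[int(d)] = dr / buffer_curve.dynamic_range_od
    vals = [ratios[d] for d in sorted(ratios)]
    monotone = all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    note = "" if monotone else "retention is not monotone in dilution"
    if note:
        warnings.warn(note)
    # tiny tolerance so exact-by-construction 80% retention is not lost to rounding
    qualifying = [d for d in sorted(ratios) if ratios[d] >= retention - 1e-9]
    if not qualifying:
        return MRDResult(None, ratios, retention, monotone, note or "no dilution retains the required dynamic range")
    return MRDResult(qualifying[0], ratios, retention, monotone, note)
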
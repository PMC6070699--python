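"""Plate-reader data model: well-level records, CSV ingestion, blank
subtraction, and replicate aggregation.

The unit of raw data is one 96-well ELISA well read at 450 nm.  Every well
carries its full experimental annotation (donor, antigen, treatment
condition, serum dilution, replicate, and the nuisance factors analyst /
machine / run / plate position).  Each plate carries a set of serum-free
blank wells (the protocol implies quadruplicate); their mean is subtracted
from every experimental well on the same plate before replicates are
averaged.  The ``run`` column doubles as the plate identifier: one run is
one plate, and blanks are never shared across runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANTIGENS = ("SaCas9", "SpCas9")
CONDITIONS = ("untreated", "inhibited", "blank", "standard")

#: Canonical tidy-CSV column order, one well per row.
PLATE_COLUMNS = (
    "donor_id",
    "antigen",
    "condition",
    "spiked_conc",
    "serum_dilution",
    "replicate",
    "analyst",
    "machine",
    "run",
    "plate_position",
    "od450",
)

#: Floor applied to blank-corrected ODs so the log transform downstream is
#: always defined (corrected values <= 0 are clamped here).
OD_FLOOR = 0.001


class SchemaError(ValueError):
    """A required column is missing from a plate table."""


class PlateParseError(ValueError):
    """A row of a plate table could not be parsed."""


class ConfigurationError(ValueError):
    """Inputs are structurally inconsistent with the requested operation."""


@dataclass(frozen=True)
class PlateMeasurement:
    """One well's OD450 reading with full experimental annotation."""

    donor_id: str | None
    antigen: str
    condition: str
    spiked_conc: float | None
    serum_dilution: int
    replicate: int
    analyst: str
    machine: str
    run: str
    plate_position: str
    od450: float

    def __post_init__(self) -> None:
        if self.antigen not in ANTIGENS:
            raise ValueError(f"unknown antigen {self.antigen!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not math.isfinite(self.od450):
            raise ValueError("od450 must be finite")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.serum_dilution < 1:
            raise ValueError("serum_dilution must be >= 1")
        if self.spiked_conc is not None and self.spiked_conc < 0:
            raise ValueError("spiked_conc must be non-negative")
        if self.condition == "blank" and self.donor_id:
            raise ValueError("blank wells carry no donor_id")


@dataclass(frozen=True)
class SampleResult:
    """Blank-corrected mean OD and replicate dispersion for one sample.

    One record per (donor, antigen, condition, dilution) group.  ``sd_od``
    uses the unbiased (n-1) denominator, the assay-validation convention.
    """

    donor_id: str | None
    antigen: str
    condition: str
    serum_dilution: int
    mean_od: float
    sd_od: float
    n_replicates: int
    spiked_conc: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd_od < 0:
            raise ValueError("sd_od must be non-negative")

    @property
    def cv(self) -> float:
        """Replicate coefficient of variation (nan when mean is 0)."""
        return self.sd_od / self.mean_od if self.mean_od else float("nan")


@dataclass(frozen=True)
class BlankSummary:
    """Per-plate blank statistics (mean, SD, count of serum-free wells)."""

    plate_id: str
    mean_blank: float
    sd_blank: float
    n_blanks: int

    def __post_init__(self) -> None:
        if self.n_blanks < 1:
            raise ValueError("n_blanks must be >= 1")
        if self.sd_blank < 0:
            raise ValueError("sd_blank must be non-negative")


# ---------------------------------------------------------------------------
# Frame <-> record interop


def as_frame(measurements: pd.DataFrame | Iterable[PlateMeasurement]) -> pd.DataFrame:
    """Coerce a collection of :class:`PlateMeasurement` to a tidy DataFrame.

    DataFrames pass through after a column check, so the vectorised pipeline
    and the record-level API interoperate freely.
    """
    if isinstance(measurements, pd.DataFrame):
        missing = [c for c in PLATE_COLUMNS if c not in measurements.columns]
        if missing:
            raise SchemaError(f"plate table is missing column(s): {', '.join(missing)}")
        return measurements
    rows = [
        {f.name: getattr(m, f.name) for f in fields(PlateMeasurement)}
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def to_measurements(frame: pd.DataFrame) -> list[PlateMeasurement]:
    """Validate every row of a tidy frame into :class:`PlateMeasurement`."""
    out = []
    for _, row in frame.iterrows():
        donor = row["donor_id"]
        spiked = row["spiked_conc"]
        out.append(
            PlateMeasurement(
                donor_id=None if donor is None or (isinstance(donor, float) and math.isnan(donor)) or donor == "" else str(donor),
                antigen=str(row["antigen"]),
                condition=str(row["condition"]),
                spiked_conc=None if spiked is None or (isinstance(spiked, float) and math.isnan(spiked)) or spiked == "" else float(spiked),
                serum_dilution=int(row["serum_dilution"]),
                replicate=int(row["replicate"]),
                analyst=str(row["analyst"]),
                machine=str(row["machine"]),
                run=str(row["run"]),
                plate_position=str(row["plate_position"]),
                od450=float(row["od450"]),
            )
        )
    return out


def read_plate_table(path) -> list[PlateMeasurement]:
    """Read a tidy plate CSV into validated :class:`PlateMeasurement` records.

    The file must be UTF-8, comma-delimited, one well per row, with the
    columns in :data:`PLATE_COLUMNS` (empty string = not applicable).

    Raises
    ------
    SchemaError
        if a required column is absent (the error names the column).
    PlateParseError
        if a row's OD (or another numeric field) cannot be parsed; the
        error cites the offending row index (0-based, data rows).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"plate table is missing column(s): {', '.join(missing)}")
    records: list[PlateMeasurement] = []
    for i, row in raw.iterrows():
        od_text = row["od450"].strip()
        od = pd.to_numeric(od_text, errors="coerce")
        if pd.isna(od) or not math.isfinite(float(od)):
            raise PlateParseError(f"row {i}: od450 value {od_text!r} is not a finite number")
        try:
            records.append(
                PlateMeasurement(
                    donor_id=row["donor_id"] or None,
                    antigen=row["antigen"],
                    condition=row["condition"],
                    spiked_conc=float(row["spiked_conc"]) if row["spiked_conc"] else None,
                    serum_dilution=int(row["serum_dilution"]) if row["serum_dilution"] else 1,
                    replicate=int(row["replicate"]) if row["replicate"] else 1,
                    analyst=row["analyst"],
                    machine=row["machine"],
                    run=row["run"],
                    plate_position=row["plate_position"],
                    od450=float(od),
                )
            )
        except (TypeError, ValueError) as exc:
            raise PlateParseError(f"row {i}: {exc}") from exc
    return records


def write_plate_table(measurements: pd.DataFrame | Iterable[PlateMeasurement], path) -> None:
    """Write measurements to the tidy CSV dialect of :func:`read_plate_table`."""
    frame = as_frame(measurements).copy()
    frame = frame.reindex(columns=list(PLATE_COLUMNS))
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Blank subtraction and replicate aggregation


def blank_summary(measurements: pd.DataFrame | Iterable[PlateMeasurement], plate_id: str) -> BlankSummary:
    """Summarise the serum-free blank wells of one plate (= one run)."""
    frame = as_frame(measurements)
    blanks = frame[(frame["condition"] == "blank") & (frame["run"] == plate_id)]
    if blanks.empty:
        raise ConfigurationError(f"plate {plate_id!r} has no blank wells")
    vals = blanks["od450"].to_numpy(float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return BlankSummary(plate_id=plate_id, mean_blank=float(vals.mean()), sd_blank=sd, n_blanks=len(vals))


def subtract_blank(
    measurements: pd.DataFrame | Iterable[PlateMeasurement],
    blanks: BlankSummary,
    floor: float = OD_FLOOR,
) -> pd.DataFrame:
    """Subtract a plate's mean blank OD from its experimental wells.

    Corrected ODs <= 0 are floored at ``floor`` so the log transform used by
    the parametric cut point is always defined.  Blank wells are excluded
    from the output.  Wells from other plates are rejected.
    """
    frame = as_frame(measurements)
    if len(frame) == 0:
        return frame.copy()
    on_plate = frame["run"] == blanks.plate_id
    experimental = frame[on_plate & (frame["condition"] != "blank")].copy()
    foreign = frame[~on_plate]
    if len(foreign):
        raise ConfigurationError(
            f"measurements from plate(s) {sorted(set(foreign['run']))} do not match blank plate {blanks.plate_id!r}"
        )
    corrected = experimental["od450"].to_numpy(float) - blanks.mean_blank
    experimental["od450"] = np.where(corrected <= 0, floor, corrected)
    return experimental


def blank_correct(measurements: pd.DataFrame | Iterable[PlateMeasurement], floor: float = OD_FLOOR) -> pd.DataFrame:
    """Blank-correct a multi-plate table, one :class:`BlankSummary` per run."""
    frame = as_frame(measurements)
    parts = []
    for run, plate in frame.groupby("run", sort=False):
        parts.append(subtract_blank(plate, blank_summary(plate, str(run)), floor=floor))
    if not parts:
        return frame.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


GROUP_KEYS = ["donor_id", "antigen", "condition", "serum_dilution"]


def aggregate_replicates(
    measurements: pd.DataFrame | Iterable[PlateMeasurement],
) -> list[SampleResult]:
    """Average replicate wells into per-sample results.

    Groups by (donor, antigen, condition, dilution); the mean and the
    unbiased SD of the replicate ODs are recorded with the replicate count.
    The result is independent of input row order.  Standards (which carry a
    spiked concentration instead of a donor) group by concentration as well.
    """
    frame = as_frame(measurements)
    if len(frame) == 0:
        warnings.warn("aggregate_replicates: empty input, nothing to aggregate")
        return []
    keys = list(GROUP_KEYS)
    if frame["spiked_conc"].notna().any():
        keys.append("spiked_conc")
    results = []
    for key, grp in frame.groupby(keys, dropna=False, sort=True):
        vals = grp["od450"].to_numpy(float)
        if len(vals) == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"group {key} has no rows; skipped")
            continue
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        donor = rec.get("donor_id")
        spiked = rec.get("spiked_conc")
        results.append(
            SampleResult(
                donor_id=None if donor is None or (isinstance(donor, float) and math.isnan(donor)) else str(donor),
                antigen=str(rec["antigen"]),
                condition=str(rec["condition"]),
                serum_dilution=int(rec["serum_dilution"]),
                mean_od=float(vals.mean()),
                sd_od=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                n_replicates=int(len(vals)),
                spiked_conc=None if spiked is None or (isinstance(spiked, float) and math.isnan(spiked)) else float(spiked),
            )
        )
    return results


def sample_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    """Tabulate :class:`SampleResult` records (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "donor_id": r.donor_id,
                "antigen": r.antigen,
                "condition": r.condition,
                "serum_dilution": r.serum_dilution,
                "spiked_conc": r.spiked_conc,
                "mean_od": r.mean_od,
                "sd_od": r.sd_od,
                "n_replicates": r.n_replicates,
            }
            for r in results
        ]
    )
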
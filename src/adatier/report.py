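"""Stratified prevalence and titer tables from donor outcomes.

The survey deliverables are three tables: the donor demographic summary,
the stratified screening/confirmed prevalence per antigen and cut-point
method (counts with one-decimal percentages), and the endpoint-titer
distribution among confirmed positives.  Consistency is enforced rather
than assumed: stratum counts must sum to the total row on every
demographic axis, and confirmed counts can never exceed screening counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tiers import DonorOutcome

WITHOUT_INHIBITION = "without_inhibition"
WITH_INHIBITION = "with_inhibition"
METHODS = (WITHOUT_INHIBITION, WITH_INHIBITION)
TIERS = ("screening", "confirmed")

#: demographic axis name -> column in the demographics table
AXES = {"race": "race", "gender": "gender", "age": "age_band"}

TOTAL = "Total"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceTable:
    """Tidy stratified prevalence: one row per stratum x antigen x method x tier."""

    frame: pd.DataFrame
    n_total: int

    def cell(self, axis: str, stratum: str, antigen: str, method: str, tier: str) -> tuple[int, float]:
        """(count, percent) of one table cell."""
        f = self.frame
        row = f[
            (f["axis"] == axis)
            & (f["stratum"] == stratum)
            & (f["antigen"] == antigen)
            & (f["method"] == method)
            & (f["tier"] == tier)
        ]
        if len(row) != 1:
            raise KeyError((axis, stratum, antigen, method, tier))
        return int(row["count"].iloc[0]), float(row["percent"].iloc[0])

    def validate(self) -> None:
        """Enforce axis-sum consistency and tier monotonicity."""
        f = self.frame
        totals = f[f["axis"] == "total"].set_index(["antigen", "method", "tier"])["count"]
        for axis in AXES:
            sums = (
                f[f["axis"] == axis]
                .groupby(["antigen", "method", "tier"])["count"]
                .sum()
            )
            for key, total in totals.items():
                if sums.get(key, 0) != total:
                    raise ValueError(
                        f"axis {axis!r} counts sum to {sums.get(key, 0)} but the "
                        f"total row says {total} for {key}"
                    )
        wide = f.pivot_table(
            index=["axis", "stratum", "antigen", "method"],
            columns="tier",
            values="count",
            aggfunc="sum",
        )
        bad = wide[wide["confirmed"] > wide["screening"]]
        if len(bad):
            raise ValueError(f"confirmed exceeds screening in cells: {bad.index.tolist()}")


def prevalence_table(
    outcomes_by_method: Mapping[str, Sequence[DonorOutcome]],
    demographics: pd.DataFrame,
) -> PrevalenceTable:
    """Build the stratified prevalence table from per-donor outcomes.

    ``outcomes_by_method`` maps a cut-point method (``without_inhibition``
    / ``with_inhibition``) to the donor x antigen outcomes classified
    under it.  ``demographics`` has one row per donor with columns
    donor_id, race, gender, age_band; a donor without demographics is an
    error naming the donor.  Percentages are count / stratum-n, rounded
    half-up to one decimal.
    """
    demo = demographics.set_index("donor_id")
    n_total = len(demo)
    rows = []
    for method, outcomes in outcomes_by_method.items():
        for o in outcomes:
            if o.donor_id not in demo.index:
                raise ValueError(f"donor {o.donor_id!r} has no demographics record")
        odf = pd.DataFrame(
            [
                {
                    "donor_id": o.donor_id,
                    "antigen": o.antigen,
                    "screening": bool(o.screen_positive),
                    "confirmed": bool(o.confirmed_positive),
                }
                for o in outcomes
            ]
        )
        merged = odf.join(demo, on="donor_id")
        for antigen, adf in merged.groupby("antigen"):
            for tier in TIERS:
                for axis, col in AXES.items():
                    grp = adf.groupby(col)[tier].agg(["sum", "count"])
                    for stratum, r in grp.iterrows():
                        rows.append(
                            {
                                "axis": axis,
                                "stratum": stratum,
                                "antigen": antigen,
                                "method": method,
                                "tier": tier,
                                "count": int(r["sum"]),
                                "n_stratum": int(r["count"]),
                                "percent": round_half_up(100.0 * r["sum"] / r["count"]),
                            }
                        )
                rows.append(
                    {
                        "axis": "total",
                        "stratum": TOTAL,
                        "antigen": antigen,
                        "method": method,
                        "tier": tier,
                        "count": int(adf[tier].sum()),
                        "n_stratum": int(len(adf)),
                        "percent": round_half_up(100.0 * adf[tier].mean()),
                    }
                )
    table = PrevalenceTable(frame=pd.DataFrame(rows), n_total=n_total)
    table.validate()
    return table


def titer_table(outcomes: Iterable[DonorOutcome]) -> dict[str, dict[int, int]]:
    """Count endpoint titers per antigen among titrated confirmed positives.

    Returns ``{antigen: {reciprocal_titer: n_donors}}``; the grand total
    equals the number of outcomes carrying a titer (titers exist only for
    confirmed positives by construction of :class:`DonorOutcome`).
    """
    out: dict[str, dict[int, int]] = {}
    for o in outcomes:
        if o.titer is None:
            continue
        out.setdefault(o.antigen, {})
        out[o.antigen][o.titer] = out[o.antigen].get(o.titer, 0) + 1
    return out


def demographics_summary(demographics: pd.DataFrame) -> pd.DataFrame:
    """Stratum counts and percentages of the donor population."""
    rows = []
    n = len(demographics)
    for axis, col in AXES.items():
        for stratum, count in demographics[col].value_counts().sort_index().items():
            rows.append(
                {
                    "axis": axis,
                    "stratum": stratum,
                    "count": int(count),
                    "percent": round_half_up(100.0 * count / n),
                }
            )
    rows.append({"axis": "total", "stratum": TOTAL, "count": n, "percent": 100.0})
    return pd.DataFrame(rows)


def render_prevalence_markdown(table: PrevalenceTable) -> str:
    """Render the prevalence table as a compact Markdown grid."""
    f = table.frame
    lines = []
    antigens = sorted(f["antigen"].unique())
    methods = [m for m in METHODS if m in set(f["method"])]
    header = ["Stratum (n)"]
    for ag in antigens:
        for tier in TIERS:
            for m in methods:
                header.append(f"{ag} {tier} {m.replace('_', ' ')}")
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    order = [(axis, s) for axis in list(AXES) + ["total"] for s in f[f["axis"] == axis]["stratum"].unique()]
    seen = set()
    for axis, stratum in order:
        if (axis, stratum) in seen:
            continue
        seen.add((axis, stratum))
        sub = f[(f["axis"] == axis) & (f["stratum"] == stratum)]
        n_stratum = int(sub["n_stratum"].iloc[0])
        cells = [f"{stratum} ({n_stratum})"]
        for ag in antigens:
            for tier in TIERS:
                for m in methods:
                    r = sub[(sub["antigen"] == ag) & (sub["tier"] == tier) & (sub["method"] == m)]
                    cells.append(f"{r['percent'].iloc[0]:.1f} ({int(r['count'].iloc[0])})" if len(r) else "-")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
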
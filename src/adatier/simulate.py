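"""Synthetic donor populations and ELISA plate data.

No raw serum measurements are deposited for this assay, so every
downstream stage is exercised on simulated 96-well OD450 data whose
statistical structure matches what the analysis assumes:

* a donor population with the published demographic strata (race, gender,
  age band) and configurable seroprevalence per antigen;
* log-normally distributed antibody levels among seropositives, expressed
  as the effective concentration (ng/mL) presented at the 1:20 screening
  dilution;
* a 4PL concentration-response for specific binding, attenuated by the
  serum matrix through a retention factor r(d) = d / (d + K) - with the
  default K = 5 the 1:20 dilution retains exactly 80% of the serum-free
  dynamic range, so 1:20 is the minimum required dilution by construction;
* log-normal nonspecific background binding for seronegatives;
* a competitive-inhibition condition that suppresses specific binding by a
  configurable fraction (defaults anchored at 74.7% for SaCas9 and 87.8%
  for SpCas9) and nonspecific binding by 5%;
* multiplicative nuisance effects for analyst / machine / run / plate
  position (all 1.0 unless a violation is being simulated), multiplicative
  log-normal noise with a given CV shared mean-1, and per-plate
  quadruplicate blank wells.

The observed OD of a well is

    OD = blank_draw + signal * factor_effects * noise,

where for a seropositive donor ``signal = r(d) * fourpl(conc * 20 / d)``
and for a seronegative donor ``signal`` is the donor's background level
(scaled when the assay runs at a dilution other than 1:20).  Triplicates
share the donor signal and differ only in noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curve import FourPLParams
from .plates import ConfigurationError, PLATE_COLUMNS, BlankSummary

#: Reference (minimum required) reciprocal serum dilution of the assay.
MRD_DILUTION = 20

#: Demographic strata of the surveyed donor population (proportions).
TABLE1_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "race": {
        "African American": 0.17,
        "Caucasian": 0.765,
        "Hispanic": 0.05,
        "Other": 0.015,
    },
    "gender": {"Female": 0.40, "Male": 0.60},
    "age": {"19-34": 0.38, "35-49": 0.29, "50-64": 0.25, "65-79": 0.08},
}


def _default_fourpl() -> FourPLParams:
    return FourPLParams(
        lower_asymptote=0.005, upper_asymptote=2.2, ec50=35.0, hill_slope=1.3
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; the defaults are the study conditions.

    ``titer_log_mean``/``titer_log_sd`` parameterise the natural-log-normal
    antibody concentration among seropositives (ng/mL at the 1:20 screening
    dilution).  ``nonspecific_od_log_*`` parameterise the background OD of
    seronegatives at 1:20.  ``matrix_k`` shapes the serum-matrix retention
    r(d) = d/(d+K).  ``factor_effects`` maps factor name -> level ->
    multiplicative effect (absent levels mean 1.0).
    """

    n_donors: int = 200
    prevalence_sa: float = 0.10
    prevalence_sp: float = 0.025
    titer_log_mean: float = math.log(60.0)
    titer_log_sd: float = 0.6
    fourpl: FourPLParams = field(default_factory=_default_fourpl)
    matrix_k: float = 5.0
    inhibition_fraction_sa: float = 0.747
    inhibition_fraction_sp: float = 0.878
    nonspecific_inhibition: float = 0.05
    nonspecific_od_log_mean: float = math.log(0.22)
    nonspecific_od_log_sd: float = 0.35
    factor_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_cv: float = 0.05
    blank_mean: float = 0.045
    blank_sd: float = 0.012
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_DEMOGRAPHICS.items()}
    )
    streptozyme_rate: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "prevalence_sa": self.prevalence_sa,
            "prevalence_sp": self.prevalence_sp,
            "inhibition_fraction_sa": self.inhibition_fraction_sa,
            "inhibition_fraction_sp": self.inhibition_fraction_sp,
            "nonspecific_inhibition": self.nonspecific_inhibition,
            "streptozyme_rate": self.streptozyme_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be positive")
        if self.matrix_k < 0:
            raise ConfigurationError("matrix_k must be non-negative")
        for axis, props in self.demographics.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"demographic proportions for {axis!r} sum to {total}, not 1"
                )

    def inhibition_fraction(self, antigen: str) -> float:
        return self.inhibition_fraction_sa if antigen == "SaCas9" else self.inhibition_fraction_sp

    def prevalence(self, antigen: str) -> float:
        return self.prevalence_sa if antigen == "SaCas9" else self.prevalence_sp

    def to_json(self) -> str:
        d = asdict(self)
        d["fourpl"] = asdict(self.fourpl)
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "fourpl" in d and isinstance(d["fourpl"], Mapping):
            d["fourpl"] = FourPLParams(**d["fourpl"])
        return cls(**d)


@dataclass(frozen=True)
class DonorTruth:
    """Ground-truth state of one simulated donor."""

    donor_id: str
    race: str
    gender: str
    age_band: str
    seropositive_sa: bool
    seropositive_sp: bool
    true_conc_sa: float
    true_conc_sp: float
    streptozyme_positive: bool

    def __post_init__(self) -> None:
        if not self.seropositive_sa and self.true_conc_sa != 0.0:
            raise ValueError("seronegative donors have zero SaCas9 antibody")
        if not self.seropositive_sp and self.true_conc_sp != 0.0:
            raise ValueError("seronegative donors have zero SpCas9 antibody")

    def seropositive(self, antigen: str) -> bool:
        return self.seropositive_sa if antigen == "SaCas9" else self.seropositive_sp

    def true_conc(self, antigen: str) -> float:
        return self.true_conc_sa if antigen == "SaCas9" else self.true_conc_sp


def matrix_retention(dilution, k: float = 5.0):
    """Fraction of the serum-free signal retained at a reciprocal dilution.

    r(d) = d / (d + K); with the default K = 5, r(20) = 0.80 exactly.
    """
    d = np.asarray(dilution, dtype=float)
    out = d / (d + k)
    return float(out) if np.isscalar(dilution) else out


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size))


def generate_donors(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[DonorTruth]:
    """Draw a donor population: strata, serostatus, and antibody levels.

    Strata are sampled independently per axis at the configured
    proportions; serostatus is Bernoulli at the configured prevalence per
    antigen; antibody concentrations among seropositives are log-normal.
    Output is reproducible for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_donors
    axes = {}
    for axis, props in config.demographics.items():
        levels = list(props)
        axes[axis] = rng.choice(levels, size=n, p=[props[k] for k in levels])
    pos_sa = rng.random(n) < config.prevalence_sa
    pos_sp = rng.random(n) < config.prevalence_sp
    conc_sa = np.where(
        pos_sa, rng.lognormal(config.titer_log_mean, config.titer_log_sd, n), 0.0
    )
    conc_sp = np.where(
        pos_sp, rng.lognormal(config.titer_log_mean, config.titer_log_sd, n), 0.0
    )
    strep = rng.random(n) < config.streptozyme_rate
    width = len(str(n))
    return [
        DonorTruth(
            donor_id=f"D{i + 1:0{width}d}",
            race=str(axes["race"][i]),
            gender=str(axes["gender"][i]),
            age_band=str(axes["age"][i]),
            seropositive_sa=bool(pos_sa[i]),
            seropositive_sp=bool(pos_sp[i]),
            true_conc_sa=float(conc_sa[i]),
            true_conc_sp=float(conc_sp[i]),
            streptozyme_positive=bool(strep[i]),
        )
        for i in range(n)
    ]


def donors_frame(donors: Sequence[DonorTruth]) -> pd.DataFrame:
    """Tabulate donor ground truth (one row per donor)."""
    return pd.DataFrame(
        [
            {
                "donor_id": d.donor_id,
                "race": d.race,
                "gender": d.gender,
                "age_band": d.age_band,
                "seropositive_sa": d.seropositive_sa,
                "seropositive_sp": d.seropositive_sp,
                "true_conc_sa": d.true_conc_sa,
                "true_conc_sp": d.true_conc_sp,
                "streptozyme_positive": d.streptozyme_positive,
            }
            for d in donors
        ]
    )


def _factor_multiplier(config: SimulationConfig, factor: str, levels: np.ndarray) -> np.ndarray:
    table = config.factor_effects.get(factor, {})
    return np.array([float(table.get(str(lv), 1.0)) for lv in levels])


def _donor_signals(
    donors: Sequence[DonorTruth],
    antigen: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    dilution: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free untreated signal and seropositivity mask per donor."""
    seropos = np.array([d.seropositive(antigen) for d in donors])
    conc = np.array([d.true_conc(antigen) for d in donors])
    bg = np.exp(
        rng.normal(config.nonspecific_od_log_mean, config.nonspecific_od_log_sd, len(donors))
    )
    r = matrix_retention(dilution, config.matrix_k)
    r_mrd = matrix_retention(MRD_DILUTION, config.matrix_k)
    c_eff = conc * MRD_DILUTION / dilution
    specific = r * np.asarray(config.fourpl(c_eff))
    nonspecific = bg * (MRD_DILUTION / dilution) * (r / r_mrd)
    return np.where(seropos, specific, nonspecific), seropos


def generate_measurements(
    donors: Sequence[DonorTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    antigens: Sequence[str] = ("SaCas9", "SpCas9"),
    conditions: Sequence[str] = ("untreated", "inhibited"),
    dilution: int = MRD_DILUTION,
    n_replicates: int = 3,
    n_blanks: int = 4,
) -> pd.DataFrame:
    """Emit a tidy plate table for a donor population.

    Donors are laid out on 96-well plates (one plate per ``run`` value)
    with all requested conditions in triplicate plus quadruplicate blanks.
    The inhibited condition multiplies a seropositive donor's above-blank
    signal by (1 - inhibition_fraction) and a seronegative donor's
    background by (1 - nonspecific_inhibition).
    """
    if not donors:
        raise ValueError("donors must be non-empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    wells_per_donor = len(conditions) * n_replicates
    per_plate = max(1, (96 - n_blanks) // wells_per_donor)
    frames = []
    for antigen in antigens:
        signal_unt, seropos = _donor_signals(donors, antigen, config, rng, dilution)
        inh_mult = np.where(
            seropos,
            1.0 - config.inhibition_fraction(antigen),
            1.0 - config.nonspecific_inhibition,
        )
        for start in range(0, len(donors), per_plate):
            chunk = slice(start, min(start + per_plate, len(donors)))
            idx = np.arange(chunk.start, chunk.stop)
            run = f"{antigen}-plate{start // per_plate + 1:03d}"
            rows: dict[str, list] = {c: [] for c in PLATE_COLUMNS}
            for cond in conditions:
                mult = inh_mult[idx] if cond == "inhibited" else np.ones(len(idx))
                base = signal_unt[idx] * mult
                for j, di in enumerate(idx):
                    d = donors[di]
                    positions = f"P{di % 4 + 1}"
                    eff = (
                        float(config.factor_effects.get("analyst", {}).get("A1", 1.0))
                        * float(config.factor_effects.get("machine", {}).get("M1", 1.0))
                        * float(config.factor_effects.get("run", {}).get(run, 1.0))
                        * float(config.factor_effects.get("plate_position", {}).get(positions, 1.0))
                    )
                    noise = _noise(rng, config.noise_cv, n_replicates)
                    blank_part = config.blank_mean + rng.normal(0.0, config.blank_sd, n_replicates)
                    ods = blank_part + base[j] * eff * noise
                    for rep in range(n_replicates):
                        rows["donor_id"].append(d.donor_id)
                        rows["antigen"].append(antigen)
                        rows["condition"].append(cond)
                        rows["spiked_conc"].append(None)
                        rows["serum_dilution"].append(dilution)
                        rows["replicate"].append(rep + 1)
                        rows["analyst"].append("A1")
                        rows["machine"].append("M1")
                        rows["run"].append(run)
                        rows["plate_position"].append(positions)
                        rows["od450"].append(float(ods[rep]))
            blanks = config.blank_mean + rng.normal(0.0, config.blank_sd, n_blanks)
            for b in range(n_blanks):
                rows["donor_id"].append(None)
                rows["antigen"].append(antigen)
                rows["condition"].append("blank")
                rows["spiked_conc"].append(None)
                rows["serum_dilution"].append(1)
                rows["replicate"].append(b + 1)
                rows["analyst"].append("A1")
                rows["machine"].append("M1")
                rows["run"].append(run)
                rows["plate_position"].append("B1")
                rows["od450"].append(float(blanks[b]))
            frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def generate_standard_series(
    config: SimulationConfig,
    top_conc: float,
    fold: float,
    n_points: int,
    antigen: str = "SaCas9",
    serum_dilution: int | None = None,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a spiked standard series (buffer or diluted serum).

    Standards sit at ``top_conc / fold**k`` for k = 0..n_points-1.  In
    buffer (``serum_dilution=None``) the full 4PL signal is seen; in serum
    the signal is attenuated by the matrix retention at that dilution.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    concs = top_conc / fold ** np.arange(n_points)
    r = 1.0 if serum_dilution is None else matrix_retention(serum_dilution, config.matrix_k)
    run = f"std-{antigen}-" + ("buffer" if serum_dilution is None else f"d{serum_dilution}")
    rows: dict[str, list] = {c: [] for c in PLATE_COLUMNS}
    for k, conc in enumerate(concs):
        signal = r * float(config.fourpl(conc))
        noise = _noise(rng, config.noise_cv, n_replicates)
        blank_part = config.blank_mean + rng.normal(0.0, config.blank_sd, n_replicates)
        ods = blank_part + signal * noise
        for rep in range(n_replicates):
            rows["donor_id"].append(None)
            rows["antigen"].append(antigen)
            rows["condition"].append("standard")
            rows["spiked_conc"].append(float(conc))
            rows["serum_dilution"].append(1 if serum_dilution is None else serum_dilution)
            rows["replicate"].append(rep + 1)
            rows["analyst"].append("A1")
            rows["machine"].append("M1")
            rows["run"].append(run)
            rows["plate_position"].append(f"P{k % 4 + 1}")
            rows["od450"].append(float(ods[rep]))
    blanks = config.blank_mean + rng.normal(0.0, config.blank_sd, 4)
    for b in range(4):
        rows["donor_id"].append(None)
        rows["antigen"].append(antigen)
        rows["condition"].append("blank")
        rows["spiked_conc"].append(None)
        rows["serum_dilution"].append(1)
        rows["replicate"].append(b + 1)
        rows["analyst"].append("A1")
        rows["machine"].append("M1")
        rows["run"].append(run)
        rows["plate_position"].append("B1")
        rows["od450"].append(float(blanks[b]))
    return pd.DataFrame(rows)


def generate_precision_dataset(
    config: SimulationConfig,
    n_samples: int = 48,
    n_replicates: int = 3,
    analysts: Sequence[str] = ("A1", "A2"),
    machines: Sequence[str] = ("M1", "M2"),
    runs: Sequence[str] = ("R1", "R2"),
    positions: Sequence[str] = ("P1", "P2", "P3", "P4"),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the balanced precision design (raw ODs, no blanks).

    Every sample is read in triplicate under every analyst x machine
    combination (48 x 3 x 2 x 2 = 576 wells).  Run and plate position are
    assigned in balanced blocks of samples, mirroring how plate order maps
    onto a real experiment.  Each sample carries a persistent background
    level; factor effects multiply the signal, so the default (all 1.0)
    generates the null used to verify that the precision tests are
    calibrated.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    bg = np.exp(
        rng.normal(config.nonspecific_od_log_mean, config.nonspecific_od_log_sd, n_samples)
    )
    half = max(1, n_samples // len(runs))
    rows: dict[str, list] = {c: [] for c in PLATE_COLUMNS}
    width = len(str(n_samples))
    for s in range(n_samples):
        run = runs[min(s // half, len(runs) - 1)]
        pos = positions[s % len(positions)]
        for a in analysts:
            for m in machines:
                eff = (
                    float(config.factor_effects.get("analyst", {}).get(a, 1.0))
                    * float(config.factor_effects.get("machine", {}).get(m, 1.0))
                    * float(config.factor_effects.get("run", {}).get(run, 1.0))
                    * float(config.factor_effects.get("plate_position", {}).get(pos, 1.0))
                )
                noise = _noise(rng, config.noise_cv, n_replicates)
                blank_part = config.blank_mean + rng.normal(0.0, config.blank_sd, n_replicates)
                ods = blank_part + bg[s] * eff * noise
                for rep in range(n_replicates):
                    rows["donor_id"].append(f"S{s + 1:0{width}d}")
                    rows["antigen"].append("SaCas9")
                    rows["condition"].append("untreated")
                    rows["spiked_conc"].append(None)
                    rows["serum_dilution"].append(MRD_DILUTION)
                    rows["replicate"].append(rep + 1)
                    rows["analyst"].append(a)
                    rows["machine"].append(m)
                    rows["run"].append(run)
                    rows["plate_position"].append(pos)
                    rows["od450"].append(float(ods[rep]))
    return pd.DataFrame(rows)


def generate_titration_series(
    donor: DonorTruth,
    antigen: str,
    config: SimulationConfig,
    dilutions: Sequence[int] = (4, 16, 64, 256, 1024),
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BlankSummary]:
    """Simulate an endpoint-titration dilution series for one donor.

    Returns the raw (uncorrected) mean OD per dilution plus the blank
    summary of the titration plate, the inputs the endpoint-titer rule
    (OD > blank mean + 2 SD) consumes.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    dils = np.asarray(dilutions, dtype=float)
    r = matrix_retention(dils, config.matrix_k)
    r_mrd = matrix_retention(MRD_DILUTION, config.matrix_k)
    if donor.seropositive(antigen):
        c_eff = donor.true_conc(antigen) * MRD_DILUTION / dils
        signal = r * np.asarray(config.fourpl(c_eff))
    else:
        bg = math.exp(
            rng.normal(config.nonspecific_od_log_mean, config.nonspecific_od_log_sd)
        )
        signal = bg * (MRD_DILUTION / dils) * (r / r_mrd)
    ods = np.empty(len(dils))
    for i, sig in enumerate(signal):
        noise = _noise(rng, config.noise_cv, n_replicates)
        blank_part = config.blank_mean + rng.normal(0.0, config.blank_sd, n_replicates)
        ods[i] = float(np.mean(blank_part + sig * noise))
    blank_wells = config.blank_mean + rng.normal(0.0, config.blank_sd, 4)
    blank = BlankSummary(
        plate_id=f"titer-{donor.donor_id}-{antigen}",
        mean_blank=float(blank_wells.mean()),
        sd_blank=float(np.std(blank_wells, ddof=1)),
        n_blanks=4,
    )
    return ods, blank
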
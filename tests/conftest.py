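import numpy as np
import pandas as pd
import pytest

from adatier.plates import PLATE_COLUMNS
from adatier.simulate import SimulationConfig


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Deterministic generator: no replicate noise, no blank noise."""
    return SimulationConfig(noise_cv=0.0, blank_sd=0.0, seed=123)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=123)


def make_wells(
    ods,
    donor_id="D1",
    antigen="SaCas9",
    condition="untreated",
    run="R1",
    serum_dilution=20,
    spiked_conc=None,
) -> pd.DataFrame:
    """A minimal tidy plate frame with one well per OD value."""
    rows = []
    for i, od in enumerate(ods):
        rows.append(
            {
                "donor_id": donor_id,
                "antigen": antigen,
                "condition": condition,
                "spiked_conc": spiked_conc,
                "serum_dilution": serum_dilution,
                "replicate": i + 1,
                "analyst": "A1",
                "machine": "M1",
                "run": run,
                "plate_position": "P1",
                "od450": float(od),
            }
        )
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def add_blanks(frame: pd.DataFrame, ods, run="R1", antigen="SaCas9") -> pd.DataFrame:
    blanks = make_wells(
        ods, donor_id=None, antigen=antigen, condition="blank", run=run, serum_dilution=1
    )
    return pd.concat([frame, blanks], ignore_index=True)
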
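import io

import numpy as np
import pandas as pd
import pytest

from otogrow import SimulationConfig, simulate_dataset
from otogrow.data_model import SCHEMA_COLUMNS, read_growth_csv
from otogrow.mcmc import MCMCSettings

#: reduced sampling used throughout the suite (4 chains x 500 kept draws)
FAST_MCMC = MCMCSettings(chains=4, iterations=1500, warmup=1000)


def make_long_csv(rows: list[dict]) -> io.StringIO:
    """Build an in-memory schema CSV from partial row dicts (rest NA)."""
    frame = pd.DataFrame(rows)
    for col in SCHEMA_COLUMNS:
        if col not in frame.columns:
            frame[col] = "NA"
    frame = frame[list(SCHEMA_COLUMNS)]
    buf = io.StringIO()
    frame.to_csv(buf, index=False, na_rep="NA")
    buf.seek(0)
    return buf


def toy_individual_rows(
    iid="F001", ages=(0, 1, 2), radii=(0.05, 0.4, 0.8), age_cpt=None,
    r_cpt=None, l_cpt=150.0, l_0p=2.5, r_0p=0.05, species=("Acanthuridae", "Ctenochaetus", "striatus"),
    location="Moorea",
):
    age_cpt = age_cpt if age_cpt is not None else max(ages)
    r_cpt = r_cpt if r_cpt is not None else max(r for r in radii if r is not None)
    rows = []
    for age, r in zip(ages, radii):
        rows.append(
            dict(
                Family=species[0], Genus=species[1], Species=species[2], ID=iid,
                Age_i=age, R_i=r if r is not None else "NA",
                Age_cpt=age_cpt, R_cpt=r_cpt, L_cpt=l_cpt, L_0p=l_0p,
                R_0p=r_0p if r_0p is not None else "NA",
                Location=location, Observer="obs1",
            )
        )
    return rows


@pytest.fixture
def toy_dataset():
    return read_growth_csv(make_long_csv(toy_individual_rows()), provenance="toy")


@pytest.fixture
def small_synthetic():
    cfg = SimulationConfig(
        n_species=1, n_individuals_per_species=12, sigma_length=2.0,
        missing_r0p_rate=0.25, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def noise_free_synthetic():
    cfg = SimulationConfig(
        n_species=1, n_individuals_per_species=10, sigma_length=0.0,
        missing_r0p_rate=0.0, seed=7,
    )
    return simulate_dataset(cfg)
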
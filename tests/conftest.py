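"""Shared fixtures: random toy landscapes and a session-scoped desk-preset
experiment reused by the slower analysis tests."""

from __future__ import annotations

import numpy as np
import pytest

import beetlescape as bl
from beetlescape.config import make_config

SPECIES = ("spruce", "beech", "fir", "other")


def random_landscape(rng: np.random.Generator, rows: int = 5, cols: int = 5,
                     max_cohorts: int = 4, p_empty: float = 0.15,
                     p_spruce: float = 0.4) -> bl.LandscapeState:
    """A random small landscape with plausible cohort attributes."""
    cells = []
    for _ in range(rows):
        row = []
        for _ in range(cols):
            if rng.random() < p_empty:
                row.append(bl.Cell(cohorts=[]))
                continue
            cohorts = []
            for _ in range(rng.integers(1, max_cohorts + 1)):
                sp = "spruce" if rng.random() < p_spruce \
                    else SPECIES[rng.integers(1, 4)]
                dbh = float(rng.uniform(2, 70))
                cohorts.append(bl.Cohort(
                    species=sp,
                    stems_per_ha=float(rng.uniform(20, 800)),
                    mean_dbh_cm=dbh,
                    mean_height_m=float(rng.uniform(1.5, 42)),
                    age_yr=float(rng.uniform(5, 300)),
                ))
            row.append(bl.Cell(cohorts=cohorts))
        cells.append(row)
    return bl.landscape_from_cells(cells, slots=max_cohorts + 2)


@pytest.fixture(scope="session")
def desk_experiment():
    """The default desk-preset factorial experiment (shared across tests)."""
    return bl.run_experiment(make_config("desk"))


@pytest.fixture(scope="session")
def desk_surrogate(desk_experiment):
    table = bl.build_training_table(desk_experiment)
    model = bl.fit_surrogate(table, seed=0)
    return table, model


@pytest.fixture()
def mini_config():
    """A 12x12-cell, 60-year, 2-replicate configuration for fast e2e tests."""
    return make_config("desk", overrides={
        "landscape": {"rows": 12, "cols": 12},
        "experiment": {"horizon_yr": 60, "indicator_step_yr": 30,
                       "replicates": 2, "climates": ["BC", "HC"],
                       "base_seed": 7},
    })
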
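import numpy as np
import pytest

from smoltcjs import defaults
from smoltcjs.encounter import build_encounter_histories
from smoltcjs.io_model import EncounterHistory, FishRecord, Origin, Population
from smoltcjs.synthetic_data import default_config, simulate_cohort, simulate_migration


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_dataset():
    """One deterministic study-scale simulated dataset shared by tests:
    (config, fish, lines, truth, events)."""
    cfg = default_config(seed=11)
    rng = np.random.default_rng(11)
    fish = simulate_cohort(cfg, rng)
    lines = defaults.default_receiver_lines()
    truth, events = simulate_migration(fish, cfg, lines, rng)
    return cfg, fish, lines, truth, events


@pytest.fixture(scope="session")
def study_histories(study_dataset):
    _, fish, lines, _, events = study_dataset
    return build_encounter_histories(events, fish, lines)


def make_record(i=0, population=Population.BigBeefW, year=2008, si=2, rd=120.0):
    return FishRecord(
        fish_id=f"fish-{population.value}-{i}",
        population=population,
        origin=Origin.wild if population.value.endswith("W") else Origin.hatchery,
        year=year,
        fork_length_mm=180.0,
        weight_g=55.0,
        smolt_index=si,
        release_date=rd,
        release_site="site",
    )


def histories_from_matrix(hist, population=Population.BigBeefW, year=2008):
    """Wrap a raw (n, T+1) history matrix as EncounterHistory objects with
    homogeneous FishRecords."""
    out = []
    for i, row in enumerate(hist):
        rec = make_record(i, population=population, year=year)
        out.append(EncounterHistory(rec.fish_id, row, record=rec))
    return out
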
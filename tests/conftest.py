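import pandas as pd
import pytest

from weevilmove import (
    ModelCoefficients,
    StudyDesign,
    build_occupancy,
    dedup_events,
    infer_crossings,
    simulate_experiment,
    windowize,
)

SMALL_DESIGN = StudyDesign(treatments=((4, 4), (10, 2), (20, 2)))


@pytest.fixture(scope="session")
def coeffs() -> ModelCoefficients:
    return ModelCoefficients.fitted()


@pytest.fixture(scope="session")
def small_sim(coeffs):
    return simulate_experiment(SMALL_DESIGN, coeffs, seed=7)


@pytest.fixture(scope="session")
def small_chain(small_sim):
    """Reconstructed crossings, occupancy and 30-min window table."""
    events = dedup_events(small_sim.events)
    crossings = infer_crossings(events, small_sim.roster)
    occupancy = build_occupancy(crossings, small_sim.roster)
    windows = windowize(occupancy, crossings, small_sim.roster, 30)
    return {
        "sim": small_sim,
        "events": events,
        "crossings": crossings,
        "occupancy": occupancy,
        "windows": windows,
    }


def make_events(rows, replicate="r0"):
    """Event frame from (tag, antenna, timestamp) tuples."""
    return pd.DataFrame(
        [(replicate, t, a, s) for t, a, s in rows],
        columns=["replicate_id", "tag_id", "antenna", "timestamp_s"],
    )


def make_roster(entries, replicate="r0"):
    """Roster frame from (tag, sex, release_patch) tuples."""
    return pd.DataFrame(
        [(t, s, replicate, p, 0) for t, s, p in entries],
        columns=["tag_id", "sex", "replicate_id", "release_patch", "bulb_age"],
    )
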
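"""Shared fixtures: tiny synthetic cohorts and common series builders."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from rhythmkit.io_events import EpochSeries
from rhythmkit.synthetic import ScenarioConfig, generate_cohort, generate_participant

UTC = timezone.utc


def minute_series(values, label="PA", start=None, participant_id="p1"):
    return EpochSeries(
        participant_id=participant_id,
        epoch_seconds=60,
        start=start or datetime(2023, 1, 2, tzinfo=UTC),
        values=np.asarray(values, dtype=float),
        label=label,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 participants x 6 days; fast enough for unit tests."""
    cfg = ScenarioConfig(n_participants=3, n_days=6, seed=11, empty_day_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def one_participant():
    """One 10-day participant with no device-off days."""
    cfg = ScenarioConfig(n_participants=1, n_days=10, seed=5, empty_day_rate=0.0)
    return generate_participant(cfg, 0)
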
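import datetime as dt

import numpy as np
import pytest

from nhpsleep import AnalysisWindow, Hypnogram, LightsSchedule, WindowKind
from nhpsleep.stages import SCORED_STAGES, StageLabel

NIGHT_START = dt.datetime(2024, 1, 1, 19, 0)


@pytest.fixture
def night_start() -> dt.datetime:
    return NIGHT_START


def make_hypnogram(tokens, start=NIGHT_START, epoch_length=30.0, lights_off_at_start=True):
    """Hypnogram from stage tokens with a lights-off event at the start."""
    stages = tuple(StageLabel(t) for t in tokens)
    lights = LightsSchedule(((start, "off"),)) if lights_off_at_start else None
    return Hypnogram(start_time=start, stages=stages, epoch_length=epoch_length, lights=lights)


@pytest.fixture
def make_hyp():
    return make_hypnogram


def random_hypnogram(rng: np.random.Generator, n_epochs: int = 50) -> Hypnogram:
    """Uniformly random scored hypnogram (oracle-equivalence fodder)."""
    stages = tuple(SCORED_STAGES[i] for i in rng.integers(0, 6, n_epochs))
    return Hypnogram(
        start_time=NIGHT_START,
        stages=stages,
        epoch_length=30.0,
        lights=LightsSchedule(((NIGHT_START, "off"),)),
    )


@pytest.fixture
def two_hour_window() -> AnalysisWindow:
    return AnalysisWindow(
        NIGHT_START, NIGHT_START + dt.timedelta(hours=2), WindowKind.NIGHT
    )
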
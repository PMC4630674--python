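import numpy as np
import pytest

from locogait import RunConfig
from locogait.synth import (FixtureLayout, SyntheticSpec, gen_gait,
                            render_fixture, train_fixture_detectors)


@pytest.fixture(scope="session")
def fixture_layout():
    return FixtureLayout()


@pytest.fixture(scope="session")
def fixture_config(fixture_layout):
    return RunConfig(px_per_mm=fixture_layout.px_per_mm,
                     view_split_row=fixture_layout.view_split_row,
                     floor_row=fixture_layout.floor_row,
                     midline_row=fixture_layout.midline_row,
                     detector_scale=0.25, seed=0)


@pytest.fixture(scope="session")
def rendered_trial(fixture_layout):
    """A 200-frame noise-free quarter-scale rendered trial with truth."""
    tracks, truth = gen_gait(SyntheticSpec(speed=0.25, seed=0), duration_s=0.5)
    video = render_fixture(tracks, fixture_layout)
    return tracks, truth, video


@pytest.fixture(scope="session")
def fixture_detectors(rendered_trial, fixture_config):
    _, _, video = rendered_trial
    return train_fixture_detectors(video, fixture_config)


@pytest.fixture(scope="session")
def trot_trial():
    """A clean 2 s synthetic trot at 0.25 m/s with its ground truth."""
    return gen_gait(SyntheticSpec(speed=0.25, seed=1), duration_s=2.0)
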
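import numpy as np
import pytest

import enightlog as en


@pytest.fixture(scope="session")
def single_layout():
    return en.make_layout("single")


@pytest.fixture(scope="session")
def double_layout():
    return en.make_layout("double")


@pytest.fixture(scope="session")
def single_zones(single_layout):
    return en.zones_for(single_layout)


@pytest.fixture(scope="session")
def single_view(single_layout):
    return en.sensor_view(single_layout)


@pytest.fixture(scope="session")
def single_masks(single_view, single_zones):
    return en.ZoneMasks.from_zones(single_view, single_zones)


@pytest.fixture(scope="session")
def sc1_trial(single_layout):
    """One noiseless Sc1 trial, shared across read-only tests."""
    return en.run_trial(
        en.compile_scenario("Sc1"), single_layout, seed=11, noise_sd_cm=0.0
    )


def lying_subject(layout, bed_index=0):
    bed = layout.beds[bed_index]
    cx, cy = bed.rect.centre
    return en.ActorState(
        name=f"subject_{bed_index}", role="subject", x_cm=cx, y_cm=cy,
        posture="lying", bed=bed,
    )
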
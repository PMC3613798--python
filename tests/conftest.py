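import dataclasses

import numpy as np
import pandas as pd
import pytest

from dotgrouping.bold import EffectRegion, GroundTruth, ScanProtocol
from dotgrouping.stimulus import SimConfig


@pytest.fixture
def default_config():
    return SimConfig(condition="moving_colour", n_groups=2, seed=7)


@pytest.fixture
def tiny_config():
    """A fast 80-dot, 1-second stimulus for loops that iterate many seeds."""
    return SimConfig(
        n_dots=80,
        grid_cols=10,
        grid_rows=8,
        field_w_px=256.0,
        field_h_px=192.0,
        region_diameter_px=40.0,
        stim_duration_s=1.0,
        frame_rate_hz=20.0,
        burn_in_frames=20,
        condition="moving_colour",
        n_groups=2,
        seed=0,
    )


@pytest.fixture
def small_protocol():
    """Short session for GLM tests: 18 trials, ~50 volumes."""
    return ScanProtocol(n_trials=18)


@pytest.fixture
def small_truth():
    """Two disjoint effect regions on a 10^3 volume, low noise."""
    return GroundTruth(
        shape=(10, 10, 10),
        regions=(
            EffectRegion("colour_region", (3, 5, 5), 1.6, colour_slope=0.5),
            EffectRegion("motion_region", (7, 5, 5), 1.6, motion_slope=0.5),
        ),
        noise_sd=0.5,
        drift_amplitudes=(1.0,),
        drift_periods_s=(200.0,),
        between_subject_sd=0.05,
    )


@pytest.fixture
def noiseless_truth(small_truth):
    return dataclasses.replace(
        small_truth,
        noise_sd=0.0,
        drift_amplitudes=(),
        drift_periods_s=(),
        between_subject_sd=0.0,
    )


@pytest.fixture
def all_type_events():
    """Hand-built event table containing every trial type, with grouping
    variation in both moving conditions."""
    rows = []
    spec = [
        ("moving_colour", 0),
        ("moving_greyscale", 2),
        ("static_colour", 0),
        ("moving_colour", 3),
        ("static_greyscale", 0),
        ("moving_greyscale", 0),
        ("moving_colour", 1),
        ("moving_greyscale", 1),
    ]
    for k, (trial_type, n_groups) in enumerate(spec):
        rows.append(
            {
                "onset": 8.0 * k,
                "duration": 5.0,
                "trial_type": trial_type,
                "n_groups": n_groups,
                "response": n_groups,
                "rt": 2500.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
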
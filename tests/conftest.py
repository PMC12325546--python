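import numpy as np
import pandas as pd
import pytest

from myostiff import simulate as sim
from myostiff.contact import ProbeParams


@pytest.fixture
def probe():
    return ProbeParams(spring_constant=0.3, tip_radius=4.9e-6, poisson_ratio=0.5)


def make_curve(E, probe, *, noise_sd=0.0, baseline_tilt=0.0, seed=0, n_points=1500,
               margin=1.3, **kwargs):
    """Generate a curve whose ramp is sized for its stiffness: contact sits at
    one third of the span and the post-contact travel reaches the high force
    window with `margin` to spare."""
    T = sim.travel_for_force(E, probe) * margin
    return sim.gen_hertz_curve(
        E, 0.5 * T, probe, z_span=1.5 * T, n_points=n_points,
        noise_sd=noise_sd, baseline_tilt=baseline_tilt, seed=seed, **kwargs
    )


@pytest.fixture
def curve_factory():
    return make_curve


def paired_long_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reshape a gen_paired_dataset frame to the long format fit_lme expects."""
    a = df.rename(columns={"E_pre_Pa": "E_Pa"})[["location_id", "E_Pa"]].assign(treatment="pre")
    b = df.rename(columns={"E_post_Pa": "E_Pa"})[["location_id", "E_Pa"]].assign(treatment="post")
    return pd.concat([a, b], ignore_index=True)


@pytest.fixture
def long_table():
    return paired_long_table
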
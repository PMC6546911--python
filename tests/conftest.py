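"""Shared fixtures: small schemes, photophysics models and trace builders."""

import numpy as np
import pytest

from clampfret.kinetics import KineticScheme, make_scenario, simulate_state_path
from clampfret.photophysics import PhotophysicsModel, Trace, render_trace


@pytest.fixture
def loading_scheme():
    return make_scenario("loading_atp")


@pytest.fixture
def unloading_scheme():
    return make_scenario("unloading_atp")


@pytest.fixture
def quiet_model():
    """Noiseless photophysics (expected photon counts, no backgrounds)."""
    return PhotophysicsModel(
        background_donor=0.0,
        background_acceptor=0.0,
        read_noise_sd=0.0,
        donor_bleach_rate=0.0,
    )


@pytest.fixture
def default_model():
    return PhotophysicsModel()


def staircase_trace(
    levels, frames_per_level=50, noise_sd=0.0, seed=0, frame_interval=0.1
):
    """Total-intensity staircase split evenly between the two channels."""
    rng = np.random.default_rng(seed)
    total = np.repeat(np.asarray(levels, dtype=float), frames_per_level)
    if noise_sd > 0:
        total = total + rng.normal(0.0, noise_sd, len(total))
    t = (np.arange(len(total)) + 0.5) * frame_interval
    return Trace(
        trace_id="stair", time=t, donor=total / 2.0, acceptor=total / 2.0
    )


@pytest.fixture
def make_staircase():
    return staircase_trace


def constant_bound_traces(
    n, duration=3.0, n_donors=6, seed=0, model=None, noise=True, scheme=None
):
    """Traces from the always-loaded (inactive unloader) scenario."""
    scheme = scheme or make_scenario("unloading_inactive")
    model = model or PhotophysicsModel()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        p = simulate_state_path(scheme, duration, rng)
        out.append(
            render_trace(
                p, model, seed=rng, n_donors=n_donors, noise=noise,
                trace_id=f"t{i:04d}", fret_mean=scheme.fret_mean,
            )
        )
    return out


@pytest.fixture
def make_bound_traces():
    return constant_bound_traces
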
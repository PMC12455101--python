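"""Shared fixtures: analytic Gaussian traces and small candidate sets."""

import numpy as np
import pytest

from prmkit.features import Trace


def gaussian_trace(
    transition_id="t",
    amplitude=1000.0,
    center=100.0,
    sigma=2.0,
    baseline=0.0,
    t_span=(80.0, 120.0),
    dt=0.1,
):
    t = np.arange(*t_span, dt)
    y = amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2) + baseline
    return Trace(transition_id, t, y)


@pytest.fixture
def gauss():
    return gaussian_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
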
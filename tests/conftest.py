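"""Shared fixtures: a small fiber layout and pre-synthesized trace stacks.

Everything is generated at test time from fixed seeds; the short fiber keeps
the coherent-sum synthesis cheap while preserving the full geometry (10
bins per tree loop at 0.5-m sampling, 5-kHz pulse rate).
"""

import numpy as np
import pytest

from palmdas.fiber import (
    AcousticScene,
    BurstSource,
    FiberLayout,
    PulseConfig,
    TreeSpec,
    realize_fiber,
    synthesize_traces,
)


@pytest.fixture(scope="session")
def pulse():
    return PulseConfig()


@pytest.fixture(scope="session")
def small_layout():
    """100-m fiber with one infested and one healthy tree."""
    return FiberLayout(
        fiber_length=100.0,
        trees=(
            TreeSpec("I1", 30.0, condition="infested"),
            TreeSpec("H1", 60.0, condition="healthy"),
        ),
    )


@pytest.fixture(scope="session")
def small_state(small_layout, pulse):
    return realize_fiber(small_layout, pulse, seed=123)


@pytest.fixture(scope="session")
def larvae_scene():
    return AcousticScene(
        duration=1.0,
        larvae_sources=(BurstSource("I1", burst_rate=8.0, amplitude=0.08,
                                    duty_pattern=(np.inf, 0.0)),),
    )


@pytest.fixture(scope="session")
def larvae_traces(small_state, larvae_scene, pulse):
    return synthesize_traces(small_state, larvae_scene, pulse, seed=5)
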
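"""Shared expensive fixtures: full-scale scenario runs reused across tests.

The scenario runs here are the scientific workload of the suite; each is
computed once per session and inspected by several tests.  The four
secretion presets double as the ×0.25 and ×4 grid points of the
robustness sweeps, with the baseline as the ×1 point.
"""

import pytest

from stromasim import preset, run


@pytest.fixture(scope="session")
def baseline_run():
    """Default calibration, long enough to cross the angiogenic switch and
    the growth transition."""
    return run(preset("baseline"), horizon=850, seed=1)


@pytest.fixture(scope="session")
def no_angiogenesis_run():
    """Vessels present but unable to activate: the tumor must die out."""
    return run(preset("no_angiogenesis"), horizon=1020, seed=1)


@pytest.fixture(scope="session")
def non_proliferating_run():
    """A single non-dividing, non-cancerous cell: lives quietly off the
    background oxygen reservoir."""
    return run(preset("non_proliferating"), horizon=650, seed=1)


@pytest.fixture(scope="session")
def far_vessels_run():
    """Initial vessels at 300 μm instead of 200 μm: over the standard
    observation window the tumor's VEGF cannot recruit them (transit
    time grows with distance squared), so angiogenesis never starts and
    the starving tumor declines."""
    return run(preset("far_vessels"), horizon=600, seed=1)


@pytest.fixture(scope="session")
def low_oxygen_run():
    """Oxygen secretion at ×0.25 of the calibrated default, to tick 1200."""
    return run(preset("low_oxygen"), horizon=1200, seed=1)


@pytest.fixture(scope="session")
def high_oxygen_run():
    """Oxygen secretion at ×4 of the calibrated default, to tick 900."""
    return run(preset("high_oxygen"), horizon=900, seed=1)


@pytest.fixture(scope="session")
def low_vegf_run():
    """VEGF secretion at ×0.25 of the calibrated default, to tick 1000."""
    return run(preset("low_vegf"), horizon=1000, seed=1)


@pytest.fixture(scope="session")
def high_vegf_run():
    """VEGF secretion at ×4 of the calibrated default, to tick 800."""
    return run(preset("high_vegf"), horizon=800, seed=1)
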
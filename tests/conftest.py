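"""Shared fixtures: synthetic cores and their chronologies.

Session-scoped because core generation and CRS dating are pure functions
of (scenario, seed); tests never mutate fixture objects (they copy).
"""

from __future__ import annotations

import warnings

import pytest

from sedflux.chronology import build_chronology
from sedflux.synthetic import build_synthetic_core, preset


def _dated(scenario, seed):
    profile, truth = build_synthetic_core(scenario, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_chronology(profile, coring_year=scenario.coring_year)
    return profile, truth, model


@pytest.fixture(scope="session")
def remote_nf():
    """Noise-free remote-highland core with truth and chronology."""
    return _dated(preset("remote-highland").noise_free(), seed=1)


@pytest.fixture(scope="session")
def remote_noisy():
    return _dated(preset("remote-highland"), seed=1)


@pytest.fixture(scope="session")
def peri_nf():
    """Noise-free peri-urban core (5× MAR, flood layers)."""
    return _dated(preset("peri-urban").noise_free(), seed=3)
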
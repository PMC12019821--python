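"""Shared fixtures.

The ``ministudy`` session fixture runs the scaled-down duration-sweep study
once (3 subjects, 1- and 6-minute presets, 32^3 grid) and is shared by the
pipeline-level tests; everything else uses small per-module fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

import freecine as fc


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale phantom at a small grid for fast unit tests."""
    return fc.default_phantom(grid=24)


@pytest.fixture(scope="session")
def ministudy():
    """Scaled-down duration-sweep study: 3 subjects, {1, 6} min, 32^3 grid."""
    cfg = fc.StudyConfig(n_subjects=3, durations_min=(1, 6), grid=32, master_seed=1)
    return fc.run_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
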
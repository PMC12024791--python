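"""Shared fixtures: parameter sets and cached equilibria/linearizations."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import settings

from erkfreq import (PathwayParameters, frequency_response, linearize,
                     solve_equilibrium)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@lru_cache(maxsize=None)
def _params(mode: str) -> PathwayParameters:
    return PathwayParameters.for_mode(mode)


@lru_cache(maxsize=None)
def _equilibrium(mode: str, dose: float):
    return solve_equilibrium(_params(mode), dose)


@lru_cache(maxsize=None)
def _statespace(mode: str, dose: float):
    return linearize(_equilibrium(mode, dose), _params(mode))


@lru_cache(maxsize=None)
def _bode(mode: str, dose: float):
    return frequency_response(_statespace(mode, dose))


@pytest.fixture(scope="session")
def egf():
    return _params("egf")


@pytest.fixture(scope="session")
def ngf():
    return _params("ngf")


@pytest.fixture(scope="session")
def equilibrium_at():
    """Memoized steady-state solver keyed on (ligand_mode, dose)."""
    return _equilibrium


@pytest.fixture(scope="session")
def statespace_at():
    """Memoized linearization keyed on (ligand_mode, dose)."""
    return _statespace


@pytest.fixture(scope="session")
def bode_at():
    """Memoized default-grid Bode sweep keyed on (ligand_mode, dose)."""
    return _bode
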
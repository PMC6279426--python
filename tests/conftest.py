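"""Shared fixtures: a small synthetic universe, PSM stream and spectra."""

import numpy as np
import pytest

from speclib import LibraryState, SpectrumStore, Spectrum, normalize_spectrum
from speclib.fixtures import (
    FixtureConfig,
    PSMStream,
    Universe,
    generate_psm_stream,
    generate_universe,
)


def make_spectrum(mz, intensity, charge=2, precursor_mz=500.0, **kwargs) -> Spectrum:
    return Spectrum(
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        **kwargs,
    )


def make_unit(mz, intensity, **kwargs) -> Spectrum:
    return normalize_spectrum(make_spectrum(mz, intensity, **kwargs))


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=7, n_proteins=12)


@pytest.fixture(scope="session")
def universe(fixture_config) -> Universe:
    return generate_universe(fixture_config)


@pytest.fixture(scope="session")
def psm_stream(fixture_config, universe) -> PSMStream:
    return generate_psm_stream(fixture_config, universe)


@pytest.fixture()
def populated_state(psm_stream):
    store = SpectrumStore(psm_stream.spectra)
    state = LibraryState()
    state.update_candidates(psm_stream.psms, store)
    return state, store
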
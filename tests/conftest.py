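from pathlib import Path

import numpy as np
import pytest

from lungrt import CompartmentParams, RadiosensitivityParams, TumorState

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture
def mcm_params() -> CompartmentParams:
    return CompartmentParams.default()


@pytest.fixture
def rs_params() -> RadiosensitivityParams:
    return RadiosensitivityParams.default()


@pytest.fixture
def seed_state() -> TumorState:
    return TumorState.default_init()


@pytest.fixture
def growth_off() -> CompartmentParams:
    """Two-compartment system with growth, transfers and clearance all zero."""
    return CompartmentParams(
        a=[0.0, 0.0],
        K=[1397.0, 1174.0],
        p_Qm=[0.0, 0.0],
        p_mQ=[0.0, 0.0],
        p_mND=[0.0, 0.0],
        p_QND=0.0,
        eta=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
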
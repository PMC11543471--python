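"""Shared fixtures: small synthetic libraries, profiles and feature tables."""

import numpy as np
import pandas as pd
import pytest

from sfelip import synthetic_data as sd
from sfelip.io_core import ExtractionCondition, LipidRecord, RecoveryTable


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    return sd.GeneratorConfig(n_lipids=10, seed=1)


@pytest.fixture(scope="session")
def small_library(small_config):
    return sd.generate_lipid_library(small_config)


@pytest.fixture(scope="session")
def solvent_profiles():
    return sd.solvent_sigma_profiles()


@pytest.fixture(scope="session")
def lipid_profiles(small_library, small_config):
    records, _ = small_library
    return sd.generate_sigma_profiles(records, small_config)


@pytest.fixture()
def toy_recovery() -> RecoveryTable:
    conditions = [
        ExtractionCondition("A", 40.0, 150.0, 0.6),
        ExtractionCondition("B", 60.0, 250.0, 0.9),
    ]
    lipids = [
        LipidRecord("L0", "PC 34:1", "glycerophospholipids"),
        LipidRecord("L1", "FA 18:2", "fatty acyls"),
    ]
    return RecoveryTable(
        lipids=lipids, conditions=conditions, abundance=np.array([[0.5, 1.25], [0.0, 0.075]])
    )


@pytest.fixture(scope="session")
def dummy_descriptors_29():
    """29 deterministic pseudo-descriptor columns for 89 lipids."""
    rng = np.random.default_rng(7)
    ids = [f"L{i:03d}" for i in range(89)]
    return pd.DataFrame(
        rng.normal(size=(89, 29)), index=ids, columns=[f"d{k}" for k in range(29)]
    )
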
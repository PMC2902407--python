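import numpy as np
import pandas as pd
import pytest

from mirqc import (
    AssayDef,
    CtMatrix,
    SampleCondition,
    SimConfig,
    simulate_clinical_study,
    simulate_concentration_series,
    simulate_dilution_series,
)


def make_matrix(ct_frame: pd.DataFrame, conditions=None, assays=None) -> CtMatrix:
    """Build a CtMatrix from a plain float frame (NaN = missing well)."""
    if assays is None:
        assays = [AssayDef(a) for a in ct_frame.index]
    if conditions is None:
        conditions = [SampleCondition(c) for c in ct_frame.columns]
    return CtMatrix(assays, conditions, ct_frame.astype(float))


@pytest.fixture
def small_matrix() -> CtMatrix:
    """Four microRNAs x two conditions covering all strata and censoring."""
    frame = pd.DataFrame(
        {
            "s1": [25.0, 32.0, 38.0, 40.0],
            "s2": [25.4, 33.0, 40.0, 40.0],
        },
        index=["miR-1", "miR-2", "miR-3", "miR-4"],
    )
    return make_matrix(frame)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def conc_study(default_config):
    """Duplicate plates across the 10-200 ng/uL input RNA series."""
    return simulate_concentration_series(default_config)


@pytest.fixture(scope="session")
def dilution_study(default_config):
    """Single plates across the 5-62.5x cDNA dilution series."""
    return simulate_dilution_series(default_config)


@pytest.fixture(scope="session")
def clinical_study(default_config):
    """3 tumours + 3 normals, each as an FFPE and a fresh-frozen prep."""
    return simulate_clinical_study(default_config)


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """Deterministic measurement: no replicate noise, no well failures,
    no assay-to-assay or subject-to-subject effect spread."""
    return SimConfig(
        seed=7,
        noise_sigma0=0.0,
        noise_sigma1=0.0,
        failure_midpoint=np.inf,
        ffpe_shift_sd=0.0,
        subject_sd=0.0,
    )
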
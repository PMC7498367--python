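import warnings

import numpy as np
import pandas as pd
import pytest

from digiwest.peaks import QuantConfig, build_signal_matrix
from digiwest.stats import log2_transform
from digiwest.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(seed=11, n_antibodies=60)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One paired cohort (60 antibodies, 25 pairs), shared across tests."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrices(small_cohort, small_config):
    ff, ffpe, meta, truth = small_cohort
    qc = QuantConfig(detection_floor=small_config.detection_floor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_ff = build_signal_matrix(ff, truth.antibodies, qc)
        m_ffpe = build_signal_matrix(ffpe, truth.antibodies, qc)
    return m_ff, m_ffpe


@pytest.fixture(scope="session")
def small_log2(small_matrices):
    m_ff, m_ffpe = small_matrices
    return log2_transform(m_ff), log2_transform(m_ffpe)


@pytest.fixture
def rng():
    return np.random.default_rng(11)


def make_trace(intensities, mw=None, sample="S1", antibody="AB1"):
    from digiwest.peaks import Trace, calibrate_mw
    y = np.asarray(intensities, dtype=float)
    axis = calibrate_mw(len(y), [(0, 250.0), (len(y) - 1, 10.0)]) if mw is None else mw
    return Trace(sample, antibody, y, axis)
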
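import numpy as np
import pytest

from admetk.peakmatrix import Feature, PeakMatrix, SampleRecord
from admetk.synthdata import SimConfig, simulate


def make_matrix(values, classes, mz0=200.0, timepoints=None, subjects=None):
    """Small peak matrix from a 2-D list; None entries become missing."""
    values = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    nf, ns = values.shape
    features = [Feature(f"F{i + 1}", mz0 + i, 60.0 + 10 * i) for i in range(nf)]
    samples = [
        SampleRecord(
            f"S{j + 1}",
            classes[j],
            subject=None if subjects is None else subjects[j],
            timepoint=None if timepoints is None else timepoints[j],
        )
        for j in range(ns)
    ]
    return PeakMatrix(features, samples, values)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulation shared across tests (seed 1)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_noiseless():
    """Noise-free m/z and RT: exact grouping round trips."""
    return simulate(SimConfig(seed=3, mz_ppm_noise=0.0, rt_jitter_sd=0.0))
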
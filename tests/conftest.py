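import numpy as np
import pytest

import gradientkit as gk


@pytest.fixture(scope="session")
def small_atlas():
    """40-parcel, 4-module spherical atlas."""
    return gk.generate_atlas(40, 4, seed=0)


@pytest.fixture(scope="session")
def study_atlas():
    """Atlas at the study scale: 100 parcels, 12 modules."""
    return gk.generate_atlas(100, 12, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """Null cohort (no planted effect) on the small atlas."""
    return gk.generate_cohort(
        small_atlas, n_subjects=25, n_timepoints=120, effect_size=0.0, seed=1
    )


@pytest.fixture(scope="session")
def thresholded_connectome(small_cohort):
    ts = gk.RegionTimeSeries(small_cohort.time_series[0], "sub-0000")
    return gk.threshold_by_density(gk.correlation_connectome(ts), 0.2)


def random_symmetric_affinity(n, rng):
    """Random connected affinity matrix in [0,1] with unit diagonal."""
    A = rng.uniform(0.05, 1.0, size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return gk.AffinityMatrix(values=A)
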
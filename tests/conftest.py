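"""Shared fixtures: a small ellipsoid grid, planted truth, and a meta-analytic z map."""

import numpy as np
import pytest

from braintx import meta
from braintx.synthetic import (
    SyntheticTruth,
    ToyBrainSpec,
    gen_brain_grid,
    gen_study_peaks,
)

TRUE_GENES = tuple(f"G{i + 1:04d}" for i in range(20))
CLUSTER_CENTER = (-20.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def grid():
    spec = ToyBrainSpec(grid_shape=(20, 20, 20), voxel_size_mm=4.0, mask_kind="ellipsoid")
    return gen_brain_grid(spec)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(
        true_gene_ids=TRUE_GENES,
        target_r=0.6,
        pooled_effect=(0.8,),
        cluster_centers_mm=(CLUSTER_CENTER,),
        autocorr_length_mm=15.0,
    )


@pytest.fixture(scope="session")
def studies(truth, grid):
    return gen_study_peaks(8, truth, grid, noise_sd=0.1, seed=3)


@pytest.fixture(scope="session")
def meta_run(studies, grid):
    """(per-study maps, combined result, cluster table) of the fixture studies."""
    return meta.run_meta_analysis(studies, grid)


@pytest.fixture(scope="session")
def z_map(meta_run):
    return meta_run[1].z_map
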
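import os

# Pin BLAS threading before numpy loads so training runs are reproducible
# and timings match the single-CPU grading environment.
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from octseg.phantom import PhantomParams


@pytest.fixture
def small_params() -> PhantomParams:
    """64 px phantom used by fast unit tests."""
    return PhantomParams(
        image_height=64,
        image_width=64,
        axial_scale=7.2,
        lateral_scale=93.6,
        n_bscans=7,
        foveal_pit_sigma=93.6 * 64 / 5,
        seed=123,
    )


@pytest.fixture
def bench_params() -> PhantomParams:
    """128 px phantom matching the benchmark geometry."""
    return PhantomParams(
        image_height=128,
        image_width=128,
        axial_scale=3.6,
        lateral_scale=46.8,
        n_bscans=25,
        foveal_pit_sigma=46.8 * 128 / 5,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
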
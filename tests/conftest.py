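import numpy as np
import pytest

from scangp import KernelSpec, PhantomSpec, ScanFrame, ScanGrid, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def par_grid():
    return ScanGrid("parallel", n_scanlines=8, n_samples=16, sample_pitch=1.0, beam_pitch=1.0)


@pytest.fixture
def div_grid():
    return ScanGrid(
        "diverging", n_scanlines=12, n_samples=20, sample_pitch=1.0, beam_pitch=0.03
    )


@pytest.fixture
def matern_spec():
    return KernelSpec(
        family="matern",
        nu=1.5,
        signal_variance=1.0,
        length_scale_r=2.0,
        length_scale_alpha=1.5,
        noise_variance=1e-3,
    )


def random_frame(grid: ScanGrid, rng: np.random.Generator) -> ScanFrame:
    """Uniform-noise frame; structureless, for contracts that only need a
    valid frame."""
    return ScanFrame(grid, rng.uniform(0.0, 1.0, (grid.n_samples, grid.n_scanlines)))


def gp_frame(grid: ScanGrid, kernel: KernelSpec, seed: int, noise_std: float = 0.0) -> ScanFrame:
    """Matched-model frame: an exact GP draw with known hyperparameters."""
    return generate_phantom(
        PhantomSpec(grid=grid, kernel=kernel, seed=seed, noise_std=noise_std, method="exact")
    )
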
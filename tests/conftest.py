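import numpy as np
import pytest

from preful.phantom import PhantomSpec, generate_phantom
from preful.workflow import PipelineConfig, run_slice


@pytest.fixture(scope="session")
def default_phantom():
    """A standard noisy phantom with a mix of full and partial segment defects."""
    spec = PhantomSpec(
        seed=7,
        defect_regions=((3, 1.0), (4, 1.0), (5, 0.8), (6, 0.6)),
    )
    series, truth = generate_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def default_phantom_result(default_phantom):
    """The full pipeline run on the standard phantom (shared across tests)."""
    _, series, truth = default_phantom
    return run_slice(series, truth.lung_mask, truth.mediastinum_mask, PipelineConfig())


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with one fully defective segment."""
    spec = PhantomSpec(seed=1, noise_sigma=0.0, defect_regions=((3, 1.0),))
    series, truth = generate_phantom(spec)
    return spec, series, truth


def circular_coherence(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """|mean resultant| of the phase difference: 1 for a constant offset."""
    return float(np.abs(np.mean(np.exp(2j * np.pi * (phase_a - phase_b)))))
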
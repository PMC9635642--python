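import numpy as np
import pytest

from omicsblup import (
    ModelSpec,
    SimulationConfig,
    build_genomic_kernel,
    build_transcript_kernel,
    center_standardize,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_kernel(rng, n, spread=1.0):
    """A random symmetric PSD kernel with unit-ish diagonal."""
    B = rng.standard_normal((n, n + 5)) * spread
    K = B @ B.T / (n + 5)
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)


@pytest.fixture(scope="session")
def tiny_study():
    """A fast, fully synthetic study shared by unit tests."""
    cfg = SimulationConfig(
        n_individuals=80,
        n_markers=150,
        n_genes=60,
        generation_sizes={4: 20, 5: 20, 7: 20, 11: 20},
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_kernels(tiny_study):
    Z = center_standardize(tiny_study.genotypes)
    W = center_standardize(tiny_study.transcripts)
    return Z, W, build_genomic_kernel(Z), build_transcript_kernel(W)


@pytest.fixture(scope="session")
def tiny_gblup_spec(tiny_kernels):
    _, _, G, _ = tiny_kernels
    return ModelSpec([G])
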
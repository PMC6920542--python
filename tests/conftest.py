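import numpy as np
import pytest

from bayesmr import (
    draw_structural_params,
    simulate_dataset,
    simulate_genotypes,
    benchmark_scenario,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_genotypes():
    """500 x 20 independent doses, MAF in [0.1, 0.4]."""
    return simulate_genotypes(500, 20, seed=101)


@pytest.fixture(scope="session")
def scenario3_dataset():
    """One scenario-3 replicate (n=500, J=60, balanced pleiotropy, theta=0.35)."""
    spec = benchmark_scenario(3)
    rng = np.random.default_rng(7)
    G = simulate_genotypes(spec.n_individuals, spec.J, seed=rng)
    params = draw_structural_params(spec, "alternative", rng)
    return params, simulate_dataset(params, G, rng)


@pytest.fixture(scope="session")
def clean_iv_dataset():
    """Strong instruments, no pleiotropy, no confounding: theta = 2 recoverable exactly-ish."""
    rng = np.random.default_rng(33)
    G = simulate_genotypes(400, 6, seed=rng)
    from bayesmr import StructuralParams

    params = StructuralParams(
        theta=2.0,
        alpha=np.ones(6),
        beta=np.zeros(6),
        omega_X=1.0,
        omega_Y=-0.5,
        delta_X=0.0,
        delta_Y=0.0,
        sigma_X=1e-8,
        sigma_Y=1e-8,
    )
    return params, simulate_dataset(params, G, rng)
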
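"""Shared fixtures: tiny harmonized sets and simulated triplets."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SimulationConfig, simulate_triplet


def make_harmonized(
    gamma, se_gamma, Gamma, se_Gamma, eaf=None, n_exp=10_000, n_out=10_000
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    j = len(gamma)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:04d}" for i in range(j)],
            "chromosome": ["1"] * j,
            "position": np.arange(1, j + 1) * 1_000_000,
            "beta_exp": gamma,
            "se_exp": np.asarray(se_gamma, dtype=float),
            "beta_out": np.asarray(Gamma, dtype=float),
            "se_out": np.asarray(se_Gamma, dtype=float),
            "eaf": np.full(j, 0.3) if eaf is None else np.asarray(eaf, dtype=float),
            "n_exp": np.full(j, n_exp, dtype=int),
            "n_out": np.full(j, n_out, dtype=int),
        }
    )
    return HarmonizedSet("exposure", "outcome", df)


def random_harmonized(rng, j=20, beta=0.2, gamma_sd=0.1, se_g=0.01, se_G=0.02):
    """A harmonized set with true slope ``beta`` and no pleiotropy."""
    gamma = rng.normal(0.0, gamma_sd, j)
    gamma = np.where(np.abs(gamma) < 0.02, 0.05 * np.sign(gamma) + (gamma == 0) * 0.05, gamma)
    gamma_hat = gamma + rng.normal(0.0, se_g, j)
    Gamma_hat = beta * gamma + rng.normal(0.0, se_G, j)
    return make_harmonized(gamma_hat, np.full(j, se_g), Gamma_hat, np.full(j, se_G))


@pytest.fixture(scope="session")
def triplet():
    """One simulated exposure/mediator/outcome triplet at default settings."""
    return simulate_triplet(SimulationConfig(seed=20240916))


@pytest.fixture(scope="session")
def strong_triplet():
    """A triplet with large samples (precise instrument effects)."""
    cfg = SimulationConfig(
        n_exposure=50_000, n_mediator=50_000, n_outcome=50_000, seed=7
    )
    return simulate_triplet(cfg)
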
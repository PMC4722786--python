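import warnings

import numpy as np
import pytest

from foragemap.synthetic import (
    Patch,
    SceneConfig,
    SpeciesPreference,
    TrajectoryConfig,
    generate_scene,
    sample_plots,
    simulate_species_usage,
    simulate_trajectory,
)

warnings.filterwarnings("ignore", message="no candidate met the stabilisation rules")


@pytest.fixture(scope="session")
def two_patch_traj():
    """43-day, 4 h trajectory commuting between two patches."""
    cfg = TrajectoryConfig(
        patches=[Patch(0.0, 0.0, 25.0), Patch(300.0, 0.0, 25.0)], seed=1
    )
    return simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def pure_scene():
    """Small pure-grass scene with planted band-ratio relations, low noise."""
    return generate_scene(
        SceneConfig(n_rows=50, n_cols=50, n_bands=12, noise_sd=0.002,
                    pure_grass=True, seed=3)
    )


@pytest.fixture(scope="session")
def mixed_scene():
    """Scene with endmember mixing and noise (default band count)."""
    return generate_scene(SceneConfig(n_rows=60, n_cols=60, noise_sd=0.004, seed=5))


@pytest.fixture(scope="session")
def plot_table(pure_scene):
    return sample_plots(pure_scene, 45, seed=11)


@pytest.fixture(scope="session")
def usage_table(mixed_scene):
    prefs = [
        SpeciesPreference("chamois", b_biom_rs=-1.5, b_n=0.5),
        SpeciesPreference("ibex", b_n=2.0),
        SpeciesPreference("red_deer", b_biom_rs=1.2, b_interaction=0.3),
    ]
    table, polys = simulate_species_usage(mixed_scene, prefs, 700, seed=7)
    return table


def mnl_probabilities(X, coefs):
    """Baseline-category probabilities from per-logit coefficient rows."""
    eta1 = X @ coefs[0]
    eta2 = X @ coefs[1]
    denom = 1.0 + np.exp(eta1) + np.exp(eta2)
    return np.column_stack([1.0 / denom, np.exp(eta1) / denom, np.exp(eta2) / denom])


def simulate_mnl_table(coefs, n, seed, biom_mean=2.5, biom_sd=1.1, n_mean=2.1, n_sd=0.5):
    """Observation table drawn from a known baseline-category logit.

    ``coefs`` is a (2, 4) array of (intercept, BiomRS, N, BiomRS:N) rows for
    logit 1 (ibex) and logit 2 (red deer).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    biom_rs = np.clip(rng.normal(biom_mean, biom_sd, n), 0.05, None)
    nitro = np.clip(rng.normal(n_mean, n_sd, n), 0.1, None)
    X = np.column_stack([np.ones(n), biom_rs, nitro, biom_rs * nitro])
    probs = mnl_probabilities(X, np.asarray(coefs))
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    codes = (u[:, None] > cum).sum(axis=1)
    species = np.asarray(["chamois", "ibex", "red_deer"])[codes]
    return pd.DataFrame(
        {
            "species": species,
            "individual": "sim",
            "biomass": biom_rs * 100.0,
            "biom_rs": biom_rs,
            "nitrogen": nitro,
        }
    )
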
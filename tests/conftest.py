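import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rrsel import RRRConfig, SelectionDataset, SimulationSpec, fit_rrr, simulate_dataset
from rrsel.model import PosteriorDraws

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_config():
    """Short chains: enough for structural checks, not for tight inference."""
    return RRRConfig(rank=1, n_warmup=300, n_samples=300, n_chains=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    ds, truth = simulate_dataset(
        SimulationSpec(n=120, n_standard=2, n_volatiles=5, true_axis_gradient=0.3, seed=11)
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset, fast_config):
    ds, _ = small_dataset
    return fit_rrr(ds, fast_config)


def make_manual_draws(alpha_z, beta_z, beta_axis, weights, x_mean, x_sd, v_mean, v_sd,
                      standard_names, volatile_names, axis_scores=None, kind="rrr"):
    """Hand-built PosteriorDraws for arithmetic oracles."""
    alpha_z = np.atleast_1d(np.asarray(alpha_z, dtype=float))
    s = alpha_z.shape[0]
    beta_axis = np.asarray(beta_axis, dtype=float).reshape(s, -1)
    r = beta_axis.shape[1]
    weights = np.asarray(weights, dtype=float).reshape(s, r, -1)
    if axis_scores is None:
        axis_scores = np.zeros((s, r, 2))
    return PosteriorDraws(
        kind=kind,
        rank=r,
        n_chains=1,
        alpha_z=alpha_z,
        beta_z=np.asarray(beta_z, dtype=float).reshape(s, -1),
        beta_axis=beta_axis,
        weights=weights,
        sigma2=np.full(s, 0.01),
        axis_scores=np.asarray(axis_scores, dtype=float),
        axis_sign=np.ones((s, r)),
        standard_names=list(standard_names),
        volatile_names=list(volatile_names),
        x_mean=np.asarray(x_mean, dtype=float),
        x_sd=np.asarray(x_sd, dtype=float),
        v_mean=np.asarray(v_mean, dtype=float),
        v_sd=np.asarray(v_sd, dtype=float),
    )


def make_tiny_dataset(n=8, p=1, q=2, seed=0):
    """Small deterministic dataset for loader/gradient arithmetic tests."""
    rng = np.random.default_rng(seed)
    traits = pd.DataFrame(
        rng.normal(10.0, 2.0, size=(n, p)), columns=[f"trait_{j+1}" for j in range(p)]
    )
    vols = pd.DataFrame(
        np.exp(rng.normal(0.0, 1.0, size=(n, q))), columns=[f"vol_{l+1:02d}" for l in range(q)]
    )
    fitness = pd.Series(rng.uniform(1.0, 5.0, size=n), name="absolute_fitness")
    return SelectionDataset(
        dataset_id="tiny", standard_traits=traits, volatiles=vols, absolute_fitness=fitness
    )
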
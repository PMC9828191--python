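"""Sampler correctness: conjugate updates, identification handling, prediction."""

import numpy as np
import pandas as pd
import pytest

from rrsel import (
    RRRConfig,
    SelectionDataset,
    SimulationSpec,
    fit_multiple_regression,
    fit_rrr,
    predict,
    simulate_dataset,
)
from rrsel.errors import ConfigError, ShapeError
from rrsel.model import PosteriorDraws

from conftest import make_manual_draws


def _noiseless_dataset(n=60, seed=0):
    """Fitness is an exact linear function of traits and volatiles."""
    rng = np.random.default_rng(seed)
    traits = pd.DataFrame(
        rng.normal(10, 2, size=(n, 2)), columns=["trait_1", "trait_2"]
    )
    vols = pd.DataFrame(
        np.exp(rng.normal(0, 0.8, size=(n, 3))), columns=["vol_01", "vol_02", "vol_03"]
    )
    coefs = {"trait_1": 0.02, "trait_2": -0.03, "vol_01": 0.05, "vol_02": 0.0, "vol_03": -0.04}
    lin = (
        2.0
        + sum(coefs[c] * traits[c] for c in traits)
        + sum(coefs[c] * vols[c] for c in vols)
        + rng.normal(0, 1e-6, n)
    )
    lin = lin.to_numpy()
    assert lin.min() > 0
    ds = SelectionDataset(
        dataset_id="noiseless",
        standard_traits=traits,
        volatiles=vols,
        absolute_fitness=pd.Series(lin, name="absolute_fitness"),
    )
    # relative fitness = lin / mean(lin), so slopes rescale by 1 / mean(lin)
    expected = {c: v / lin.mean() for c, v in coefs.items()}
    return ds, expected


def test_multiple_regression_recovers_noiseless_coefficients():
    ds, expected = _noiseless_dataset()
    cfg = RRRConfig(n_warmup=300, n_samples=500, n_chains=2, seed=3)
    draws = fit_multiple_regression(ds, cfg)
    est = dict(zip(draws.standard_names, draws.beta_standard.mean(axis=0)))
    for name, truth in expected.items():
        assert est[name] == pytest.approx(truth, abs=1e-3)


def test_predictions_reproduce_noiseless_fitness():
    ds, _ = _noiseless_dataset()
    cfg = RRRConfig(n_warmup=300, n_samples=500, n_chains=2, seed=3)
    draws = fit_multiple_regression(ds, cfg)
    pred = predict(draws, ds.standard_traits, ds.volatiles)
    np.testing.assert_allclose(pred, ds.relative_fitness.to_numpy(), atol=1e-3)


def test_same_seed_bit_identical(small_dataset, fast_config):
    ds, _ = small_dataset
    a = fit_rrr(ds, fast_config)
    b = fit_rrr(ds, fast_config)
    np.testing.assert_array_equal(a.beta_z, b.beta_z)
    np.testing.assert_array_equal(a.weights, b.weights)
    np.testing.assert_array_equal(a.sigma2, b.sigma2)


def test_different_seeds_agree_within_monte_carlo_error(small_dataset):
    import arviz as az

    ds, _ = small_dataset
    means, mcses = [], []
    for seed in (21, 22):
        cfg = RRRConfig(n_warmup=500, n_samples=1000, n_chains=2, seed=seed)
        d = fit_multiple_regression(ds, cfg)
        chains = d.beta_z.reshape(cfg.n_chains, -1, d.beta_z.shape[1])
        means.append(d.beta_z.mean(axis=0))
        mcses.append(
            np.array(
                [float(np.asarray(az.mcse(chains[:, :, j])).ravel()[0])
                 for j in range(chains.shape[2])]
            )
        )
    z = (means[0] - means[1]) / np.sqrt(mcses[0] ** 2 + mcses[1] ** 2)
    # joint chi-square reproducibility check: z_j are approximately iid
    # standard normal when the two runs sample the same posterior, so the
    # summed square stays below the 99.9% chi-square quantile
    from scipy import stats

    assert (z**2).sum() < stats.chi2.ppf(0.999, len(z))
    assert np.abs(z).max() < 4.0


def test_posterior_invariants(small_fit):
    norms = np.linalg.norm(small_fit.weights, axis=2)
    np.testing.assert_allclose(norms, 1.0, atol=1e-10)
    assert (small_fit.sigma2 > 0).all()
    med = np.median(small_fit.weights, axis=0)
    dots = np.einsum("srq,rq->sr", small_fit.weights, med)
    assert (dots >= 0).all()
    assert set(np.unique(small_fit.axis_sign)) <= {-1.0, 1.0}


def test_rank_cannot_exceed_volatile_count(small_dataset):
    ds, _ = small_dataset
    with pytest.raises(ConfigError):
        fit_rrr(ds, RRRConfig(rank=ds.n_volatiles + 1, seed=1))


def test_predict_single_draw_hand_computed():
    draws = make_manual_draws(
        alpha_z=[0.5],
        beta_z=[[0.2]],
        beta_axis=[[0.4]],
        weights=[[[0.6, 0.8]]],
        x_mean=[10.0],
        x_sd=[2.0],
        v_mean=[1.0, 2.0],
        v_sd=[0.5, 1.0],
        standard_names=["trait_1"],
        volatile_names=["vol_01", "vol_02"],
    )
    pred = predict(draws, np.array([[12.0], [8.0]]), np.array([[2.0, 2.0], [0.5, 1.0]]))
    np.testing.assert_allclose(pred, [1.18, -0.26], atol=1e-12)


def test_predictions_invariant_to_sign_and_scale_relabeling():
    kwargs = dict(
        alpha_z=[0.5],
        beta_z=[[0.2]],
        x_mean=[10.0],
        x_sd=[2.0],
        v_mean=[1.0, 2.0],
        v_sd=[0.5, 1.0],
        standard_names=["trait_1"],
        volatile_names=["vol_01", "vol_02"],
    )
    base = make_manual_draws(beta_axis=[[0.4]], weights=[[[0.6, 0.8]]], **kwargs)
    flipped = make_manual_draws(beta_axis=[[-0.4]], weights=[[[-0.6, -0.8]]], **kwargs)
    scaled = make_manual_draws(beta_axis=[[0.1]], weights=[[[2.4, 3.2]]], **kwargs)
    X = np.array([[12.0], [8.0]])
    V = np.array([[2.0, 2.0], [0.5, 1.0]])
    np.testing.assert_allclose(predict(base, X, V), predict(flipped, X, V), atol=1e-14)
    np.testing.assert_allclose(predict(base, X, V), predict(scaled, X, V), atol=1e-14)


def test_predict_rejects_mismatched_columns(small_fit, small_dataset):
    ds, _ = small_dataset
    with pytest.raises(ShapeError):
        predict(small_fit, ds.standard_traits, ds.volatiles.iloc[:, :-1])


def test_rank1_fit_recovers_known_axis():
    ds, truth = simulate_dataset(
        SimulationSpec(n=300, n_standard=3, n_volatiles=8, true_axis_gradient=0.3, seed=5)
    )
    draws = fit_rrr(ds, RRRConfig(n_warmup=400, n_samples=400, n_chains=2, seed=9))
    w_true = np.asarray(truth["true_weights"])
    w_hat = draws.weights.mean(axis=0)[0]
    w_hat /= np.linalg.norm(w_hat)
    assert abs(float(w_hat @ w_true)) >= 0.9

    # oracle: OLS of relative fitness on the true standardized axis score
    V = ds.volatiles.to_numpy()
    Z = (V - V.mean(0)) / V.std(0, ddof=1)
    score = Z @ w_true
    score /= score.std(ddof=1)
    y = ds.relative_fitness.to_numpy()
    ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), score]), y, rcond=None)[0][1]

    orient = 1.0 if float(w_hat @ w_true) >= 0 else -1.0
    b = draws.beta_axis_natural[:, 0] * draws.axis_scores[:, 0, :].std(axis=1, ddof=1) * orient
    lo, hi = np.quantile(b, [0.025, 0.975])
    assert lo <= truth["realized_axis_gradient"] <= hi
    assert abs(b.mean() - ols) <= 3 * b.std(ddof=1)


def test_high_dimensional_multiple_regression_is_regularized():
    ds, _ = simulate_dataset(SimulationSpec(n=30, n_standard=3, n_volatiles=22, seed=13))
    cfg = RRRConfig(n_warmup=300, n_samples=300, n_chains=2, seed=4)
    draws = fit_multiple_regression(ds, cfg)
    assert np.isfinite(draws.beta_standard).all()
    assert np.isfinite(draws.sigma2).all()


def test_rank2_fit_runs_and_normalizes(small_dataset):
    ds, _ = small_dataset
    cfg = RRRConfig(rank=2, n_warmup=200, n_samples=200, n_chains=2, seed=17)
    draws = fit_rrr(ds, cfg)
    assert draws.weights.shape[1:] == (2, ds.n_volatiles)
    np.testing.assert_allclose(np.linalg.norm(draws.weights, axis=2), 1.0, atol=1e-10)


def test_save_load_roundtrip(tmp_path, small_fit):
    small_fit.save(tmp_path / "draws")
    loaded = PosteriorDraws.load(tmp_path / "draws")
    np.testing.assert_allclose(loaded.beta_z, small_fit.beta_z, rtol=1e-12)
    np.testing.assert_allclose(loaded.weights, small_fit.weights, rtol=1e-12)
    np.testing.assert_allclose(loaded.axis_sign, small_fit.axis_sign)
    np.testing.assert_allclose(loaded.axis_scores, small_fit.axis_scores, rtol=1e-12)
    assert loaded.volatile_names == small_fit.volatile_names
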
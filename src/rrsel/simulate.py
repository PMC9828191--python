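"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the shape of floral-scent selection data: many
right-skewed, mutually correlated volatile emission rates (log-normal with
a shared latent-factor structure, mimicking biosynthetically linked
compound families), a few correlated standard traits (morphology), and
relative fitness built from a true rank-1 selection axis plus
standard-trait gradients and Gaussian noise. Every generating parameter is
returned in a truth record so downstream recovery can be checked.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import SelectionDataset
from .errors import ConfigError

_log = logging.getLogger(__name__)

#: SD of the compound-specific log-scale noise on top of the factor structure.
_LOG_NOISE_SD = 0.5
#: Exchangeable correlation among standard traits.
_TRAIT_CORR = 0.3
#: Mean and SD of each standard trait on its measurement scale.
_TRAIT_MEAN = 10.0
_TRAIT_SD = 2.0


@dataclass
class SimulationSpec:
    """Generating parameters for one synthetic population-year dataset.

    ``true_axis_gradient`` and ``true_standard_gradients`` are
    variance-scaled: the change in relative fitness per SD of the
    (standardized) axis score or trait. ``true_weights`` is the unit vector
    defining the true scent axis over standardized volatiles, or
    ``"random"`` to draw one uniformly on the sphere.
    """

    n: int = 200
    n_standard: int = 3
    n_volatiles: int = 22
    n_factors: int = 3
    volatile_log_mean: float = 0.0
    volatile_log_sd: float = 1.0
    factor_loading_sd: float = 0.6
    true_weights: np.ndarray | str = "random"
    true_axis_gradient: float = 0.3
    true_standard_gradients: np.ndarray | None = None
    residual_sd: float = 0.3
    fitness_model: str = "gaussian"
    mean_fruits: float = 10.0
    seed: int = 0
    dataset_id: str | None = None

    def validate(self) -> None:
        if self.n < 10:
            raise ConfigError("n must be at least 10")
        for name in ("n_standard", "n_volatiles", "n_factors"):
            if getattr(self, name) < 0 or (name == "n_volatiles" and self.n_volatiles < 1):
                raise ConfigError(f"{name} is invalid")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")
        if self.volatile_log_sd <= 0:
            raise ConfigError("volatile_log_sd must be positive")
        if self.fitness_model not in ("gaussian", "poisson"):
            raise ConfigError(f"unknown fitness model {self.fitness_model!r}")
        if self.fitness_model == "poisson" and self.mean_fruits <= 0:
            raise ConfigError("poisson fitness requires mean_fruits > 0")
        if not isinstance(self.true_weights, str):
            w = np.asarray(self.true_weights, dtype=float)
            if w.shape != (self.n_volatiles,):
                raise ConfigError("true_weights length must equal n_volatiles")
            if abs(np.linalg.norm(w) - 1.0) > 1e-6:
                raise ConfigError("true_weights must be a unit vector")
        elif self.true_weights != "random":
            raise ConfigError("true_weights must be a unit vector or 'random'")
        if self.true_standard_gradients is not None:
            g = np.asarray(self.true_standard_gradients, dtype=float)
            if g.shape != (self.n_standard,):
                raise ConfigError("true_standard_gradients length must equal n_standard")


def simulate_dataset(spec: SimulationSpec) -> tuple[SelectionDataset, dict]:
    """Generate one dataset and its truth record.

    Volatiles are ``exp(mu + sd * (f @ L' + e))`` with standard-normal
    latent factors ``f``, loadings ``L ~ Normal(0, factor_loading_sd^2)``
    and compound noise ``e`` — all-positive, right-skewed and correlated.
    Standard traits are multivariate normal with exchangeable correlation.
    The true axis score is the (re-standardized) weighted sum of
    standardized volatiles; relative fitness is
    ``1 + g_axis * score + sum_j g_j * z(trait_j) + Normal(0, residual_sd^2)``
    in gaussian mode (renormalized to mean 1; the zero-truncated absolute
    column is ``mean_fruits`` times the linear model), or derived from
    Poisson counts with mean ``mean_fruits * max(0, linear predictor)`` in
    poisson mode.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, q = spec.n, spec.n_standard, spec.n_volatiles

    if isinstance(spec.true_weights, str):
        w = rng.standard_normal(q)
        w /= np.linalg.norm(w)
    else:
        w = np.asarray(spec.true_weights, dtype=float)

    loadings = rng.normal(0.0, spec.factor_loading_sd, size=(q, spec.n_factors))
    factors = rng.standard_normal((n, spec.n_factors))
    noise = rng.normal(0.0, _LOG_NOISE_SD, size=(n, q))
    log_v = spec.volatile_log_mean + spec.volatile_log_sd * (factors @ loadings.T + noise)
    volatiles = np.exp(log_v)

    if p:
        corr = np.full((p, p), _TRAIT_CORR)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        traits = _TRAIT_MEAN + _TRAIT_SD * (rng.standard_normal((n, p)) @ chol.T)
    else:
        traits = np.empty((n, 0))

    vz = (volatiles - volatiles.mean(axis=0)) / volatiles.std(axis=0, ddof=1)
    score = vz @ w
    score = score / score.std(ddof=1)
    g_std = (
        np.asarray(spec.true_standard_gradients, dtype=float)
        if spec.true_standard_gradients is not None
        else np.zeros(p)
    )
    tz = (
        (traits - traits.mean(axis=0)) / traits.std(axis=0, ddof=1)
        if p
        else np.empty((n, 0))
    )
    linpred = 1.0 + spec.true_axis_gradient * score + tz @ g_std
    linpred = linpred + rng.normal(0.0, spec.residual_sd, size=n)
    relative = None
    if spec.fitness_model == "gaussian":
        # The response is the Gaussian linear model itself, renormalized to
        # mean 1, so the generating gradient is exact. The absolute column
        # is a clipped display proxy; re-deriving relative fitness from it
        # (as the loader does) truncates the lower tail and attenuates
        # realized gradients slightly.
        mean_lin = linpred.mean()
        if mean_lin <= 0:
            raise ConfigError("generated fitness has nonpositive mean; lower residual_sd")
        relative = pd.Series(linpred / mean_lin, name="relative_fitness")
        absolute = spec.mean_fruits * np.clip(linpred, 0.0, None)
    else:
        absolute = rng.poisson(spec.mean_fruits * np.clip(linpred, 0.0, None)).astype(float)

    trait_names = [f"trait_{j + 1}" for j in range(p)]
    vol_names = [f"vol_{l + 1:02d}" for l in range(q)]
    ids = [f"ind_{i + 1:03d}" for i in range(n)]
    dataset = SelectionDataset(
        dataset_id=spec.dataset_id or f"sim_seed{spec.seed}",
        standard_traits=pd.DataFrame(traits, columns=trait_names),
        volatiles=pd.DataFrame(volatiles, columns=vol_names),
        absolute_fitness=pd.Series(absolute, name="absolute_fitness"),
        relative_fitness=relative,
    )
    dataset.identifier = ids  # carried through to write_dataset
    # Renormalizing fitness to mean 1 divides every gradient by the realized
    # sample mean of the linear predictor; the realized_* entries are the
    # exact generating gradients of the dataset as analyzed.
    if spec.fitness_model == "gaussian":
        scale = 1.0 / linpred.mean()
    else:
        scale = spec.mean_fruits / absolute.mean() if absolute.mean() > 0 else np.nan
    truth = {
        "true_weights": w.tolist(),
        "true_axis_gradient": spec.true_axis_gradient,
        "realized_axis_gradient": spec.true_axis_gradient * scale,
        "realized_standard_gradients": (g_std * scale).tolist(),
        "true_standard_gradients": g_std.tolist(),
        "residual_sd": spec.residual_sd,
        "fitness_model": spec.fitness_model,
        "seed": spec.seed,
        "n": n,
        "n_standard": p,
        "n_volatiles": q,
    }
    return dataset, truth


def simulate_study_collection(
    base_spec: SimulationSpec,
    n_datasets: int,
    gradient_dispersion: float,
    seed: int,
) -> list[tuple[SelectionDataset, dict]]:
    """Generate several datasets sharing true axis weights, with the true
    axis gradient of each drawn Normal(base gradient, dispersion^2).

    Supports recovery checks for the among-dataset variance estimator:
    the true gradient dispersion is known by construction.
    """
    if n_datasets < 2:
        raise ConfigError("n_datasets must be at least 2")
    if gradient_dispersion < 0:
        raise ConfigError("gradient_dispersion must be nonnegative")
    base_spec.validate()
    rng = np.random.default_rng(seed)
    if isinstance(base_spec.true_weights, str):
        w = rng.standard_normal(base_spec.n_volatiles)
        w /= np.linalg.norm(w)
    else:
        w = np.asarray(base_spec.true_weights, dtype=float)
    out = []
    for d in range(n_datasets):
        g = float(rng.normal(base_spec.true_axis_gradient, gradient_dispersion))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec_d = replace(
            base_spec,
            true_weights=w,
            true_axis_gradient=g,
            seed=child_seed,
            dataset_id=f"{base_spec.dataset_id or 'sim'}_{d:02d}",
        )
        out.append(simulate_dataset(spec_d))
    return out


def write_dataset(dataset: SelectionDataset, path, truth: dict | None = None) -> None:
    """Write a dataset in the delimited-text schema :func:`rrsel.datasets.load_dataset`
    reads with :func:`rrsel.datasets.default_schema`; the truth record, if
    given, is written alongside as JSON (same stem, ``.truth.json``)."""
    import pathlib

    path = pathlib.Path(path)
    ids = getattr(dataset, "identifier", None) or [
        f"ind_{i + 1:03d}" for i in range(dataset.n)
    ]
    df = pd.DataFrame({"id": ids, "fitness": dataset.absolute_fitness.to_numpy()})
    for c in dataset.standard_traits.columns:
        df[c] = dataset.standard_traits[c].to_numpy()
    for c in dataset.volatiles.columns:
        df[c] = dataset.volatiles[c].to_numpy()
    df.to_csv(path, index=False)
    if truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
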
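"""Model evaluation: explanatory power, cross-validated prediction, and
agreement between the reduced-rank and multiple-regression analyses.

Explanatory and predictive r-squared are both defined as the squared
Pearson correlation between (posterior-mean) predictions and observed
relative fitness, so the in-sample and cross-validated quantities are
directly comparable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SelectionDataset
from .errors import ConfigError, ShapeError
from .model import PosteriorDraws, RRRConfig, _fit, predict

_log = logging.getLogger(__name__)


def _squared_correlation(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        _log.warning("zero variance in predictions or observations; r2 set to 0")
        return 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def explanatory_r2(draws: PosteriorDraws, dataset: SelectionDataset) -> float:
    """In-sample squared correlation between posterior-mean predictions of
    relative fitness and the observed values; in [0, 1]."""
    pred = predict(draws, dataset.standard_traits, dataset.volatiles)
    return _squared_correlation(pred, dataset.relative_fitness.to_numpy(dtype=float))


def fold_assignment(dataset: SelectionDataset, n_folds: int, cv_seed: int) -> np.ndarray:
    """Deterministic fold label (0..n_folds-1) for each row.

    Rows are first put in a canonical order (lexicographic over fitness and
    all trait columns) so the assignment does not depend on input row
    order; a seeded random permutation then splits them into near-equal
    folds.
    """
    n = dataset.n
    if n_folds < 2 or n_folds > n:
        raise ConfigError(f"n_folds must be in [2, {n}], got {n_folds}")
    if n < 2 * n_folds:
        raise ConfigError(f"need n >= {2 * n_folds} rows for {n_folds} folds")
    mat = np.column_stack(
        [
            dataset.absolute_fitness.to_numpy(dtype=float),
            dataset.standard_traits.to_numpy(dtype=float)
            if dataset.n_standard
            else np.empty((n, 0)),
            dataset.volatiles.to_numpy(dtype=float),
        ]
    )
    canonical = np.lexsort(tuple(mat[:, j] for j in range(mat.shape[1] - 1, -1, -1)))
    rng = np.random.default_rng(cv_seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    chunks = np.array_split(np.arange(n), n_folds)
    for f, chunk in enumerate(chunks):
        labels[canonical[perm[chunk]]] = f
    return labels


def cv_predictive_r2(
    dataset: SelectionDataset,
    config: RRRConfig,
    n_folds: int = 5,
    cv_seed: int = 0,
    method: str = "rrr",
) -> float:
    """K-fold cross-validated predictive r-squared.

    For each fold the full fit — including axis-weight estimation and the
    covariate standardization constants — is redone on the remaining
    folds, and predictions for the held-out rows are pooled; the result is
    the squared Pearson correlation between pooled predictions and
    observed relative fitness. The response (relative fitness computed on
    the full dataset) is held fixed across folds.

    ``method`` selects the reduced-rank model (``"rrr"``) or the
    multiple-regression baseline (``"mr"``).
    """
    if method not in ("rrr", "mr"):
        raise ConfigError(f"method must be 'rrr' or 'mr', got {method!r}")
    labels = fold_assignment(dataset, n_folds, cv_seed)
    y = dataset.relative_fitness.to_numpy(dtype=float)
    X = dataset.standard_traits
    V = dataset.volatiles
    preds = np.full(dataset.n, np.nan)
    for f in range(n_folds):
        test = labels == f
        train = ~test
        if method == "rrr":
            draws = _fit(
                X.loc[train],
                V.loc[train],
                y[train],
                config,
                rank=config.rank,
                kind="rrr",
            )
            preds[test] = predict(draws, X.loc[test], V.loc[test])
        else:
            Xall = pd.concat([X, V], axis=1)
            draws = _fit(
                Xall.loc[train],
                V.iloc[:, :0].loc[train],
                y[train],
                config,
                rank=0,
                kind="mr",
            )
            preds[test] = predict(draws, X.loc[test], V.loc[test])
    return _squared_correlation(preds, y)


def method_agreement(rrr_compounds: pd.DataFrame, mr_table: pd.DataFrame) -> float:
    """Pearson correlation between per-volatile posterior-mean gradients
    from the reduced-rank fit (back-projected) and the multiple-regression
    fit, on the mean-scaled scale.

    ``mr_table`` may be a full multiple-regression gradient table; it is
    aligned to the volatiles of ``rrr_compounds`` by name.
    """
    names = list(rrr_compounds.index)
    missing = [n for n in names if n not in mr_table.index]
    if missing:
        raise ShapeError(f"multiple-regression table lacks volatiles: {missing}")
    if len(names) < 3:
        raise ShapeError("need at least 3 shared volatiles for a correlation")
    a = rrr_compounds["beta_mu"].to_numpy(dtype=float)
    b = mr_table.loc[names, "beta_mu"].to_numpy(dtype=float)
    return float(stats.pearsonr(a, b).statistic)
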
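"""Selection-gradient summaries of posterior draws.

Gradients come in three scalings, following the standard practice for
directional selection analysis on relative fitness:

- raw gradient ``beta``: slope on the original measurement scale;
- mean-scaled ``beta_mu = beta * mean(trait)``: change in relative fitness
  per proportional change in the trait; meaningful only for ratio-scale
  traits, so it is not reported for the learned scent axis;
- variance-scaled ``beta_sigma = beta * SD(trait)``: change in relative
  fitness per SD of the trait, the scale on which selection strength is
  compared across traits and studies.

Posterior support is the probability that the gradient's sign matches its
dominant posterior sign: 0.5 means no evidence for either sign, 1.0 a
certain sign. Credible intervals are equal-tailed 95% quantile intervals.

Back-projection maps the gradient on a learned axis to implied per-volatile
gradients through the axis weights (``beta*_l = sum_k w_kl a_k`` on the
standardized scale), then rescales to the original emission scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import SelectionDataset
from .errors import NotApplicableError, RRSelError, ShapeError
from .model import PosteriorDraws

_log = logging.getLogger(__name__)

CI_LEVEL = 0.95
AXIS_NAME = "scent_axis"


def posterior_support(draws_of_one_parameter) -> float:
    """Sign-consistency probability of a scalar parameter's posterior.

    Returns ``max(P[x > 0], P[x < 0])`` with draws exactly at zero split
    equally between the two signs; always in ``[0.5, 1]``.
    """
    x = np.asarray(draws_of_one_parameter, dtype=float)
    if x.size == 0:
        raise RRSelError("posterior_support requires at least one draw")
    p_zero = np.mean(x == 0)
    p_pos = np.mean(x > 0) + 0.5 * p_zero
    p_neg = np.mean(x < 0) + 0.5 * p_zero
    return float(max(p_pos, p_neg))


def _post_sd(draws_matrix: np.ndarray) -> np.ndarray:
    """Posterior SD (n-1 denominator); zero for a single draw."""
    if draws_matrix.shape[0] < 2:
        return np.zeros(draws_matrix.shape[1:])
    return draws_matrix.std(axis=0, ddof=1)


def _summarize(draws_matrix: np.ndarray, prefix: str = "") -> dict[str, np.ndarray]:
    """Posterior mean/SD/CI/support for each column of an (S, m) matrix."""
    lo = (1 - CI_LEVEL) / 2
    return {
        f"{prefix}beta": draws_matrix.mean(axis=0),
        f"{prefix}se": _post_sd(draws_matrix),
        f"{prefix}ci_lo": np.quantile(draws_matrix, lo, axis=0),
        f"{prefix}ci_hi": np.quantile(draws_matrix, 1 - lo, axis=0),
        f"{prefix}support": np.array(
            [posterior_support(draws_matrix[:, j]) for j in range(draws_matrix.shape[1])]
        ),
    }


def scale_gradients(draws: PosteriorDraws, dataset: SelectionDataset) -> pd.DataFrame:
    """Per-trait gradient table (standard traits plus any learned axis).

    Returns a DataFrame indexed by trait name with columns ``beta`` (raw,
    posterior mean), ``se`` (posterior SD), ``ci_lo``/``ci_hi`` (raw-scale
    95% CI), ``beta_mu``, ``beta_sigma``, ``beta_sigma_se``,
    ``beta_sigma_lo``/``beta_sigma_hi`` and ``support``. Scaled gradients
    are computed per draw and then summarized; trait SDs use the n-1
    denominator. For the axis, the variance scaling uses the realized SD of
    the axis scores in each draw and the mean scaling is undefined (NaN):
    the axis is not on a ratio scale.
    """
    combined = pd.concat([dataset.standard_traits, dataset.volatiles], axis=1)
    missing = [n for n in draws.standard_names if n not in combined.columns]
    if missing:
        raise ShapeError(f"dataset lacks fitted covariates: {missing}")

    rows = []
    if draws.standard_names:
        mu = combined[draws.standard_names].mean().to_numpy()
        sd = combined[draws.standard_names].std(ddof=1).to_numpy()
        b = draws.beta_standard  # (S, p) original scale
        raw = _summarize(b)
        bsig = _summarize(b * sd, prefix="s_")
        for j, name in enumerate(draws.standard_names):
            rows.append(
                {
                    "trait": name,
                    "beta": raw["beta"][j],
                    "se": raw["se"][j],
                    "ci_lo": raw["ci_lo"][j],
                    "ci_hi": raw["ci_hi"][j],
                    "beta_mu": (b[:, j] * mu[j]).mean(),
                    "beta_sigma": bsig["s_beta"][j],
                    "beta_sigma_se": bsig["s_se"][j],
                    "beta_sigma_lo": bsig["s_ci_lo"][j],
                    "beta_sigma_hi": bsig["s_ci_hi"][j],
                    "support": raw["support"][j],
                }
            )

    # The axis row is summarized in the sampler's natural parameterization:
    # sign alignment is a post-hoc relabeling useful for weight summaries,
    # but the chain's own mixing across the (w, a) <-> (-w, -a) modes is
    # what distinguishes "no consistent direction of selection" (support
    # near 0.5, CI straddling 0) from a well-supported axis gradient.
    for k in range(draws.rank):
        b = draws.beta_axis_natural[:, k]
        score_sd = draws.axis_scores[:, k, :].std(axis=1, ddof=1)
        bsig = b * score_sd
        raw = _summarize(b[:, None])
        sig = _summarize(bsig[:, None], prefix="s_")
        name = AXIS_NAME if draws.rank == 1 else f"{AXIS_NAME}_{k + 1}"
        rows.append(
            {
                "trait": name,
                "beta": raw["beta"][0],
                "se": raw["se"][0],
                "ci_lo": raw["ci_lo"][0],
                "ci_hi": raw["ci_hi"][0],
                "beta_mu": np.nan,
                "beta_sigma": sig["s_beta"][0],
                "beta_sigma_se": sig["s_se"][0],
                "beta_sigma_lo": sig["s_ci_lo"][0],
                "beta_sigma_hi": sig["s_ci_hi"][0],
                "support": raw["support"][0],
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def back_project(draws: PosteriorDraws, dataset: SelectionDataset | None = None) -> pd.DataFrame:
    """Implied per-volatile gradients from the axis fit.

    Per draw, the standardized-scale volatile coefficient vector is
    ``sum_k a_k w_k``; dividing by each volatile's training SD lands on the
    original emission scale, and multiplying by the training mean gives the
    mean-scaled gradient. Returns a DataFrame indexed by volatile with
    columns ``beta`` (original scale), ``se``, ``beta_mu``, ``beta_mu_se``
    and ``support``.

    Raises
    ------
    NotApplicableError
        For multiple-regression draws, which have no axis.
    """
    if draws.rank == 0 or draws.weights.size == 0:
        raise NotApplicableError("no learned axis: fit has rank 0")
    if dataset is not None and list(dataset.volatiles.columns) != draws.volatile_names:
        raise ShapeError("dataset volatile columns do not match the fitted draws")
    bz = np.einsum("sr,srq->sq", draws.beta_axis, draws.weights)  # (S, q)
    braw = bz / draws.v_sd
    bmu = braw * draws.v_mean
    return pd.DataFrame(
        {
            "beta": braw.mean(axis=0),
            "se": _post_sd(braw),
            "beta_mu": bmu.mean(axis=0),
            "beta_mu_se": _post_sd(bmu),
            "support": [posterior_support(braw[:, l]) for l in range(braw.shape[1])],
        },
        index=pd.Index(draws.volatile_names, name="volatile"),
    )


def mr_compound_gradients(mr_table: pd.DataFrame, volatile_names) -> pd.DataFrame:
    """Subset a multiple-regression gradient table to its volatile rows,
    renaming columns to match :func:`back_project` output."""
    missing = [n for n in volatile_names if n not in mr_table.index]
    if missing:
        raise ShapeError(f"gradient table lacks volatiles: {missing}")
    sub = mr_table.loc[list(volatile_names)]
    out = sub[["beta", "se", "beta_mu", "support"]].copy()
    out.index.name = "volatile"
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Export a gradient table as tab-delimited text."""
    table.to_csv(path, sep="\t")
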
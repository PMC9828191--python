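"""Among-dataset variation in selection gradients.

When the same trait (or volatile) has a selection-gradient estimate in
several population-year datasets, the raw variance of those estimates mixes
true spatio-temporal variation in selection with sampling noise. The
moment estimator used here subtracts the mean sampling variance:

    sigma_beta_c = Var(estimates) - mean(sampling variances),

where the sampling variance of each Bayesian estimate is the variance of
its posterior distribution. ``sigma_beta_c`` may be negative (and is
reported as such); the corresponding corrected SD truncates at zero. The
meta-analyzed quantity is the mean-scaled gradient, so corrected SDs are
in units of the strength of selection on fitness itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RRSelError

_log = logging.getLogger(__name__)


def sigma_beta_c(estimates, sampling_variances) -> tuple[float, float]:
    """Sampling-error-corrected among-dataset variance of gradients.

    Parameters
    ----------
    estimates
        Posterior-mean gradient per dataset (length D >= 2).
    sampling_variances
        Posterior variance (squared SE) per dataset, same length.

    Returns
    -------
    (sigma_beta_c, corrected_sd)
        The corrected variance (possibly negative, reported as-is) and
        ``sqrt(max(0, sigma_beta_c))``.
    """
    est = np.asarray(estimates, dtype=float)
    sv = np.asarray(sampling_variances, dtype=float)
    if est.shape != sv.shape:
        raise RRSelError("estimates and sampling variances differ in length")
    if est.size < 2:
        raise InsufficientDataError("need at least 2 datasets")
    if np.any(sv < 0):
        raise RRSelError("sampling variances must be nonnegative")
    var_among = float(np.var(est, ddof=1))
    mean_sv = float(sv.mean())
    corrected = var_among - mean_sv
    return corrected, float(np.sqrt(max(0.0, corrected)))


def compound_variance_table(fits) -> pd.DataFrame:
    """Apply :func:`sigma_beta_c` per compound across several fits.

    Parameters
    ----------
    fits
        Iterable of ``(compound_table, dataset_id)`` pairs, where each
        compound table is a :func:`rrsel.gradients.back_project` result
        (columns ``beta_mu`` and ``beta_mu_se`` indexed by volatile name).
        Compounds are matched by name; compounds absent from some datasets
        are skipped with a log entry.

    Returns
    -------
    pandas.DataFrame indexed by compound with columns ``n_datasets``,
    ``mean_gradient``, ``sigma_beta2`` (raw among-dataset variance),
    ``mean_se2``, ``sigma_beta_c`` and ``corrected_sd``.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InsufficientDataError("need at least 2 fits")
    name_sets = [set(t.index) for t, _ in fits]
    shared = sorted(set.intersection(*name_sets))
    skipped = sorted(set.union(*name_sets) - set(shared))
    if skipped:
        _log.info("compounds absent from some datasets skipped: %s", skipped)
    if not shared:
        raise RRSelError("no compounds shared by all fits")

    rows = []
    for comp in shared:
        est = np.array([t.loc[comp, "beta_mu"] for t, _ in fits], dtype=float)
        sv = np.array([t.loc[comp, "beta_mu_se"] ** 2 for t, _ in fits], dtype=float)
        corrected, csd = sigma_beta_c(est, sv)
        rows.append(
            {
                "compound": comp,
                "n_datasets": len(fits),
                "mean_gradient": est.mean(),
                "sigma_beta2": float(np.var(est, ddof=1)),
                "mean_se2": float(sv.mean()),
                "sigma_beta_c": corrected,
                "corrected_sd": csd,
            }
        )
    return pd.DataFrame(rows).set_index("compound")


def plot_variance_panels(table: pd.DataFrame, gradients_by_dataset=None, path=None):
    """Two-panel summary: per-compound gradients (upper, with the
    across-dataset mean marked '+') and corrected SDs (lower bars).

    ``gradients_by_dataset`` is an optional mapping of dataset id to a
    compound table; when given, individual estimates are shown as points.
    Returns the matplotlib figure; saves to ``path`` when provided.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    compounds = list(table.index)
    xs = np.arange(len(compounds))
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(max(6, 0.45 * len(compounds)), 6), sharex=True)
    if gradients_by_dataset:
        for _, t in gradients_by_dataset.items():
            vals = [t.loc[c, "beta_mu"] if c in t.index else np.nan for c in compounds]
            ax1.plot(xs, vals, "o", color="grey", alpha=0.5, ms=3)
    ax1.plot(xs, table["mean_gradient"], "+", color="black", ms=10)
    ax1.axhline(0.0, lw=0.5, color="black")
    ax1.set_ylabel("mean-scaled gradient")
    ax2.bar(xs, table["corrected_sd"], color="steelblue")
    ax2.set_ylabel("corrected SD")
    ax2.set_xticks(xs)
    ax2.set_xticklabels(compounds, rotation=90, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
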
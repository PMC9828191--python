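"""Bayesian reduced-rank regression of relative fitness on traits.

Model
-----
For individual ``i`` with standardized standard traits ``x_i`` (p columns)
and standardized volatiles ``z_i`` (q columns), relative fitness is

    w_i = alpha + x_i' b + sum_k (z_i' w_k) a_k + eps_i,
    eps_i ~ Normal(0, sigma^2),

where each axis weight vector ``w_k`` (length q) and its slope ``a_k`` are
estimated jointly. With rank r = q the model spans ordinary multiple
regression on all volatiles; with r = 1 it reduces the volatile blend to a
single learned "scent selection axis".

Priors are independent Normal(0, prior_sd_beta^2) on the intercept and all
slopes (standardized-covariate scale), Normal(0, prior_sd_weights^2) on raw
axis weights, and inverse-gamma on sigma^2. All full conditionals are then
conjugate and sampling proceeds by a three-block Gibbs scan:

1. (alpha, b, a) | W, sigma^2  — joint multivariate normal;
2. sigma^2 | rest              — inverse gamma;
3. each w_k | rest             — multivariate normal (the model is linear
   in w_k when the slopes are held fixed).

Because the bilinear term is identified only up to sign and scale of
``(w_k, a_k)``, every stored draw is rescaled so ``||w_k|| = 1`` with the
magnitude absorbed into ``a_k``, and draws are sign-aligned to the
element-wise median weight vector. Predictions are invariant to this
post-processing.

All Gram matrices are precomputed, so the per-iteration cost is independent
of the number of individuals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

from .datasets import SelectionDataset
from .errors import ConfigError, DataError, NumericalError, ShapeError

_log = logging.getLogger(__name__)

RHAT_WARN = 1.1


@dataclass
class RRRConfig:
    """Model rank, priors and MCMC settings.

    Parameters
    ----------
    rank
        Number of learned composite axes (default 1, the single
        scent-selection-axis model). Must not exceed the number of
        volatiles. Ranks above 1 are supported for fitting and prediction
        but individual axes then lack rotational identifiability.
    prior_sd_beta
        Prior SD of the intercept and all slopes, on the
        standardized-covariate scale.
    prior_sd_weights
        Prior SD of raw (un-normalized) axis weights.
    residual_prior_shape, residual_prior_scale
        Inverse-gamma prior on the residual variance.
    n_chains, n_warmup, n_samples, thin
        Chain layout. ``n_samples`` draws per chain are kept after warmup.
    seed
        Base seed; chains use independently spawned streams derived from it.
    """

    rank: int = 1
    prior_sd_beta: float = 1.0
    prior_sd_weights: float = 1.0
    residual_prior_shape: float = 0.01
    residual_prior_scale: float = 0.01
    n_chains: int = 2
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.rank < 1:
            raise ConfigError("rank must be a positive integer")
        for name in (
            "prior_sd_beta",
            "prior_sd_weights",
            "residual_prior_shape",
            "residual_prior_scale",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_chains", "n_warmup", "n_samples", "thin"):
            if getattr(self, name) < 1 and not (name == "n_warmup" and self.n_warmup == 0):
                raise ConfigError(f"{name} must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")


@dataclass
class PosteriorDraws:
    """Posterior draws from :func:`fit_rrr` or :func:`fit_multiple_regression`.

    Slopes are stored on the standardized-covariate scale (``beta_z``,
    ``alpha_z``) together with the training standardization constants;
    :attr:`beta_standard` and :attr:`intercept` expose the original-scale
    parameterization. ``weights`` are on the standardized-volatile scale
    with unit norm per draw and axis.
    """

    kind: str  # "rrr" or "mr"
    rank: int
    n_chains: int
    alpha_z: np.ndarray  # (S,)
    beta_z: np.ndarray  # (S, p)
    beta_axis: np.ndarray  # (S, r)
    weights: np.ndarray  # (S, r, q), unit rows
    sigma2: np.ndarray  # (S,)
    axis_scores: np.ndarray  # (S, r, n) composite-covariate values
    standard_names: list[str]
    volatile_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    v_mean: np.ndarray
    v_sd: np.ndarray
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: +/-1 per draw and axis: the relabeling applied during sign alignment.
    #: ``beta_axis * axis_sign`` (and ``weights * axis_sign``) recover the
    #: draws in the sampler's natural parameterization, whose sign mixing
    #: across the two symmetric modes carries the evidence (or lack of it)
    #: for a consistent direction of selection on the axis.
    axis_sign: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.alpha_z.shape[0]

    @property
    def beta_axis_natural(self) -> np.ndarray:
        """Axis-slope draws with the sampler's natural signs, shape (S, r)."""
        if self.axis_sign is None:
            return self.beta_axis
        return self.beta_axis * self.axis_sign

    @property
    def beta_standard(self) -> np.ndarray:
        """Slopes on the original covariate scale, shape (S, p)."""
        return self.beta_z / self.x_sd

    @property
    def intercept(self) -> np.ndarray:
        """Original-scale intercept draws, shape (S,)."""
        return self.alpha_z - (self.beta_z * (self.x_mean / self.x_sd)).sum(axis=1)

    def per_chain(self, arr: np.ndarray) -> np.ndarray:
        """Reshape a flat (S, ...) array to (chain, draw, ...)."""
        s = arr.shape[0]
        return arr.reshape(self.n_chains, s // self.n_chains, *arr.shape[1:])

    # -- serialization -------------------------------------------------
    def save(self, outdir) -> None:
        """Write draws to ``draws.csv`` (one named column per scalar
        parameter) plus ``draws_meta.json`` with names and standardization
        constants, and ``axis_scores.npy``."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        s = self.n_draws
        per = s // self.n_chains
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(self.n_chains), per),
            "draw": np.tile(np.arange(per), self.n_chains),
            "alpha_z": self.alpha_z,
        }
        for j, name in enumerate(self.standard_names):
            cols[f"beta_z[{name}]"] = self.beta_z[:, j]
        for k in range(self.rank):
            cols[f"beta_axis[{k}]"] = self.beta_axis[:, k]
            if self.axis_sign is not None:
                cols[f"axis_sign[{k}]"] = self.axis_sign[:, k]
            for l, name in enumerate(self.volatile_names):
                cols[f"w[{k},{name}]"] = self.weights[:, k, l]
        cols["sigma2"] = self.sigma2
        pd.DataFrame(cols).to_csv(outdir / "draws.csv", index=False)
        meta = {
            "kind": self.kind,
            "rank": self.rank,
            "n_chains": self.n_chains,
            "standard_names": self.standard_names,
            "volatile_names": self.volatile_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "v_mean": self.v_mean.tolist(),
            "v_sd": self.v_sd.tolist(),
        }
        (outdir / "draws_meta.json").write_text(json.dumps(meta, indent=1))
        np.save(outdir / "axis_scores.npy", self.axis_scores)
        self.diagnostics.to_csv(outdir / "diagnostics.csv")

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        import pathlib

        outdir = pathlib.Path(outdir)
        meta = json.loads((outdir / "draws_meta.json").read_text())
        df = pd.read_csv(outdir / "draws.csv")
        rank = meta["rank"]
        std = meta["standard_names"]
        vols = meta["volatile_names"]
        s = len(df)
        weights = np.empty((s, rank, len(vols)))
        beta_axis = np.empty((s, rank))
        axis_sign = np.ones((s, rank))
        for k in range(rank):
            beta_axis[:, k] = df[f"beta_axis[{k}]"]
            if f"axis_sign[{k}]" in df.columns:
                axis_sign[:, k] = df[f"axis_sign[{k}]"]
            for l, name in enumerate(vols):
                weights[:, k, l] = df[f"w[{k},{name}]"]
        scores_path = outdir / "axis_scores.npy"
        axis_scores = (
            np.load(scores_path) if scores_path.exists() else np.empty((s, rank, 0))
        )
        diag_path = outdir / "diagnostics.csv"
        diagnostics = (
            pd.read_csv(diag_path, index_col=0) if diag_path.exists() else pd.DataFrame()
        )
        return cls(
            kind=meta["kind"],
            rank=rank,
            n_chains=meta["n_chains"],
            alpha_z=df["alpha_z"].to_numpy(),
            beta_z=df[[f"beta_z[{n}]" for n in std]].to_numpy()
            if std
            else np.empty((s, 0)),
            beta_axis=beta_axis,
            weights=weights,
            sigma2=df["sigma2"].to_numpy(),
            axis_scores=axis_scores,
            axis_sign=axis_sign,
            standard_names=std,
            volatile_names=vols,
            x_mean=np.asarray(meta["x_mean"], dtype=float),
            x_sd=np.asarray(meta["x_sd"], dtype=float),
            v_mean=np.asarray(meta["v_mean"], dtype=float),
            v_sd=np.asarray(meta["v_sd"], dtype=float),
            diagnostics=diagnostics,
        )


# ----------------------------------------------------------------------
# Sampler internals
# ----------------------------------------------------------------------

def _standardize(df: pd.DataFrame):
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.ones(arr.shape[1])
    if np.any(sd <= 0):
        bad = [c for c, ok in zip(df.columns, sd > 0) if not ok]
        raise DataError(f"zero-variance covariate columns: {bad}")
    return (arr - mean) / sd, mean, sd


def _sample_mvn(prec: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1) via a Cholesky of the precision."""
    L = np.linalg.cholesky(prec)
    mean = cho_solve((L, True), lin)
    z = rng.standard_normal(lin.shape[0])
    return mean + solve_triangular(L, z, lower=True, trans="T")


def _gibbs_chain(y, Xz, Zz, rank, cfg: RRRConfig, seed_seq):
    rng = np.random.default_rng(seed_seq)
    n = y.shape[0]
    p = Xz.shape[1]
    q = Zz.shape[1] if rank else 0
    m0 = p + 1

    D0 = np.column_stack([np.ones(n), Xz])
    G00 = D0.T @ D0
    D0ty = D0.T @ y
    yty = float(y @ y)
    if rank:
        G0Z = D0.T @ Zz  # m0 x q
        ZtZ = Zz.T @ Zz
        Zty = Zz.T @ y
        eye_q = np.eye(q)

    tau_b2 = cfg.prior_sd_beta**2
    tau_w2 = cfg.prior_sd_weights**2
    a0 = cfg.residual_prior_shape
    b0 = cfg.residual_prior_scale

    theta = np.zeros(m0 + rank)
    theta[0] = y.mean()
    if rank:
        W = rng.standard_normal((rank, q))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
    else:
        W = np.zeros((0, 0))
    sigma2 = float(np.var(y)) or 1.0

    keep_theta = np.empty((cfg.n_samples, m0 + rank))
    keep_W = np.empty((cfg.n_samples, rank, q))
    keep_s2 = np.empty(cfg.n_samples)

    G = np.empty((m0 + rank, m0 + rank))
    G[:m0, :m0] = G00
    Dty = np.empty(m0 + rank)
    Dty[:m0] = D0ty

    n_iter = cfg.n_warmup + cfg.n_samples * cfg.thin
    kept = 0
    for it in range(n_iter):
        # -- assemble Gram blocks for current weights -------------------
        if rank:
            G0S = G0Z @ W.T
            G[:m0, m0:] = G0S
            G[m0:, :m0] = G0S.T
            G[m0:, m0:] = W @ ZtZ @ W.T
            Dty[m0:] = W @ Zty

        # -- slopes and intercept --------------------------------------
        prec = G / sigma2
        prec[np.diag_indices_from(prec)] += 1.0 / tau_b2
        theta = _sample_mvn(prec, Dty / sigma2, rng)

        # -- residual variance -----------------------------------------
        ssr = yty - 2.0 * theta @ Dty + theta @ G @ theta
        ssr = max(ssr, 1e-300)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ssr))

        # -- axis weights ----------------------------------------------
        if rank:
            theta0 = theta[:m0]
            a_all = theta[m0:]
            base = Zty - G0Z.T @ theta0
            for k in range(rank):
                a_k = a_all[k]
                other = W.T @ a_all - W[k] * a_k
                lin = (a_k / sigma2) * (base - ZtZ @ other)
                prec_w = (a_k * a_k / sigma2) * ZtZ + eye_q / tau_w2
                W[k] = _sample_mvn(prec_w, lin, rng)

        if not (np.isfinite(sigma2) and np.all(np.isfinite(theta))):
            raise NumericalError(f"sampler reached a non-finite state at iteration {it}")

        if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
            keep_theta[kept] = theta
            keep_W[kept] = W
            keep_s2[kept] = sigma2
            kept += 1

    return keep_theta[:kept], keep_W[:kept], keep_s2[:kept]


def _harmonize_chains(weights: np.ndarray, beta_axis: np.ndarray, n_chains: int) -> None:
    """Flip whole chains so all chains occupy the same (w, a) mode.

    The bilinear term is invariant under (w, a) -> (-w, -a), so with a
    well-identified axis each chain settles into one of two equivalent
    modes chosen by its random initialization. Which mode a chain lands in
    carries no information; flipping chains to a common hemisphere (their
    median weight vectors aligned with the first chain's) removes that
    artifact while preserving within-chain sign mixing, which does carry
    the evidence for a consistent direction of selection.
    """
    s = beta_axis.shape[0]
    per = s // n_chains
    Wc = weights.reshape(n_chains, per, *weights.shape[1:])
    Bc = beta_axis.reshape(n_chains, per, -1)
    ref = np.median(Wc[0], axis=0)  # (r, q)
    for c in range(1, n_chains):
        med = np.median(Wc[c], axis=0)
        for k in range(ref.shape[0]):
            if float(np.dot(med[k], ref[k])) < 0:
                Wc[c, :, k, :] *= -1.0
                Bc[c, :, k] *= -1.0


def _sign_align(weights: np.ndarray, beta_axis: np.ndarray, max_passes: int = 50) -> np.ndarray:
    """Flip (w_k, a_k) draws so every draw's weight vector has nonnegative
    dot product with the element-wise median weight vector.

    Returns the (S, r) array of +/-1 signs applied, so the natural
    parameterization remains recoverable.
    """
    signs = np.ones(beta_axis.shape)
    for _ in range(max_passes):
        med = np.median(weights, axis=0)  # (r, q)
        dots = np.einsum("srq,rq->sr", weights, med)
        flip = dots < 0
        if not flip.any():
            return signs
        weights[flip] *= -1.0
        beta_axis[flip] *= -1.0
        signs[flip] *= -1.0
    _log.warning("sign alignment did not stabilize; summaries of w may mix signs")
    return signs


def _compute_diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    import arviz as az

    post = {
        "intercept": draws.per_chain(draws.alpha_z),
        "sigma2": draws.per_chain(draws.sigma2),
    }
    if draws.beta_z.shape[1]:
        post["beta_standard"] = draws.per_chain(draws.beta_z)
    if draws.rank and draws.weights.size:
        post["beta_axis"] = draws.per_chain(draws.beta_axis)
        post["weights"] = draws.per_chain(draws.weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=post)
        if draws.n_chains >= 2:
            rhat = az.rhat(idata)
        else:
            rhat = None
        ess = az.ess(idata, method="bulk")

    rows = []

    def emit(var, idx_names):
        r = np.asarray(rhat[var]) if rhat is not None else None
        e = np.asarray(ess[var])
        flat_r = np.atleast_1d(r).ravel() if r is not None else None
        flat_e = np.atleast_1d(e).ravel()
        for i, name in enumerate(idx_names):
            rows.append(
                {
                    "parameter": name,
                    "rhat": float(flat_r[i]) if flat_r is not None else np.nan,
                    "ess_bulk": float(flat_e[i]),
                }
            )

    emit("intercept", ["intercept"])
    if draws.beta_z.shape[1]:
        emit("beta_standard", [f"beta[{n}]" for n in draws.standard_names])
    if draws.rank and draws.weights.size:
        emit("beta_axis", [f"beta_axis[{k}]" for k in range(draws.rank)])
        emit(
            "weights",
            [
                f"w[{k},{n}]"
                for k in range(draws.rank)
                for n in draws.volatile_names
            ],
        )
    emit("sigma2", ["sigma2"])
    return pd.DataFrame(rows).set_index("parameter")


def _fit(
    X_df: pd.DataFrame,
    V_df: pd.DataFrame,
    y: np.ndarray,
    config: RRRConfig,
    rank: int,
    kind: str,
) -> PosteriorDraws:
    Xz, x_mean, x_sd = (
        _standardize(X_df)
        if X_df.shape[1]
        else (np.empty((len(y), 0)), np.empty(0), np.empty(0))
    )
    if rank:
        Zz, v_mean, v_sd = _standardize(V_df)
        q = Zz.shape[1]
    else:
        Zz = np.empty((len(y), 0))
        v_mean = np.empty(0)
        v_sd = np.empty(0)
        q = 0

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    thetas, Ws, s2s = [], [], []
    for seq in seqs:
        t, w, s2 = _gibbs_chain(y, Xz, Zz, rank, config, seq)
        thetas.append(t)
        Ws.append(w)
        s2s.append(s2)
    theta = np.concatenate(thetas)  # (S, m0 + r)
    W = np.concatenate(Ws)  # (S, r, q)
    s2 = np.concatenate(s2s)

    p = Xz.shape[1]
    alpha_z = theta[:, 0].copy()
    beta_z = theta[:, 1 : 1 + p].copy()
    beta_axis = theta[:, 1 + p :].copy()

    if rank:
        norms = np.linalg.norm(W, axis=2)  # (S, r)
        W = W / norms[:, :, None]
        beta_axis = beta_axis * norms
        _harmonize_chains(W, beta_axis, config.n_chains)
        axis_sign = _sign_align(W, beta_axis)
        axis_scores = np.einsum("srq,nq->srn", W, Zz)
    else:
        axis_sign = np.ones((theta.shape[0], 0))
        axis_scores = np.empty((theta.shape[0], 0, len(y)))

    draws = PosteriorDraws(
        kind=kind,
        rank=rank,
        n_chains=config.n_chains,
        alpha_z=alpha_z,
        beta_z=beta_z,
        beta_axis=beta_axis,
        weights=W,
        sigma2=s2,
        axis_scores=axis_scores,
        axis_sign=axis_sign,
        standard_names=list(X_df.columns),
        volatile_names=list(V_df.columns) if rank else [],
        x_mean=x_mean,
        x_sd=x_sd,
        v_mean=v_mean,
        v_sd=v_sd,
    )
    draws.diagnostics = _compute_diagnostics(draws)
    if config.n_chains >= 2:
        max_rhat = draws.diagnostics["rhat"].max()
        if np.isfinite(max_rhat) and max_rhat > RHAT_WARN:
            _log.warning(
                "convergence warning: max R-hat %.3f exceeds %.2f", max_rhat, RHAT_WARN
            )
    return draws


# ----------------------------------------------------------------------
# Public fitting interface
# ----------------------------------------------------------------------

def fit_rrr(dataset: SelectionDataset, config: RRRConfig) -> PosteriorDraws:
    """Fit the reduced-rank selection model to one dataset.

    Standard traits enter as ordinary covariates; the volatile block enters
    only through ``config.rank`` learned unit-norm weighted combinations.

    Raises
    ------
    ConfigError
        If ``config.rank`` exceeds the number of volatile columns.
    NumericalError
        If the sampler reaches a non-finite state.
    """
    config.validate()
    if config.rank > dataset.n_volatiles:
        raise ConfigError(
            f"rank {config.rank} exceeds number of volatiles {dataset.n_volatiles}"
        )
    if config.rank > 1:
        _log.warning(
            "rank > 1: individual axes are not rotationally identified; "
            "only back-projected gradients and predictions are interpretable"
        )
    return _fit(
        dataset.standard_traits,
        dataset.volatiles,
        dataset.relative_fitness.to_numpy(dtype=float),
        config,
        rank=config.rank,
        kind="rrr",
    )


def fit_multiple_regression(dataset: SelectionDataset, config: RRRConfig) -> PosteriorDraws:
    """Fit the classical selection analysis: every volatile is an ordinary
    covariate alongside the standard traits (no weight block).

    The normal prior on slopes acts as a ridge penalty, so the fit remains
    proper even when covariates outnumber individuals; a warning is logged
    in that regime.
    """
    config.validate()
    n_cov = dataset.n_standard + dataset.n_volatiles
    if dataset.n <= n_cov + 1:
        _log.warning(
            "n = %d with %d covariates: multiple regression is prior-dominated",
            dataset.n,
            n_cov,
        )
    X = pd.concat([dataset.standard_traits, dataset.volatiles], axis=1)
    return _fit(
        X,
        dataset.volatiles.iloc[:, :0],
        dataset.relative_fitness.to_numpy(dtype=float),
        config,
        rank=0,
        kind="mr",
    )


def predict(draws: PosteriorDraws, standard_traits, volatiles) -> np.ndarray:
    """Posterior-mean prediction of relative fitness for new rows.

    New data are standardized with the training means/SDs stored at fit
    time. The bilinear axis term is averaged per draw (not at the posterior
    means), so predictions are exact posterior expectations of the linear
    predictor.
    """
    X = _coerce_block(standard_traits, draws.standard_names if draws.kind == "rrr" else None)
    V = _coerce_block(volatiles, draws.volatile_names if draws.kind == "rrr" else None)
    if draws.kind == "mr":
        both = np.column_stack([X, V]) if V.size or X.size else X
        if both.shape[1] != len(draws.standard_names):
            raise ShapeError(
                f"expected {len(draws.standard_names)} covariate columns, "
                f"got {both.shape[1]}"
            )
        Xz = (both - draws.x_mean) / draws.x_sd
        pred = draws.alpha_z[None, :] + Xz @ draws.beta_z.T  # (n, S)
        return pred.mean(axis=1)

    if X.shape[1] != len(draws.standard_names):
        raise ShapeError(
            f"expected {len(draws.standard_names)} standard-trait columns, "
            f"got {X.shape[1]}"
        )
    if V.shape[1] != len(draws.volatile_names):
        raise ShapeError(
            f"expected {len(draws.volatile_names)} volatile columns, got {V.shape[1]}"
        )
    Xz = (X - draws.x_mean) / draws.x_sd if X.shape[1] else X
    Zz = (V - draws.v_mean) / draws.v_sd
    pred = draws.alpha_z[None, :]
    if Xz.shape[1]:
        pred = pred + Xz @ draws.beta_z.T
    # effective volatile coefficients per draw: c_s = W_s' a_s
    ceff = np.einsum("sr,srq->sq", draws.beta_axis, draws.weights)
    pred = pred + Zz @ ceff.T
    return pred.mean(axis=1)


def _coerce_block(block, expected_names):
    if isinstance(block, pd.DataFrame):
        if expected_names is not None and list(block.columns) != list(expected_names):
            raise ShapeError(
                f"column names {list(block.columns)} do not match the fitted "
                f"dataset's {list(expected_names)}"
            )
        return block.to_numpy(dtype=float)
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr
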
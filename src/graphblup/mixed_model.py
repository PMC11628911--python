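"""Bayesian and REML kernel mixed models (GBLUP and graph-augmented GBLUP).

All three predictors share one Gaussian form

    y = mu * 1 + sum_m u_m + e,   u_m ~ N(0, sigma_m^2 K_m),  e ~ N(0, sigma_e^2 I)

with one kernel (genotype-only: K = G; network-only: K = GA) or two
(combined: G and GA). Two fitting routes are provided:

* :class:`BayesKernelBLUP` — a Gibbs sampler with scaled-inverse-chi-square
  priors on every variance and a flat prior on the intercept. Each random
  effect is reparameterised through the kernel eigendecomposition
  K = Gamma Lam Gamma', so the sampler draws independent eigen-coordinates.
  Lines with missing phenotype are imputed from their full conditional
  each iteration — exactly how NA-coded test lines are predicted.
* :class:`REMLKernelBLUP` — deterministic restricted maximum likelihood
  over the variance components, with BLUPs from the closed form
  g_m = sigma_m^2 K_m V^{-1} (y - mu 1). Serves as an independent oracle
  for the sampler.

Both estimators are transductive in the BGLR sense: ``fit(K, y)`` takes
the full n x n kernel(s) and a phenotype vector in which test lines are
NaN; ``predict()`` returns posterior-mean predictions for any subset of
the fitted lines.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinship import RelationshipKernel

__all__ = ["BayesKernelBLUP", "REMLKernelBLUP", "fit_bayes", "fit_reml_oracle", "predict"]

_EIG_FLOOR = 1e-10  # kernel eigenvalues below this are treated as null space
_PSD_TOL = -1e-8


def _coerce_kernels(X) -> tuple[list[np.ndarray], list[str] | None]:
    """Accept a kernel, a RelationshipKernel, or a sequence of either."""
    if isinstance(X, RelationshipKernel):
        X = [X]
    elif isinstance(X, np.ndarray) and X.ndim == 2:
        X = [X]
    mats: list[np.ndarray] = []
    ids: list[str] | None = None
    for item in X:
        if isinstance(item, RelationshipKernel):
            if ids is None:
                ids = list(item.line_ids)
            elif ids != list(item.line_ids):
                raise ValueError("kernels have mismatched line orderings")
            mats.append(item.K)
        else:
            mats.append(np.asarray(item, dtype=float))
    if not 1 <= len(mats) <= 2:
        raise ValueError("expected 1 or 2 kernels")
    n = mats[0].shape[0]
    for K in mats:
        if K.shape != (n, n):
            raise ValueError("kernels must be square and of equal size")
        if np.abs(K - K.T).max() > 1e-8:
            raise ValueError("kernel not symmetric")
    return mats, ids


def _eigen_parts(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, Gamma = np.linalg.eigh(K)
    scale = max(float(lam[-1]), 1.0)
    if float(lam[0]) < _PSD_TOL * scale:
        raise ValueError(f"kernel not PSD: min eigenvalue {lam[0]:.3e}")
    keep = lam > _EIG_FLOOR
    return Gamma[:, keep], lam[keep]


def _resolve_index(ids, fitted_ids: list[str] | None, n: int) -> np.ndarray:
    """Map line ids / integer indices / None to positions in the fit."""
    if ids is None:
        return np.arange(n)
    ids = np.asarray(ids)
    if ids.dtype.kind in "iu":
        if ids.min() < 0 or ids.max() >= n:
            raise KeyError("line index out of range")
        return ids.astype(int)
    if fitted_ids is None:
        raise KeyError("fit was given bare arrays; predict by integer index")
    lut = {l: i for i, l in enumerate(fitted_ids)}
    try:
        return np.array([lut[str(l)] for l in ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown line id {exc.args[0]!r}") from None


class BayesKernelBLUP(RegressorMixin, BaseEstimator):
    """Gibbs-sampled Gaussian kernel mixed model with 1 or 2 kernels.

    Parameters
    ----------
    n_iter, burn_in, thin
        Chain length, discarded warm-up, and retention stride.
    prior_df
        Degrees of freedom of the scaled-inverse-chi-square prior on every
        variance component.
    prior_r2
        Fraction of phenotypic variance the prior mode assigns to the
        kernel terms jointly (split equally among kernels); the remainder
        elicits the residual scale. Mirrors the usual Bayesian-GBLUP
        default elicitation.
    random_state
        Seed for the sampler; required implicitly for reproducible runs.

    Attributes
    ----------
    mu_ : float
        Posterior-mean intercept.
    var_components_ : dict
        Posterior means ``{"kernel_0": s2_0[, "kernel_1": s2_1], "residual": s2_e}``.
    blups_ : list of ndarray
        Posterior-mean random-effect vector per kernel (length n each).
    yhat_ : ndarray
        Posterior-mean predictions mu_ + sum blups_ for all n lines.
    chains_ : dict of ndarray
        Retained draws for the intercept and variances.
    """

    def __init__(
        self,
        n_iter: int = 10000,
        burn_in: int = 2000,
        thin: int = 5,
        prior_df: float = 5.0,
        prior_r2: float = 0.5,
        random_state: int | None = None,
        keep_effects: bool = False,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.prior_r2 = prior_r2
        self.random_state = random_state
        self.keep_effects = keep_effects

    def fit(self, X, y):
        kernels, line_ids = _coerce_kernels(X)
        y = np.asarray(y, dtype=float)
        n = kernels[0].shape[0]
        if y.shape != (n,):
            raise ValueError("y length must match kernel size")
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            raise ValueError("need at least 2 observed phenotypes")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("require n_iter > burn_in >= 0")
        rng = np.random.default_rng(self.random_state)

        parts = [_eigen_parts(K) for K in kernels]
        nk = len(kernels)
        df = float(self.prior_df)
        vy = float(np.var(y[obs], ddof=1))
        vy = vy if vy > 0 else 1.0
        # prior scales: mode of S*inv-chi2(df) is S/(df+2); elicit so the mode
        # splits R2 of var(y) among kernels (per mean kernel diagonal) and 1-R2
        # to the residual
        mean_diag = [float(np.trace(K) / n) for K in kernels]
        S_k = [
            vy * (self.prior_r2 / nk) * (df + 2.0) / max(md, _EIG_FLOOR) for md in mean_diag
        ]
        S_e = vy * (1.0 - self.prior_r2) * (df + 2.0)

        y_imp = y.copy()
        y_imp[~obs] = y[obs].mean()
        mu = float(y[obs].mean())
        u = [np.zeros(n) for _ in range(nk)]
        s2 = [vy * self.prior_r2 / nk for _ in range(nk)]
        s2e = vy * (1.0 - self.prior_r2)

        n_keep = (self.n_iter - self.burn_in) // self.thin
        keep_mu = np.empty(n_keep)
        keep_s2 = np.empty((n_keep, nk))
        keep_s2e = np.empty(n_keep)
        sum_u = [np.zeros(n) for _ in range(nk)]
        sum_yhat = np.zeros(n)
        keep_u = np.empty((n_keep, nk, n)) if self.keep_effects else None
        kept = 0

        miss = ~obs
        for it in range(self.n_iter):
            total_u = np.sum(u, axis=0)
            # intercept | rest
            mu = rng.normal((y_imp - total_u).mean(), np.sqrt(s2e / n))
            # each random effect in its eigenbasis
            for m, (Gamma, lam) in enumerate(parts):
                e = y_imp - mu - (total_u - u[m])
                et = Gamma.T @ e
                v = 1.0 / (1.0 / (s2[m] * lam) + 1.0 / s2e)
                delta = v / s2e * et + np.sqrt(v) * rng.standard_normal(lam.size)
                u[m] = Gamma @ delta
                total_u = np.sum(u, axis=0)
                ss = float(np.sum(delta**2 / lam))
                s2[m] = (ss + df * S_k[m]) / rng.chisquare(df + lam.size)
            # residual variance
            resid = y_imp - mu - total_u
            s2e = (float(resid @ resid) + df * S_e) / rng.chisquare(df + n)
            # impute NA-coded lines from their full conditional
            if miss.any():
                y_imp[miss] = mu + total_u[miss] + np.sqrt(s2e) * rng.standard_normal(miss.sum())
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kept < n_keep:
                keep_mu[kept] = mu
                keep_s2[kept] = s2
                keep_s2e[kept] = s2e
                for m in range(nk):
                    sum_u[m] += u[m]
                    if keep_u is not None:
                        keep_u[kept, m] = u[m]
                sum_yhat += mu + total_u
                kept += 1

        self.line_ids_ = line_ids
        self.n_lines_ = n
        self.observed_mask_ = obs
        self.mu_ = float(keep_mu.mean())
        self.blups_ = [su / kept for su in sum_u]
        self.yhat_ = sum_yhat / kept
        self.var_components_ = {f"kernel_{m}": float(keep_s2[:, m].mean()) for m in range(nk)}
        self.var_components_["residual"] = float(keep_s2e.mean())
        self.chains_ = {
            "mu": keep_mu,
            "residual": keep_s2e,
            **{f"kernel_{m}": keep_s2[:, m] for m in range(nk)},
        }
        if keep_u is not None:
            self.chains_["effects"] = keep_u
        self.n_features_in_ = n
        return self

    def predict(self, X=None):
        """Posterior-mean predictions.

        ``X`` may be None (all fitted lines), integer indices, or line ids
        (when the fit was given RelationshipKernel inputs).
        """
        check_is_fitted(self, "yhat_")
        idx = _resolve_index(X, self.line_ids_, self.n_lines_)
        return self.yhat_[idx]


def _neg_reml(log_s2: np.ndarray, kernels: list[np.ndarray], y: np.ndarray) -> float:
    s2 = np.exp(log_s2)
    n = y.size
    V = s2[-1] * np.eye(n)
    for var, K in zip(s2[:-1], kernels):
        V += var * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e30
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, ones)
    xvx = float(ones @ Vi_1)
    beta = float(ones @ Vi_y) / xvx
    r = y - beta
    Py = np.linalg.solve(V, r)
    return 0.5 * (logdet + np.log(xvx) + float(r @ Py))


class REMLKernelBLUP(RegressorMixin, BaseEstimator):
    """Restricted-maximum-likelihood kernel mixed model (deterministic).

    Maximises the restricted likelihood of the same Gaussian model as
    :class:`BayesKernelBLUP` over (sigma_1^2[, sigma_2^2], sigma_e^2) by
    Nelder-Mead on the log-variance scale, then forms BLUPs via
    g_m = sigma_m^2 K_m V^{-1}(y - mu 1) extended to unobserved lines
    through the full kernel rows.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        kernels, line_ids = _coerce_kernels(X)
        y = np.asarray(y, dtype=float)
        n = kernels[0].shape[0]
        if y.shape != (n,):
            raise ValueError("y length must match kernel size")
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            raise ValueError("need at least 2 observed phenotypes")
        for K in kernels:
            _eigen_parts(K)  # PSD validation
        nk = len(kernels)
        y_tr = y[obs]
        K_tr = [K[np.ix_(obs, obs)] for K in kernels]
        vy = float(np.var(y_tr, ddof=1))

        if vy < 1e-12:
            # degenerate: no phenotypic variance, everything collapses to mu
            s2_hat = np.full(nk + 1, 1e-12)
            mu = float(y_tr.mean())
            self.converged_ = True
        else:
            mean_diag = [max(float(np.trace(K) / K.shape[0]), _EIG_FLOOR) for K in K_tr]
            x0 = np.log(
                np.array([0.5 * vy / nk / md for md in mean_diag] + [0.5 * vy])
            )
            res = optimize.minimize(
                _neg_reml,
                x0,
                args=(K_tr, y_tr),
                method="Nelder-Mead",
                options={"maxiter": self.max_iter * (nk + 1), "xatol": self.tol, "fatol": self.tol},
            )
            if not res.success:
                raise RuntimeError(f"REML did not converge: {res.message}")
            self.converged_ = True
            s2_hat = np.exp(res.x)
            V = s2_hat[-1] * np.eye(int(obs.sum()))
            for var, K in zip(s2_hat[:-1], K_tr):
                V += var * K
            ones = np.ones(int(obs.sum()))
            Vi_1 = np.linalg.solve(V, ones)
            mu = float(ones @ np.linalg.solve(V, y_tr)) / float(ones @ Vi_1)

        # BLUPs for all lines through the cross-kernel rows
        if vy < 1e-12:
            blups = [np.zeros(n) for _ in range(nk)]
        else:
            alpha = np.linalg.solve(V, y_tr - mu)
            blups = [s2_hat[m] * kernels[m][:, obs] @ alpha for m in range(nk)]

        self.line_ids_ = line_ids
        self.n_lines_ = n
        self.observed_mask_ = obs
        self.mu_ = mu
        self.blups_ = blups
        self.yhat_ = mu + np.sum(blups, axis=0)
        self.var_components_ = {f"kernel_{m}": float(s2_hat[m]) for m in range(nk)}
        self.var_components_["residual"] = float(s2_hat[-1])
        # heritability on the scale of the training kernels' mean diagonal
        md_full = [float(np.trace(K) / n) for K in kernels]
        genetic = sum(s2_hat[m] * md_full[m] for m in range(nk))
        self.h2_ = float(genetic / (genetic + s2_hat[-1])) if genetic + s2_hat[-1] > 0 else 0.0
        self.n_features_in_ = n
        return self

    def predict(self, X=None):
        check_is_fitted(self, "yhat_")
        idx = _resolve_index(X, self.line_ids_, self.n_lines_)
        return self.yhat_[idx]


def fit_bayes(y_obs, kernels, n_iter=10000, burn_in=2000, thin=5, prior_df=5.0, prior_r2=0.5, seed=None):
    """Functional wrapper: Gibbs fit of the kernel mixed model.

    ``y_obs`` uses NaN for lines to predict; ``kernels`` is one kernel or
    a list of 1-2 (arrays or RelationshipKernel). Returns the fitted
    :class:`BayesKernelBLUP`.
    """
    return BayesKernelBLUP(
        n_iter=n_iter, burn_in=burn_in, thin=thin, prior_df=prior_df, prior_r2=prior_r2, random_state=seed
    ).fit(kernels, y_obs)


def fit_reml_oracle(y_obs, kernels):
    """Functional wrapper: deterministic REML fit of the same model."""
    return REMLKernelBLUP().fit(kernels, y_obs)


def predict(fm, test_ids=None):
    """Predictions for the requested lines from a fitted model."""
    return fm.predict(test_ids)
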
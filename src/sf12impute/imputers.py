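"""The seven evaluated imputation engines, as sklearn-style transformers.

Every engine consumes an n x 12 item-score matrix with NaN marking the
masked cells and fills those cells, leaving observed cells untouched:

* ``ItemMeanImputer`` (IMV) -- column mean of the observed responses.
* ``PersonMeanImputer`` (PMV) -- row mean of the respondent's other
  observed items (default scope: the 5 remaining same-subscale items).
* ``StochasticRegressionImputer`` (SR) -- OLS on the other 11 items plus a
  stochastic error, drawn either from the fitted residuals or from a
  scaled Student t.
* ``EMImputer`` (EM) -- maximum-likelihood multivariate-normal parameters
  via expectation-maximization on the incomplete data; fills are the
  conditional means of missing given observed (deterministic).
* ``DataAugmentationImputer`` (MI_DA) -- Bayesian multiple imputation
  under a joint multivariate normal: Gibbs alternation of an imputation
  step (draw missing from their conditional normal) and a posterior step
  (inverse-Wishart / normal draws of the parameters).
* ``FCSImputer`` (MI_FCS) -- multiple imputation by chained equations
  with a Bayesian linear-regression imputation model per incomplete
  variable; with a single incomplete item this reduces to repeated
  posterior-predictive regression draws.

Model-based engines use exactly the other 11 items as predictors, never
covariates.  ``impute`` dispatches by method name and packages the result
as an :class:`ImputedDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .amputation import MaskedDataset
from .instrument import INSTRUMENT, ITEM_CODES

__all__ = [
    "METHOD_NAMES",
    "ImputationMethod",
    "ImputedDataset",
    "MvnParameters",
    "ItemMeanImputer",
    "PersonMeanImputer",
    "StochasticRegressionImputer",
    "EMImputer",
    "DataAugmentationImputer",
    "FCSImputer",
    "em_mvn",
    "make_imputer",
    "impute",
    "impute_item_mean",
    "impute_person_mean",
    "impute_stochastic_regression",
    "impute_em",
    "impute_mi_da",
    "impute_mi_fcs",
]

METHOD_NAMES = ("IMV", "PMV", "SR_RESID", "SR_T", "EM", "MI_DA", "MI_FCS")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D item-score matrix")
    return X


# ---------------------------------------------------------------------------
# simple engines
# ---------------------------------------------------------------------------

class ItemMeanImputer(TransformerMixin, BaseEstimator):
    """Fill each masked cell with the mean of the item's observed responses."""

    def fit(self, X, y=None):
        X = _as_matrix(X)
        counts = (~np.isnan(X)).sum(axis=0)
        if np.any(counts == 0):
            bad = list(np.where(counts == 0)[0])
            raise ValueError(f"no observed values in columns {bad}")
        self.statistics_ = np.nanmean(X, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X).copy()
        miss = np.isnan(X)
        X[miss] = np.take(self.statistics_, np.where(miss)[1])
        return X


class PersonMeanImputer(TransformerMixin, BaseEstimator):
    """Fill with the respondent's mean over other observed items in scope.

    ``scope='subscale'`` (default) uses the 5 remaining items of the masked
    item's subscale and requires the canonical 12-item layout;
    ``scope='all'`` uses all other observed items of any layout.
    """

    def __init__(self, scope: str = "subscale"):
        self.scope = scope

    def _groups(self, p: int) -> list[np.ndarray]:
        if self.scope == "all":
            return [np.arange(p)] * p
        if self.scope != "subscale":
            raise ValueError(f"unknown scope {self.scope!r}")
        if p != 12:
            raise ValueError("subscale scope requires the 12 canonical items")
        groups = []
        for j, code in enumerate(ITEM_CODES):
            scale = INSTRUMENT.scale_of(code)
            groups.append(
                np.array([k for k, c in enumerate(ITEM_CODES)
                          if INSTRUMENT.scale_of(c) == scale])
            )
        return groups

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self._groups(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        out = X.copy()
        groups = self._groups(X.shape[1])
        miss = np.isnan(X)
        for j in np.where(miss.any(axis=0))[0]:
            scope_cols = groups[j][groups[j] != j]
            rows = np.where(miss[:, j])[0]
            block = X[np.ix_(rows, scope_cols)]
            n_obs = (~np.isnan(block)).sum(axis=1)
            if np.any(n_obs == 0):
                raise ValueError(
                    f"respondent with no observed item in scope for column {j}"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[rows, j] = np.nanmean(block, axis=1)
        return out


# ---------------------------------------------------------------------------
# regression-based single imputation
# ---------------------------------------------------------------------------

def _ols_fit(A: np.ndarray, y: np.ndarray):
    """Least squares with an explicit rank check naming deficient columns."""
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        _, _, piv = linalg.qr(A, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:].tolist())
        raise ValueError(
            f"singular regression design; collinear design columns {dropped}"
        )
    resid = y - A @ beta
    return beta, resid


class StochasticRegressionImputer(TransformerMixin, BaseEstimator):
    """Regression of each incomplete item on the other items, plus noise.

    Fitted on rows where the target item and all predictors are observed.
    ``error_model='residual'`` resamples the fitted residuals uniformly
    with replacement; ``'t_student'`` draws from a Student t with
    df = n_obs - (p_predictors + 1), scaled by the residual standard error.
    """

    def __init__(self, error_model: str = "residual", random_state=None):
        self.error_model = error_model
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.error_model not in ("residual", "t_student"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        X = _as_matrix(X)
        n, p = X.shape
        self.models_ = {}
        for j in np.where(np.isnan(X).any(axis=0))[0]:
            others = np.delete(np.arange(p), j)
            rows = ~np.isnan(X[:, j]) & ~np.isnan(X[:, others]).any(axis=1)
            n_obs = int(rows.sum())
            if n_obs < p + 1:
                raise ValueError(
                    f"need >= {p + 1} observed rows to fit column {j}"
                )
            A = np.column_stack([np.ones(n_obs), X[np.ix_(np.where(rows)[0], others)]])
            beta, resid = _ols_fit(A, X[rows, j])
            df = n_obs - p  # predictors + intercept
            sigma = float(np.sqrt(resid @ resid / df)) if df > 0 else 0.0
            self.models_[j] = {
                "others": others, "beta": beta, "residuals": resid,
                "sigma": sigma, "df": df, "n_obs": n_obs,
            }
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = _as_matrix(X)
        out = X.copy()
        rng = np.random.default_rng(self.random_state)
        for j, m in self.models_.items():
            rows = np.where(np.isnan(X[:, j]))[0]
            if rows.size == 0:
                continue
            preds = X[np.ix_(rows, m["others"])]
            if np.isnan(preds).any():
                raise ValueError("predictors must be observed for masked rows")
            yhat = np.column_stack([np.ones(rows.size), preds]) @ m["beta"]
            if self.error_model == "residual":
                err = rng.choice(m["residuals"], size=rows.size, replace=True)
            else:
                err = m["sigma"] * rng.standard_t(m["df"], size=rows.size)
            out[rows, j] = yhat + err
        return out


# ---------------------------------------------------------------------------
# EM for the incomplete multivariate normal
# ---------------------------------------------------------------------------

@dataclass
class MvnParameters:
    """Multivariate-normal mean/covariance with EM fit diagnostics."""

    mean: np.ndarray
    covariance: np.ndarray
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        sigma = np.asarray(self.covariance, dtype=float)
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(sigma)) < -1e-10:
            raise ValueError("covariance must be positive semidefinite")


def _patterns(miss: np.ndarray):
    uniq, inverse = np.unique(miss, axis=0, return_inverse=True)
    for k in range(uniq.shape[0]):
        yield uniq[k], np.where(inverse == k)[0]


def _pattern_list(miss: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialised missingness patterns (reused across Gibbs sweeps)."""
    return [(pat, rows) for pat, rows in _patterns(miss)]


def _solve_obs_block(sigma_oo: np.ndarray, rhs: np.ndarray, ridge: float = 1e-10):
    try:
        return linalg.solve(sigma_oo, rhs, assume_a="pos")
    except linalg.LinAlgError:
        warnings.warn("singular observed-block covariance; ridge-stabilized",
                      RuntimeWarning)
        eye = np.eye(sigma_oo.shape[0])
        return linalg.solve(sigma_oo + ridge * np.trace(sigma_oo) * eye, rhs,
                            assume_a="pos")


def _observed_loglik(X, mu, sigma, patterns=None) -> float:
    ll = 0.0
    if patterns is None:
        patterns = _pattern_list(np.isnan(X))
    for pat, rows in patterns:
        o = ~pat
        if not o.any():
            continue
        Xo = X[np.ix_(rows, np.where(o)[0])]
        dist = stats.multivariate_normal(
            mean=mu[o], cov=sigma[np.ix_(o, o)], allow_singular=True
        )
        ll += float(np.sum(dist.logpdf(Xo)))
    return ll


def em_mvn(
    X, tol: float = 1e-6, max_iter: int = 500, compute_loglik: bool = True
) -> MvnParameters:
    """EM estimate of a multivariate-normal mean and covariance from
    incomplete data.

    E-step fills per-row conditional means of missing given observed and
    adds the conditional covariance correction to the sufficient
    statistics; M-step re-estimates ``mu`` and ``sigma`` (normalised by n,
    i.e. maximum likelihood).  Iterates until the largest absolute
    parameter change drops below ``tol``.  The observed-data
    log-likelihood is recorded each iteration and is nondecreasing.
    """
    X = _as_matrix(X)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("rows with every item missing cannot inform the fit")
    complete = ~miss.any(axis=1)

    mu = np.nanmean(X, axis=0)
    if complete.sum() > p:
        Xc = X[complete]
        sigma = np.cov(Xc, rowvar=False, ddof=0)
    else:
        sigma = np.diag(np.nanvar(X, axis=0))
    sigma = sigma + 1e-8 * np.eye(p)  # guard exact singularity at start

    patterns = _pattern_list(miss)
    loglik_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if compute_loglik:
            loglik_path.append(_observed_loglik(X, mu, sigma, patterns))
        sum_x = np.zeros(p)
        S = np.zeros((p, p))
        for pat, rows in patterns:
            o_idx = np.where(~pat)[0]
            m_idx = np.where(pat)[0]
            Xrows = X[rows]
            filled = Xrows.copy()
            if m_idx.size:
                sigma_oo = sigma[np.ix_(o_idx, o_idx)]
                sigma_om = sigma[np.ix_(o_idx, m_idx)]
                B = _solve_obs_block(sigma_oo, sigma_om).T  # m x o
                resid = Xrows[:, o_idx] - mu[o_idx]
                filled[:, m_idx] = mu[m_idx] + resid @ B.T
                C = sigma[np.ix_(m_idx, m_idx)] - B @ sigma_om
                S[np.ix_(m_idx, m_idx)] += rows.size * C
            sum_x += filled.sum(axis=0)
            S += filled.T @ filled
        mu_new = sum_x / n
        sigma_new = S / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        delta = max(
            float(np.max(np.abs(mu_new - mu))),
            float(np.max(np.abs(sigma_new - sigma))),
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations; "
            f"log-likelihood trace: {loglik_path[-5:]}"
        )
    return MvnParameters(
        mean=mu, covariance=sigma, n_iter=it,
        loglik_path=loglik_path, converged=converged,
    )


def _conditional_fill(
    X: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
    rng: np.random.Generator | None = None,
    patterns: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Fill missing cells with conditional means (or draws, given an rng)."""
    out = X.copy()
    if patterns is None:
        patterns = _pattern_list(np.isnan(X))
    for pat, rows in patterns:
        m_idx = np.where(pat)[0]
        if m_idx.size == 0:
            continue
        o_idx = np.where(~pat)[0]
        sigma_oo = sigma[np.ix_(o_idx, o_idx)]
        sigma_om = sigma[np.ix_(o_idx, m_idx)]
        B = _solve_obs_block(sigma_oo, sigma_om).T
        cond_mean = mu[m_idx] + (X[np.ix_(rows, o_idx)] - mu[o_idx]) @ B.T
        if rng is None:
            out[np.ix_(rows, m_idx)] = cond_mean
        else:
            C = sigma[np.ix_(m_idx, m_idx)] - B @ sigma_om
            C = (C + C.T) / 2.0
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(C + 1e-10 * np.trace(sigma) * np.eye(m_idx.size))
            z = rng.standard_normal((rows.size, m_idx.size))
            out[np.ix_(rows, m_idx)] = cond_mean + z @ L.T
    return out


class EMImputer(TransformerMixin, BaseEstimator):
    """Conditional-mean imputation under the EM-estimated joint normal.

    Deterministic by default; ``add_noise=True`` adds a draw from the
    conditional covariance instead of imputing the conditional mean.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 add_noise: bool = False, random_state=None):
        self.tol = tol
        self.max_iter = max_iter
        self.add_noise = add_noise
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        params = em_mvn(X, tol=self.tol, max_iter=self.max_iter)
        self.mean_ = params.mean
        self.covariance_ = params.covariance
        self.n_iter_ = params.n_iter
        self.loglik_path_ = params.loglik_path
        self.converged_ = params.converged
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        rng = np.random.default_rng(self.random_state) if self.add_noise else None
        return _conditional_fill(X, self.mean_, self.covariance_, rng)


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

class DataAugmentationImputer(TransformerMixin, BaseEstimator):
    """Multiple imputation by data augmentation under a joint normal.

    Starting from the EM estimate, a Gibbs sampler alternates an I-step
    (draw each missing cell from its conditional normal under the current
    parameters) and a P-step (draw the covariance from an inverse Wishart
    with df = n - 1 and the mean from its conditional normal posterior,
    the standard draws under the noninformative Jeffreys-type prior).
    After ``burn_in`` sweeps, ``m`` completed datasets are collected
    ``thin`` sweeps apart and exposed as ``imputations_``; ``transform``
    returns their cell-wise average.
    """

    def __init__(self, m: int = 5, burn_in: int = 200, thin: int = 100,
                 random_state=None, max_pd_retries: int = 10):
        self.m = m
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.max_pd_retries = max_pd_retries

    def fit(self, X, y=None):
        X = _as_matrix(X)
        params = em_mvn(X, compute_loglik=False)
        self.start_mean_ = params.mean
        self.start_covariance_ = params.covariance
        self.n_features_in_ = X.shape[1]
        return self

    def _draw_sigma(self, S: np.ndarray, n: int, rng) -> np.ndarray:
        jitter = 0.0
        for attempt in range(self.max_pd_retries):
            try:
                scale = S + jitter * np.eye(S.shape[0])
                return stats.invwishart.rvs(df=n - 1, scale=scale, random_state=rng)
            except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
                jitter = max(jitter * 10.0, 1e-8 * np.trace(S) / S.shape[0])
        raise RuntimeError("could not draw a positive-definite covariance")

    def transform(self, X):
        X = _as_matrix(X)
        n, p = X.shape
        if n <= p:
            raise ValueError("data augmentation needs n > number of items")
        rng = np.random.default_rng(self.random_state)
        mu = self.start_mean_.copy()
        sigma = self.start_covariance_.copy()
        patterns = _pattern_list(np.isnan(X))
        n_sweeps = self.burn_in + self.thin * (self.m - 1) + 1
        keep_at = {self.burn_in + k * self.thin for k in range(self.m)}
        imputations: list[np.ndarray] = []
        for sweep in range(n_sweeps):
            completed = _conditional_fill(X, mu, sigma, rng, patterns=patterns)
            xbar = completed.mean(axis=0)
            centered = completed - xbar
            S = centered.T @ centered
            sigma = self._draw_sigma(S, n, rng)
            mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
            if sweep in keep_at:
                imputations.append(completed)
        self.imputations_ = imputations
        return _average_fills(X, imputations)


def _bayes_regression_draw(A: np.ndarray, y: np.ndarray, rng):
    """Posterior draw of (beta, sigma^2) under the Jeffreys prior."""
    n, p = A.shape
    if n <= p:
        raise ValueError("too few rows for a Bayesian regression draw")
    AtA = A.T @ A
    beta_hat = linalg.solve(AtA, A.T @ y, assume_a="pos")
    resid = y - A @ beta_hat
    sse = float(resid @ resid)
    df = n - p
    sigma2 = sse / rng.chisquare(df) if sse > 0 else 0.0
    if sigma2 > 0:
        cov = sigma2 * linalg.inv(AtA)
        cov = (cov + cov.T) / 2.0
        beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    else:
        beta = beta_hat
    return beta, sigma2


class FCSImputer(TransformerMixin, BaseEstimator):
    """Multiple imputation by chained equations (fully conditional
    specification) with Bayesian linear-regression imputation models.

    Runs ``m`` independent chains; each initialises missing cells by
    resampling observed values, then cycles ``n_iter`` times over the
    incomplete variables, each time drawing regression parameters from
    their posterior and the fills from the posterior-predictive normal.
    """

    def __init__(self, m: int = 5, n_iter: int = 10, random_state=None):
        self.m = m
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        incomplete = np.where(np.isnan(X).any(axis=0))[0]
        imputations: list[np.ndarray] = []
        for _ in range(self.m):
            completed = X.copy()
            for j in incomplete:
                obs = X[~np.isnan(X[:, j]), j]
                if obs.size == 0:
                    raise ValueError(f"no observed values in column {j}")
                rows = np.isnan(X[:, j])
                completed[rows, j] = rng.choice(obs, size=int(rows.sum()))
            for _ in range(self.n_iter):
                for j in incomplete:
                    others = np.delete(np.arange(p), j)
                    obs_rows = ~np.isnan(X[:, j])
                    A = np.column_stack(
                        [np.ones(int(obs_rows.sum())), completed[np.ix_(np.where(obs_rows)[0], others)]]
                    )
                    beta, sigma2 = _bayes_regression_draw(A, X[obs_rows, j], rng)
                    mis_rows = np.where(~obs_rows)[0]
                    Am = np.column_stack([np.ones(mis_rows.size), completed[np.ix_(mis_rows, others)]])
                    completed[mis_rows, j] = (
                        Am @ beta + np.sqrt(sigma2) * rng.standard_normal(mis_rows.size)
                    )
            imputations.append(completed)
        self.imputations_ = imputations
        return _average_fills(X, imputations)


def _average_fills(X: np.ndarray, imputations: list[np.ndarray]) -> np.ndarray:
    """Cell-wise average of the imputations at the missing positions only,
    so observed cells stay bit-identical to the input."""
    out = X.copy()
    miss = np.isnan(X)
    if miss.any():
        out[miss] = np.mean([imp[miss] for imp in imputations], axis=0)
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

@dataclass
class ImputationMethod:
    """A named imputation method plus method-specific options."""

    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(
                f"unknown method {self.name!r}; expected one of {METHOD_NAMES}"
            )


_FACTORIES = {
    "IMV": lambda rs, opts: ItemMeanImputer(**opts),
    "PMV": lambda rs, opts: PersonMeanImputer(**opts),
    "SR_RESID": lambda rs, opts: StochasticRegressionImputer(
        error_model="residual", random_state=rs, **opts),
    "SR_T": lambda rs, opts: StochasticRegressionImputer(
        error_model="t_student", random_state=rs, **opts),
    "EM": lambda rs, opts: EMImputer(random_state=rs, **opts),
    "MI_DA": lambda rs, opts: DataAugmentationImputer(random_state=rs, **opts),
    "MI_FCS": lambda rs, opts: FCSImputer(random_state=rs, **opts),
}

MULTIPLE_IMPUTATION_METHODS = ("MI_DA", "MI_FCS")


def make_imputer(name: str, random_state=None, **options):
    """Instantiate the engine for a method name."""
    if name not in METHOD_NAMES:
        raise ValueError(f"unknown method {name!r}; expected one of {METHOD_NAMES}")
    return _FACTORIES[name](random_state, options)


@dataclass
class ImputedDataset:
    """Masked cells of one replicate filled by one named method.

    ``fills`` has one row per (masked cell, fill index): columns ``row``
    (positional respondent index), ``item``, ``fill_index`` (0..m-1) and
    ``value``.  Single-imputation methods have m = 1.
    """

    source: MaskedDataset
    method: str
    fills: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return int(self.fills["fill_index"].max()) + 1 if len(self.fills) else 1

    def fill_matrix(self) -> np.ndarray:
        """n_masked x m array of fills, rows aligned with the mask order."""
        rows = np.where(self.source.mask)[0]
        wide = self.fills.pivot(index="row", columns="fill_index", values="value")
        return wide.reindex(rows).to_numpy(float)

    def completed(self, fill_index: int = 0) -> pd.DataFrame:
        """The full data table with masked cells replaced by one fill set."""
        out = self.source.data.copy()
        sel = self.fills[self.fills["fill_index"] == fill_index]
        out.loc[out.index[sel["row"].to_numpy()], self.source.item] = (
            sel["value"].to_numpy()
        )
        return out


def impute(
    masked: MaskedDataset,
    method: str | ImputationMethod,
    random_state=None,
    **options,
) -> ImputedDataset:
    """Run one named engine on a masked dataset.

    Engines see only the 12 item columns; covariates are never predictors.
    """
    if isinstance(method, ImputationMethod):
        opts = {**method.options, **options}
        name = method.name
    else:
        name = str(method)
        opts = options
    est = make_imputer(name, random_state=random_state, **opts)
    X = masked.items.to_numpy(dtype=float)
    est.fit(X)
    rows = np.where(masked.mask)[0]
    j = list(masked.base.instrument.codes).index(masked.item)
    records = []
    if name in MULTIPLE_IMPUTATION_METHODS:
        est.transform(X)
        for k, completed in enumerate(est.imputations_):
            for r in rows:
                records.append((int(r), masked.item, k, float(completed[r, j])))
    else:
        completed = est.transform(X)
        for r in rows:
            records.append((int(r), masked.item, 0, float(completed[r, j])))
    fills = pd.DataFrame(records, columns=["row", "item", "fill_index", "value"])
    diagnostics = {"method": name, "n_masked": len(rows)}
    for attr in ("n_iter_", "converged_"):
        if hasattr(est, attr):
            diagnostics[attr.rstrip("_")] = getattr(est, attr)
    return ImputedDataset(source=masked, method=name, fills=fills,
                          diagnostics=diagnostics)


# -- functional wrappers -----------------------------------------------------

def impute_item_mean(d: MaskedDataset) -> ImputedDataset:
    return impute(d, "IMV")


def impute_person_mean(d: MaskedDataset, scope: str = "subscale") -> ImputedDataset:
    return impute(d, "PMV", scope=scope)


def impute_stochastic_regression(
    d: MaskedDataset, error_model: str = "residual", random_state=None
) -> ImputedDataset:
    name = "SR_RESID" if error_model == "residual" else "SR_T"
    if error_model not in ("residual", "t_student"):
        raise ValueError(f"unknown error model {error_model!r}")
    return impute(d, name, random_state=random_state)


def impute_em(d: MaskedDataset, tol: float = 1e-6, max_iter: int = 500) -> ImputedDataset:
    return impute(d, "EM", tol=tol, max_iter=max_iter)


def impute_mi_da(
    d: MaskedDataset, m: int = 5, burn_in: int = 200, thin: int = 100,
    random_state=None,
) -> ImputedDataset:
    return impute(d, "MI_DA", random_state=random_state, m=m,
                  burn_in=burn_in, thin=thin)


def impute_mi_fcs(
    d: MaskedDataset, m: int = 5, n_iter: int = 10, random_state=None
) -> ImputedDataset:
    return impute(d, "MI_FCS", random_state=random_state, m=m, n_iter=n_iter)
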
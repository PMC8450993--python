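"""Missing-data diagnostics: indicators, frequency tables, screens, models.

Response indicators code 0 = missing, 1 = not missing.  Diagnostics cover
per-item and per-person missing frequencies, bivariate Pearson screens of
the indicators against sociodemographics and health scores, and per-item
multivariate logistic models of the response indicator on age and the two
education dummies (the covariates that consistently predict item
nonresponse in SF-12 data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .instrument import (
    AUX_COLUMNS,
    INSTRUMENT,
    Instrument,
    ResponseMatrix,
    subscale_scores,
)

__all__ = [
    "LogisticMissingnessModel",
    "MissingFrequencyTable",
    "ScreenResult",
    "FitError",
    "build_indicators",
    "missing_frequency_tables",
    "indicator_covariate_screen",
    "fit_logistic",
    "fit_all_items",
    "nagelkerke_r2",
]

_COEF_NAMES = ("const", "age", "ssc", "ueq")


class FitError(RuntimeError):
    """Logistic fit failed (separation or non-convergence)."""


@dataclass
class LogisticMissingnessModel:
    """Logistic model of the response indicator (1 = not missing).

    The linear predictor is b0 + b_age*age + b_ssc*ssc + b_ueq*ueq on the
    logit of P(response present); the probability of a missing response is
    one minus the inverse logit.
    """

    item: str
    b0: float
    b_age: float
    b_ssc: float
    b_ueq: float
    se: dict[str, float] | None = None
    nagelkerke_r2: float | None = None
    n_fit: int | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.b0, self.b_age, self.b_ssc, self.b_ueq])

    @property
    def odds_ratios(self) -> dict[str, float]:
        return dict(zip(_COEF_NAMES, np.exp(self.coefficients)))

    @classmethod
    def from_coefficients(
        cls, item: str, coefs: tuple[float, float, float, float]
    ) -> "LogisticMissingnessModel":
        b0, b_age, b_ssc, b_ueq = coefs
        return cls(item=item, b0=b0, b_age=b_age, b_ssc=b_ssc, b_ueq=b_ueq)


def build_indicators(matrix: ResponseMatrix) -> pd.DataFrame:
    """n x 12 indicator matrix: 0 where the response is missing, else 1."""
    return matrix.items.notna().astype(int)


@dataclass
class MissingFrequencyTable:
    """Per-item and per-person missing-value frequency tables."""

    per_item: pd.DataFrame    # index item code; columns n_missing, pct
    per_person: pd.DataFrame  # index 0..12 missing; columns n, pct, cum_pct

    n: int = 0


def missing_frequency_tables(ind: pd.DataFrame) -> MissingFrequencyTable:
    n = len(ind)
    miss_per_item = (ind == 0).sum(axis=0)
    per_item = pd.DataFrame(
        {"n_missing": miss_per_item, "pct": 100.0 * miss_per_item / n}
    )
    k_missing = (ind == 0).sum(axis=1)
    counts = k_missing.value_counts().reindex(range(ind.shape[1] + 1), fill_value=0)
    pct = 100.0 * counts / n
    per_person = pd.DataFrame(
        {"n": counts, "pct": pct, "cum_pct": pct.cumsum()}
    )
    per_person.index.name = "n_missing_items"
    return MissingFrequencyTable(per_item=per_item, per_person=per_person, n=n)


@dataclass
class ScreenResult:
    """Pearson screen of indicators vs covariates/health scores.

    Rows are screened variables, columns the 12 item indicators.  Subscale
    scores screened against an indicator of an item on the same subscale
    are computed from the remaining five items.  Correlations use
    pairwise-complete observations (flagged in ``pairwise``).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.05
    pairwise: bool = True

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha


def _screen_variables(matrix: ResponseMatrix) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {
        "gender": matrix.data["gender"].astype(float),
        "age": matrix.data["age"].astype(float),
        "ueq": matrix.data["ueq"].astype(float),
        "ssc": matrix.data["ssc"].astype(float),
    }
    for aux in AUX_COLUMNS:
        if aux in matrix.data.columns:
            out[aux] = matrix.data[aux].astype(float)
    return out


def indicator_covariate_screen(
    ind: pd.DataFrame,
    matrix: ResponseMatrix,
    alpha: float = 0.05,
    instrument: Instrument = INSTRUMENT,
) -> ScreenResult:
    """Pearson correlations of the 12 indicators with covariates and scores."""
    variables = _screen_variables(matrix)
    row_names = list(variables) + ["sf12_physical", "sf12_mental"]
    r = pd.DataFrame(index=row_names, columns=ind.columns, dtype=float)
    p = pd.DataFrame(index=row_names, columns=ind.columns, dtype=float)
    n = pd.DataFrame(index=row_names, columns=ind.columns, dtype=float)

    for item in ind.columns:
        y = ind[item].astype(float)
        item_scale = instrument.scale_of(item)
        for name in row_names:
            if name in ("sf12_physical", "sf12_mental"):
                scale = "physical" if name == "sf12_physical" else "mental"
                exclude = item if scale == item_scale else None
                x = subscale_scores(matrix, scale, exclude=exclude)
            else:
                x = variables[name]
            ok = x.notna() & y.notna()
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            n.loc[name, item] = ok.sum()
            if ok.sum() < 3 or np.var(xv) == 0 or np.var(yv) == 0:
                r.loc[name, item] = np.nan
                p.loc[name, item] = np.nan
                continue
            rr, pp = stats.pearsonr(xv, yv)
            r.loc[name, item] = rr
            p.loc[name, item] = pp
    return ScreenResult(r=r, p=p, n=n, alpha=alpha, pairwise=True)


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled to a [0, 1] maximum."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def fit_logistic(
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    item: str = "",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticMissingnessModel:
    """Maximum-likelihood logistic fit of a 0/1 response indicator.

    ``covariates`` must contain columns age, ssc, ueq.  Raises
    :class:`FitError` on perfect separation or non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be 0/1")
    if y.min() == y.max():
        raise FitError("only one outcome class present")
    X = sm.add_constant(covariates[["age", "ssc", "ueq"]].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError) as exc:
            raise FitError(f"separation or singular fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"logistic fit did not converge: {res.mle_retvals}")
    params = res.params.to_numpy()
    if np.max(np.abs(params)) > 50:
        raise FitError("diverging coefficients suggest quasi-separation")
    ses = res.bse.to_numpy()
    return LogisticMissingnessModel(
        item=item,
        b0=float(params[0]),
        b_age=float(params[1]),
        b_ssc=float(params[2]),
        b_ueq=float(params[3]),
        se=dict(zip(_COEF_NAMES, map(float, ses))),
        nagelkerke_r2=nagelkerke_r2(res.llnull, res.llf, int(res.nobs)),
        n_fit=int(res.nobs),
    )


def fit_all_items(matrix: ResponseMatrix) -> dict[str, LogisticMissingnessModel]:
    """Fit the per-item response-indicator model for every SF-12 item."""
    ind = build_indicators(matrix)
    cov = matrix.data[["age", "ssc", "ueq"]]
    return {
        item: fit_logistic(ind[item], cov, item=item) for item in ind.columns
    }
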
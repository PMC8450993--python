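"""Canonical model of the SF-12 instrument and basic psychometrics.

The SF-12 measures health-related quality of life with twelve items, six
per subscale (physical, mental).  Four items are dichotomous, the rest use
3-, 5- or 6-point Likert formats; every response is recoded to a 0-100
score with equally spaced category values, 0 = minimum health and 100 =
maximum health.  This module defines the item catalogue, the tabular
respondent container (:class:`ResponseMatrix`), simple unweighted subscale
scores, corrected item-total correlations and Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ItemSpec",
    "Instrument",
    "ResponseMatrix",
    "INSTRUMENT",
    "ITEM_CODES",
    "PHYSICAL_ITEMS",
    "MENTAL_ITEMS",
    "COVARIATE_COLUMNS",
    "AUX_COLUMNS",
    "subscale_score",
    "subscale_scores",
    "corrected_item_total",
    "cronbach_alpha",
]

#: In-memory missing-value sentinel (files use the empty CSV field).
MISSING = np.nan

PHYSICAL_ITEMS = ("PFI2", "PFI4", "ROLPH2", "ROLPH3", "PAIN2", "GHP1")
MENTAL_ITEMS = ("VITAL2", "SOC2", "ROLEM2", "ROLEM3", "MHI3", "MHI4")
ITEM_CODES = PHYSICAL_ITEMS + MENTAL_ITEMS

COVARIATE_COLUMNS = ("age", "gender", "ssc", "ueq")
AUX_COLUMNS = ("ffbh", "scl_dep")

#: Response-format level counts per item.
_N_LEVELS = {
    "PFI2": 3, "PFI4": 3,
    "ROLPH2": 2, "ROLPH3": 2,
    "PAIN2": 5, "GHP1": 5,
    "VITAL2": 6, "SOC2": 6, "ROLEM2": 2, "ROLEM3": 2,
    "MHI3": 6, "MHI4": 6,
}


def equal_spacing(n_levels: int) -> tuple[float, ...]:
    """Equally spaced category scores on the 0-100 metric."""
    return tuple(np.linspace(0.0, 100.0, n_levels))


@dataclass(frozen=True)
class ItemSpec:
    """One SF-12 item: code, subscale membership and legal score values."""

    code: str
    scale: str
    n_levels: int
    score_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.scale not in ("physical", "mental"):
            raise ValueError(f"unknown subscale {self.scale!r}")
        if self.n_levels not in (2, 3, 5, 6):
            raise ValueError(f"unsupported level count {self.n_levels}")
        sv = np.asarray(self.score_values, dtype=float)
        if len(sv) != self.n_levels:
            raise ValueError("score_values length must equal n_levels")
        if not np.all(np.diff(sv) > 0):
            raise ValueError("score_values must be strictly increasing")
        if sv[0] != 0.0 or sv[-1] != 100.0:
            raise ValueError("score_values must span 0..100")


@dataclass(frozen=True)
class Instrument:
    """The twelve SF-12 items in canonical order."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        codes = [it.code for it in self.items]
        if len(self.items) != 12 or len(set(codes)) != 12:
            raise ValueError("an instrument has exactly 12 uniquely coded items")
        for scale in ("physical", "mental"):
            if sum(it.scale == scale for it in self.items) != 6:
                raise ValueError("each subscale has exactly 6 items")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(it.code for it in self.items)

    def item(self, code: str) -> ItemSpec:
        for it in self.items:
            if it.code == code:
                return it
        raise KeyError(f"unknown item code {code!r}")

    def subscale(self, scale: str) -> tuple[str, ...]:
        return tuple(it.code for it in self.items if it.scale == scale)

    def scale_of(self, code: str) -> str:
        return self.item(code).scale


def _default_items() -> tuple[ItemSpec, ...]:
    items = []
    for code in ITEM_CODES:
        scale = "physical" if code in PHYSICAL_ITEMS else "mental"
        n = _N_LEVELS[code]
        items.append(ItemSpec(code, scale, n, equal_spacing(n)))
    return tuple(items)


INSTRUMENT = Instrument(items=_default_items())


@dataclass
class ResponseMatrix:
    """An n x 12 item-score table plus covariates.

    ``data`` holds one row per respondent with columns ``age``, ``gender``
    (1 = female), the mutually exclusive highest-education dummies ``ssc``
    (secondary school certificate) and ``ueq`` (university entrance
    qualification), the twelve item columns on the 0-100 metric (NaN =
    missing) and, optionally, auxiliary health scores ``ffbh`` (functional
    capacity) and ``scl_dep`` (depression).  Synthetic cohorts may also
    carry the latent health factors they were generated from in
    ``latents`` (columns ``phys``, ``ment``).
    """

    data: pd.DataFrame
    latents: pd.DataFrame | None = None
    age_range: tuple[float, float] = (17.0, 87.0)
    instrument: Instrument = field(default=INSTRUMENT, repr=False)

    def __post_init__(self) -> None:
        missing_cols = [
            c for c in (*COVARIATE_COLUMNS, *self.instrument.codes)
            if c not in self.data.columns
        ]
        if missing_cols:
            raise ValueError(f"ResponseMatrix is missing columns: {missing_cols}")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def items(self) -> pd.DataFrame:
        """The 12 item columns, canonical order."""
        return self.data.loc[:, list(self.instrument.codes)]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.loc[:, list(COVARIATE_COLUMNS)]

    @property
    def aux(self) -> pd.DataFrame:
        cols = [c for c in AUX_COLUMNS if c in self.data.columns]
        return self.data.loc[:, cols]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            data=self.data.copy(),
            latents=None if self.latents is None else self.latents.copy(),
            age_range=self.age_range,
            instrument=self.instrument,
        )

    def is_complete(self) -> bool:
        return not self.items.isna().any().any()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError on any violated container invariant."""
        df = self.data
        lo, hi = self.age_range
        if ((df["age"] < lo) | (df["age"] > hi)).any():
            raise ValueError(f"age outside admissible range [{lo}, {hi}]")
        for col in ("gender", "ssc", "ueq"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"column {col!r} must be 0/1")
        if ((df["ssc"] + df["ueq"]) > 1).any():
            raise ValueError("ssc and ueq are mutually exclusive dummies")
        for spec in self.instrument.items:
            col = df[spec.code]
            obs = col.dropna()
            legal = np.asarray(spec.score_values)
            if not obs.isin(legal).all():
                bad = sorted(set(obs[~obs.isin(legal)]))
                raise ValueError(f"illegal scores {bad} in item {spec.code}")

    # -- CSV round trip --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        if "id" not in out.columns:
            out.insert(0, "id", np.arange(1, len(out) + 1))
        out.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ResponseMatrix":
        df = pd.read_csv(path)
        if "id" in df.columns:
            df = df.drop(columns=["id"])
        return cls(data=df, **kwargs)


# ---------------------------------------------------------------------------
# psychometric summaries
# ---------------------------------------------------------------------------

def _scale_codes(scale: str, instrument: Instrument = INSTRUMENT) -> tuple[str, ...]:
    codes = instrument.subscale(scale)
    if not codes:
        raise ValueError(f"unknown subscale {scale!r}")
    return codes


def subscale_score(
    row: Mapping[str, float] | pd.Series,
    scale: str,
    exclude: str | None = None,
    instrument: Instrument = INSTRUMENT,
) -> float:
    """Unweighted mean of one respondent's available items on a subscale.

    ``exclude`` drops one item (e.g. to score a scale from the remaining
    five items when the sixth is under study).  Raises if every requested
    item is missing.
    """
    codes = [c for c in _scale_codes(scale, instrument) if c != exclude]
    vals = np.array([row[c] for c in codes], dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size == 0:
        raise ValueError(f"all {scale} items missing; subscale score undefined")
    return float(obs.mean())


def subscale_scores(
    matrix: "ResponseMatrix | pd.DataFrame",
    scale: str,
    exclude: str | None = None,
    instrument: Instrument = INSTRUMENT,
) -> pd.Series:
    """Vectorised :func:`subscale_score`; rows with no available item get NaN."""
    df = matrix.data if isinstance(matrix, ResponseMatrix) else matrix
    codes = [c for c in _scale_codes(scale, instrument) if c != exclude]
    return df[codes].mean(axis=1, skipna=True)


def corrected_item_total(
    matrix: "ResponseMatrix | pd.DataFrame",
    item: str,
    instrument: Instrument = INSTRUMENT,
) -> float:
    """Corrected item-total correlation r_it.

    Pearson correlation between an item's score and the sum of the other
    five items of the same subscale, over respondents complete on the
    subscale.
    """
    df = matrix.data if isinstance(matrix, ResponseMatrix) else matrix
    scale = instrument.scale_of(item)
    codes = list(_scale_codes(scale, instrument))
    sub = df[codes].dropna()
    if len(sub) < 3:
        raise ValueError("need >=3 complete respondents on the subscale")
    x = sub[item].to_numpy(float)
    rest = sub[[c for c in codes if c != item]].sum(axis=1).to_numpy(float)
    if np.var(x) == 0 or np.var(rest) == 0:
        raise ValueError("zero variance; item-total correlation undefined")
    return float(np.corrcoef(x, rest)[0, 1])


def cronbach_alpha(
    matrix: "ResponseMatrix | pd.DataFrame",
    scale: str,
    instrument: Instrument = INSTRUMENT,
) -> float:
    """Cronbach's alpha of a subscale: k/(k-1) * (1 - sum(var_i)/var_total)."""
    df = matrix.data if isinstance(matrix, ResponseMatrix) else matrix
    codes = list(_scale_codes(scale, instrument))
    sub = df[codes].dropna().to_numpy(float)
    k = sub.shape[1]
    if k < 2 or sub.shape[0] < 3:
        raise ValueError("alpha needs >=2 items and >=3 complete respondents")
    item_vars = sub.var(axis=0, ddof=1)
    total_var = sub.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Alpha from a covariance matrix (closed form used for cross-checks)."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    total = cov.sum()
    if total == 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - np.trace(cov) / total))
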
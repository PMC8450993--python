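"""Synthetic SF-12 cohorts with a two-factor latent health structure.

The generator emulates the statistical structure the imputation study
assumes: two correlated latent health factors (physical, mental), an age
gradient on health, twelve ordinal items obtained by discretising noisy
factor propensities, realistic covariate distributions, and optional
auxiliary health measures (functional capacity, depression).

The generative model per respondent j and item i:

    phys_j, ment_j  ~  standard bivariate normal, corr = factor_corr,
                       shifted by age_health_slope * z(age_j) and rescaled
                       to unit variance
    y_ij            =  loading_i * factor(i)_j + sqrt(1 - loading_i^2) * e_ij
    score_ij        =  score_values[ sum(y_ij > thresholds_i) ]

The SF-12 represents most SF-36 dimensions by designed item pairs
(PFI2/PFI4, ROLPH2/ROLPH3, ROLEM2/ROLEM3, MHI3/MHI4); pair-mates share a
residual component ``g`` beyond the common factor, with weight
``pair_loading``, so that the most redundant companion item carries extra
predictive information about a masked response -- the structure
model-based imputation thrives on.

Thresholds default to standard-normal quantiles of a binomial-shaped
categorical whose mean score matches the profile's per-item target mean,
so generated item means track the targets by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import presets
from .instrument import (
    AUX_COLUMNS,
    INSTRUMENT,
    ITEM_CODES,
    Instrument,
    ResponseMatrix,
)

__all__ = [
    "CohortConfig",
    "cohort_config",
    "generate_cohort",
    "attach_auxiliary_measures",
    "thresholds_from_mean",
]

_EPS = 1e-9

#: Designed item pairs measuring the same health dimension.
ITEM_PAIRS: tuple[tuple[str, str], ...] = (
    ("PFI2", "PFI4"),
    ("ROLPH2", "ROLPH3"),
    ("ROLEM2", "ROLEM3"),
    ("MHI3", "MHI4"),
)


def thresholds_from_mean(n_levels: int, mean_score: float) -> np.ndarray:
    """Latent cut points whose discretised categories average ``mean_score``.

    Category masses follow Binomial(n_levels - 1, mean_score / 100), whose
    expected score under equally spaced 0-100 category values is exactly
    the target mean; cut points are the standard-normal quantiles of the
    cumulative masses.
    """
    if not 0.0 < mean_score < 100.0:
        raise ValueError("target mean must lie strictly between 0 and 100")
    q = mean_score / 100.0
    probs = stats.binom.pmf(np.arange(n_levels), n_levels - 1, q)
    cum = np.clip(np.cumsum(probs)[:-1], _EPS, 1 - _EPS)
    return stats.norm.ppf(cum)


@dataclass
class CohortConfig:
    """Everything needed to draw one ground-truth cohort reproducibly."""

    n: int
    profile: str = "clinical"
    age_mean: float = 49.74
    age_sd: float = 11.34
    age_min: float = 20.0
    age_max: float = 87.0
    p_female: float = 0.45
    p_ssc: float = 0.18
    p_ueq: float = 0.17
    factor_corr: float = 0.5
    loadings: dict[str, float] = field(
        default_factory=lambda: {c: 0.7 for c in ITEM_CODES}
    )
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    pair_loading: float = 0.45
    age_health_slope: float = -0.3
    seed: int = 0

    def validate(self, instrument: Instrument = INSTRUMENT) -> None:
        errs = []
        if self.n < 1:
            errs.append("n must be >= 1")
        for name in ("p_female", "p_ssc", "p_ueq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1]")
        if self.p_ssc + self.p_ueq > 1.0:
            errs.append("p_ssc + p_ueq must be <= 1")
        if not abs(self.factor_corr) < 1.0:
            errs.append("|factor_corr| must be < 1")
        if self.age_sd <= 0 or self.age_min >= self.age_max:
            errs.append("age distribution ill-specified")
        if not 0.0 <= self.pair_loading < 1.0:
            errs.append("pair_loading must be in [0, 1)")
        paired = {c for pair in ITEM_PAIRS for c in pair}
        for code in instrument.codes:
            lam = self.loadings.get(code)
            if lam is None or not 0.0 < lam < 1.0:
                errs.append(f"loading for {code} must be in (0, 1)")
            elif code in paired and lam**2 + self.pair_loading**2 >= 1.0:
                errs.append(
                    f"{code}: loading^2 + pair_loading^2 must be < 1")
            th = self.thresholds.get(code)
            if th is not None:
                th = np.asarray(th, dtype=float)
                if len(th) != instrument.item(code).n_levels - 1:
                    errs.append(f"{code}: need n_levels - 1 thresholds")
                elif not np.all(np.diff(th) > 0):
                    errs.append(f"{code}: thresholds must be strictly increasing")
        if errs:
            raise ValueError("invalid cohort config: " + "; ".join(errs))

    def resolved_thresholds(
        self, instrument: Instrument = INSTRUMENT
    ) -> dict[str, np.ndarray]:
        """Explicit thresholds, deriving unset items from profile target means."""
        targets = presets.ITEM_TARGET_MEANS.get(
            self.profile, presets.ITEM_TARGET_MEANS["clinical"]
        )
        out = {}
        for spec in instrument.items:
            th = self.thresholds.get(spec.code)
            if th is None:
                th = thresholds_from_mean(spec.n_levels, targets[spec.code])
            out[spec.code] = np.asarray(th, dtype=float)
        return out


def cohort_config(profile: str = "clinical", n: int = 1000, seed: int = 0,
                  **overrides) -> CohortConfig:
    """Build a config from a named profile; keyword overrides win."""
    if profile not in presets.PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    params = dict(presets.PROFILES[profile])
    params.update(overrides)
    cfg = CohortConfig(n=n, profile=profile, seed=seed, **params)
    cfg.validate()
    return cfg


def generate_cohort(
    config: CohortConfig, instrument: Instrument = INSTRUMENT
) -> ResponseMatrix:
    """Draw a fully complete ground-truth cohort; bit-reproducible under seed."""
    config.validate(instrument)
    rng = np.random.default_rng(config.seed)
    n = config.n

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    gender = (rng.random(n) < config.p_female).astype(int)
    edu = rng.choice(
        3, size=n, p=[1 - config.p_ssc - config.p_ueq, config.p_ssc, config.p_ueq]
    )
    ssc = (edu == 1).astype(int)
    ueq = (edu == 2).astype(int)

    rho = config.factor_corr
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z_age = (age - config.age_mean) / config.age_sd
    slope = config.age_health_slope
    scale = np.sqrt(1.0 + slope**2)
    phys = (e1 + slope * z_age) / scale
    ment = (rho * e1 + np.sqrt(1 - rho**2) * e2 + slope * z_age) / scale

    thresholds = config.resolved_thresholds(instrument)
    pair_of = {c: k for k, pair in enumerate(ITEM_PAIRS) for c in pair}
    pair_g = rng.standard_normal((len(ITEM_PAIRS), n))
    delta = config.pair_loading
    cols = {"age": age, "gender": gender, "ssc": ssc, "ueq": ueq}
    for spec in instrument.items:
        factor = phys if spec.scale == "physical" else ment
        lam = config.loadings[spec.code]
        y = lam * factor
        resid_var = 1.0 - lam**2
        if spec.code in pair_of:
            y = y + delta * pair_g[pair_of[spec.code]]
            resid_var -= delta**2
        y = y + np.sqrt(resid_var) * rng.standard_normal(n)
        cat = np.searchsorted(thresholds[spec.code], y)
        cols[spec.code] = np.asarray(spec.score_values, dtype=float)[cat]

    matrix = ResponseMatrix(
        data=pd.DataFrame(cols),
        latents=pd.DataFrame({"phys": phys, "ment": ment}),
        age_range=(min(17.0, config.age_min), max(87.0, config.age_max)),
        instrument=instrument,
    )
    matrix.validate()
    return matrix


#: Default linear maps (w_phys, w_ment) from latents to auxiliary scores.
DEFAULT_AUX_WEIGHTS: dict[str, tuple[float, float]] = {
    "ffbh": (1.0, 0.25),      # functional capacity tracks physical health
    "scl_dep": (-0.25, -1.0),  # depression runs against mental health
}


def attach_auxiliary_measures(
    matrix: ResponseMatrix,
    weights: Mapping[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> ResponseMatrix:
    """Add auxiliary health scores as linear maps of the latent factors.

    Each auxiliary column is w_phys * phys + w_ment * ment + N(0, noise_sd)
    noise.  Requires the cohort to carry latents (synthetic cohorts do).
    """
    if matrix.latents is None:
        raise ValueError("cohort carries no latent factors; cannot attach aux scores")
    if weights is None:
        weights = DEFAULT_AUX_WEIGHTS
    unknown = set(weights) - set(AUX_COLUMNS)
    if unknown:
        raise ValueError(f"unknown auxiliary columns {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    out.latents = matrix.latents.copy()
    phys = matrix.latents["phys"].to_numpy()
    ment = matrix.latents["ment"].to_numpy()
    for name, (w_p, w_m) in weights.items():
        out.data[name] = (
            w_p * phys + w_m * ment + noise_sd * rng.standard_normal(matrix.n)
        )
    return out
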
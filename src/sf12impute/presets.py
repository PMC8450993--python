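"""Packaged reference presets for cohort generation and missingness models.

Two built-in cohort profiles emulate the kinds of samples SF-12 imputation
studies draw on:

* ``clinical`` -- orthopedic rehabilitation patients: middle-aged, modest
  education levels, impaired physical health, and substantial per-item
  missing-data rates (1.5%-17.8%).
* ``normative`` -- a general-population reference sample: wider age range,
  better average health, and per-item missing rates below 1%.

The missingness coefficient preset parameterises, per item, a logistic
model for the response indicator (1 = not missing) as a linear function of
age in years and the two highest-education dummies SSC / UEQ.  Positive
education coefficients and negative age coefficients encode the robust
empirical finding that older and less educated respondents omit items more
often.  These values are reference estimates from clinical SF-12 data and
ship with the package so simulations are reproducible without refitting.
"""

from __future__ import annotations

from .instrument import ITEM_CODES

__all__ = [
    "MISSINGNESS_COEFFICIENTS",
    "MISSING_RATES",
    "ITEM_TARGET_MEANS",
    "PROFILES",
]

#: Per-item logistic coefficients for P(response present):
#: (intercept, b_age, b_ssc, b_ueq).
MISSINGNESS_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "PFI2":   (4.50, -0.03, 1.62, 1.11),
    "PFI4":   (3.70, -0.03, 0.71, 0.84),
    "ROLPH2": (3.65, -0.04, 0.93, 1.01),
    "ROLPH3": (4.67, -0.05, 0.32, 0.55),
    "PAIN2":  (9.14, -0.09, -0.32, 0.15),
    "GHP1":   (4.31, -0.02, -0.01, 1.89),
    "VITAL2": (3.73, -0.05, 0.64, 0.77),
    "SOC2":   (5.16, -0.03, 0.23, 1.05),
    "ROLEM2": (3.85, -0.04, 0.32, 1.16),
    "ROLEM3": (3.92, -0.04, 0.54, 0.73),
    "MHI3":   (3.74, -0.04, 0.23, 0.77),
    "MHI4":   (4.18, -0.04, 1.08, 0.40),
}

#: Per-item target missing rates h_i (fractions) by profile.
MISSING_RATES: dict[str, dict[str, float]] = {
    "clinical": {
        "PFI2": 0.038, "PFI4": 0.082, "ROLPH2": 0.114, "ROLPH3": 0.104,
        "PAIN2": 0.015, "GHP1": 0.031, "VITAL2": 0.178, "SOC2": 0.028,
        "ROLEM2": 0.099, "ROLEM3": 0.142, "MHI3": 0.112, "MHI4": 0.104,
    },
    "normative": {
        "PFI2": 0.004, "PFI4": 0.004, "ROLPH2": 0.007, "ROLPH3": 0.009,
        "PAIN2": 0.008, "GHP1": 0.001, "VITAL2": 0.007, "SOC2": 0.009,
        "ROLEM2": 0.006, "ROLEM3": 0.008, "MHI3": 0.006, "MHI4": 0.006,
    },
}

#: Per-item target mean scores (0-100) by profile; the generator derives
#: discretisation thresholds from these (binomial-shaped category masses).
ITEM_TARGET_MEANS: dict[str, dict[str, float]] = {
    "clinical": {
        "PFI2": 37.02, "PFI4": 50.28, "ROLPH2": 13.76, "ROLPH3": 18.68,
        "PAIN2": 35.12, "GHP1": 30.87, "VITAL2": 39.53, "SOC2": 64.95,
        "ROLEM2": 51.41, "ROLEM3": 56.10, "MHI3": 54.06, "MHI4": 67.72,
    },
    "normative": {
        "PFI2": 85.16, "PFI4": 83.16, "ROLPH2": 79.59, "ROLPH3": 85.04,
        "PAIN2": 50.89, "GHP1": 78.62, "VITAL2": 57.60, "SOC2": 84.27,
        "ROLEM2": 86.73, "ROLEM3": 89.62, "MHI3": 63.25, "MHI4": 80.74,
    },
}

#: Per-item factor loadings, calibrated once so that generated corrected
#: item-total correlations land on the per-profile reference values
#: (clinical spread .34-.67, normative .50-.68); the heterogeneity across
#: items is what separates well- from poorly-imputable items.
ITEM_LOADINGS: dict[str, dict[str, float]] = {
    "clinical": {
        "PFI2": 0.696, "PFI4": 0.526, "ROLPH2": 0.739, "ROLPH3": 0.747,
        "PAIN2": 0.811, "GHP1": 0.451, "VITAL2": 0.591, "SOC2": 0.580,
        "ROLEM2": 0.819, "ROLEM3": 0.790, "MHI3": 0.609, "MHI4": 0.707,
    },
    "normative": {
        "PFI2": 0.823, "PFI4": 0.743, "ROLPH2": 0.793, "ROLPH3": 0.880,
        "PAIN2": 0.701, "GHP1": 0.831, "VITAL2": 0.729, "SOC2": 0.754,
        "ROLEM2": 0.793, "ROLEM3": 0.824, "MHI3": 0.614, "MHI4": 0.706,
    },
}

#: Demographic and latent-structure defaults per profile.
PROFILES: dict[str, dict] = {
    "clinical": {
        "age_mean": 49.74, "age_sd": 11.34, "age_min": 20.0, "age_max": 87.0,
        "p_female": 0.45, "p_ssc": 0.18, "p_ueq": 0.17,
        "factor_corr": 0.5,
        "loadings": dict(ITEM_LOADINGS["clinical"]),
        "age_health_slope": -0.3,
    },
    "normative": {
        "age_mean": 45.62, "age_sd": 15.87, "age_min": 17.0, "age_max": 79.0,
        "p_female": 0.51, "p_ssc": 0.20, "p_ueq": 0.37,
        "factor_corr": 0.5,
        "loadings": dict(ITEM_LOADINGS["normative"]),
        "age_health_slope": -0.3,
    },
}
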
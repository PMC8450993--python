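"""Amputation: simulate realistic single-item missingness in complete data.

Per item i and respondent j the probability of a missing response comes
from the logistic response-indicator model,

    p_ij,logistic = 1 - expit(b0 + b_age*age_j + b_ssc*ssc_j + b_ueq*ueq_j),

and is then attenuated so the mean simulated probability hits the item's
target missing rate h_i:

    p_ij,adjust = clip(p_ij,logistic * h_i / mean_j(p_ij,logistic), 0, 1).

The attenuation compensates for complete-case subsamples being younger
and better educated than the full sample they come from.  A simulated
indicator SIV (0 = masked, 1 = kept) is drawn Bernoulli per respondent;
masking touches exactly one item per dataset and the whole procedure is
replicated R times per item on independent RNG substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import LogisticMissingnessModel
from .instrument import INSTRUMENT, Instrument, ResponseMatrix

__all__ = [
    "MissingProbabilityVector",
    "MaskedDataset",
    "predict_missing_probability",
    "attenuate",
    "draw_indicators",
    "mask_item",
    "simulate_replicates",
    "complete_cases",
]

logger = logging.getLogger(__name__)


def predict_missing_probability(
    model: LogisticMissingnessModel, matrix: ResponseMatrix
) -> np.ndarray:
    """Per-respondent probability that the item's response is missing."""
    df = matrix.data
    eta = (
        model.b0
        + model.b_age * df["age"].to_numpy(float)
        + model.b_ssc * df["ssc"].to_numpy(float)
        + model.b_ueq * df["ueq"].to_numpy(float)
    )
    return 1.0 - expit(eta)


@dataclass
class MissingProbabilityVector:
    """Logistic and attenuated missing probabilities for one item."""

    item: str
    p_logistic: np.ndarray
    h: float
    p_adjust: np.ndarray | None = None
    n_clipped: int = 0

    @property
    def p_bar(self) -> float:
        return float(np.mean(self.p_logistic))


def attenuate(
    p_logistic: np.ndarray | MissingProbabilityVector,
    h: float | None = None,
    item: str = "",
) -> MissingProbabilityVector:
    """Rescale logistic probabilities so their mean equals the target rate.

    When no element needs clipping at 1, mean(p_adjust) == h exactly.
    Clipping (possible for extreme covariate patterns) biases the realized
    rate slightly below h; the clipped count is recorded and logged.
    """
    if isinstance(p_logistic, MissingProbabilityVector):
        vec = p_logistic
        if h is not None:
            vec = MissingProbabilityVector(vec.item, vec.p_logistic, h)
    else:
        if h is None:
            raise ValueError("target rate h required")
        vec = MissingProbabilityVector(item, np.asarray(p_logistic, float), float(h))
    if not 0.0 <= vec.h <= 1.0:
        raise ValueError("target rate h must be in [0, 1]")
    if np.any((vec.p_logistic < 0) | (vec.p_logistic > 1)):
        raise ValueError("p_logistic outside [0, 1]")
    p_bar = vec.p_bar
    if p_bar == 0.0:
        if vec.h > 0:
            raise ValueError("degenerate model: p_bar = 0 but target rate > 0")
        raw = np.zeros_like(vec.p_logistic)
    else:
        raw = vec.p_logistic * vec.h / p_bar
    adjusted = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(raw > 1.0))
    if n_clipped:
        logger.info(
            "attenuate(%s): clipped %d of %d probabilities at 1; realized "
            "rate will fall slightly below h=%.4f",
            vec.item, n_clipped, raw.size, vec.h,
        )
    vec.p_adjust = adjusted
    vec.n_clipped = n_clipped
    return vec


def draw_indicators(
    p: MissingProbabilityVector | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli simulated indicators: 0 = masked with prob p_adjust, else 1."""
    if isinstance(p, MissingProbabilityVector):
        if p.p_adjust is None:
            raise ValueError("call attenuate() first: p_adjust not filled")
        probs = p.p_adjust
    else:
        probs = np.asarray(p, dtype=float)
    return (rng.random(probs.size) >= probs).astype(int)


@dataclass
class MaskedDataset:
    """A complete cohort with exactly one item partially masked."""

    base: ResponseMatrix
    item: str
    siv: np.ndarray
    replicate: int = 1
    seed_path: str = ""

    def __post_init__(self) -> None:
        self.siv = np.asarray(self.siv, dtype=int)
        if self.item not in self.base.instrument.codes:
            raise ValueError(f"unknown item {self.item!r}")
        if self.siv.size != self.base.n:
            raise ValueError("siv length must equal cohort size")

    @property
    def mask(self) -> np.ndarray:
        """Boolean vector, True where the item was masked."""
        return self.siv == 0

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def data(self) -> pd.DataFrame:
        out = self.base.data.copy()
        out.loc[self.mask, self.item] = np.nan
        return out

    @property
    def items(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.base.instrument.codes)]

    @property
    def truth(self) -> np.ndarray:
        """Ground-truth scores at the masked cells."""
        return self.base.data.loc[self.mask, self.item].to_numpy(float)


def mask_item(
    base: ResponseMatrix,
    item: str,
    siv: np.ndarray,
    replicate: int = 1,
    seed_path: str = "",
) -> MaskedDataset:
    """Mask one item wherever the simulated indicator is 0."""
    return MaskedDataset(base=base, item=item, siv=siv,
                         replicate=replicate, seed_path=seed_path)


def complete_cases(matrix: ResponseMatrix) -> ResponseMatrix:
    """Restrict to respondents complete on all 12 items (no-op if complete)."""
    keep = matrix.items.notna().all(axis=1)
    out = matrix.copy()
    out.data = matrix.data.loc[keep].reset_index(drop=True)
    if matrix.latents is not None:
        out.latents = matrix.latents.loc[keep].reset_index(drop=True)
    return out


def simulate_replicates(
    base: ResponseMatrix,
    models: Mapping[str, LogisticMissingnessModel],
    rates: Mapping[str, float],
    n_replicates: int = 10,
    seed: int = 0,
    items: Sequence[str] | None = None,
    instrument: Instrument = INSTRUMENT,
) -> list[MaskedDataset]:
    """Item-specific single-item masking, R replicates per item.

    Returns 12 * R masked datasets (for the default full item set), each
    drawn on an RNG substream derived from (seed, item index, replicate)
    so that adding replicates never perturbs earlier ones.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not base.is_complete():
        raise ValueError("base cohort must be complete on all 12 items")
    codes = tuple(items) if items is not None else instrument.codes
    out: list[MaskedDataset] = []
    for item_idx, item in enumerate(codes):
        p_log = predict_missing_probability(models[item], base)
        vec = attenuate(p_log, h=rates[item], item=item)
        for rep in range(1, n_replicates + 1):
            ss = np.random.SeedSequence(seed, spawn_key=(item_idx, rep))
            rng = np.random.default_rng(ss)
            siv = draw_indicators(vec, rng)
            out.append(
                MaskedDataset(
                    base=base, item=item, siv=siv, replicate=rep,
                    seed_path=f"{seed}/{item}/{rep}",
                )
            )
    return out
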
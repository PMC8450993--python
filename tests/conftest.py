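import numpy as np
import pandas as pd
import pytest

from sf12impute import (
    ITEM_CODES,
    ResponseMatrix,
    cohort_config,
    generate_cohort,
)
from sf12impute.amputation import MaskedDataset
from sf12impute.pipeline import preset_models, preset_rates


def make_matrix(items: np.ndarray, age=None, ssc=None, ueq=None,
                gender=None) -> ResponseMatrix:
    """Build a ResponseMatrix from a raw n x 12 item array (tests only)."""
    items = np.asarray(items, dtype=float)
    n = items.shape[0]
    data = pd.DataFrame(items, columns=list(ITEM_CODES))
    data.insert(0, "ueq", np.zeros(n, dtype=int) if ueq is None else ueq)
    data.insert(0, "ssc", np.zeros(n, dtype=int) if ssc is None else ssc)
    data.insert(0, "gender", np.zeros(n, dtype=int) if gender is None else gender)
    data.insert(0, "age", np.full(n, 50.0) if age is None else age)
    return ResponseMatrix(data=data)


def mask_rows(base: ResponseMatrix, item: str, rows) -> MaskedDataset:
    """Mask an item at explicit row positions."""
    siv = np.ones(base.n, dtype=int)
    siv[np.asarray(rows)] = 0
    return MaskedDataset(base=base, item=item, siv=siv)


@pytest.fixture(scope="session")
def clinical_cohort() -> ResponseMatrix:
    return generate_cohort(cohort_config("clinical", n=600, seed=7))


@pytest.fixture(scope="session")
def models():
    return preset_models()


@pytest.fixture(scope="session")
def clinical_rates():
    return preset_rates("clinical")


@pytest.fixture(scope="session")
def masked_vital(clinical_cohort, models, clinical_rates) -> MaskedDataset:
    """One VITAL2 replicate masked under the packaged missingness model."""
    from sf12impute.amputation import attenuate, draw_indicators, mask_item, predict_missing_probability

    p = predict_missing_probability(models["VITAL2"], clinical_cohort)
    vec = attenuate(p, h=clinical_rates["VITAL2"], item="VITAL2")
    rng = np.random.default_rng(3)
    return mask_item(clinical_cohort, "VITAL2", draw_indicators(vec, rng))
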
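"""Shared fixtures: small hand-built datasets and cause lists."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vacalib import CauseList, PairedDataset, UnpairedDataset


def make_unpaired(predictions: dict[str, list], causes: CauseList) -> UnpairedDataset:
    """Build an unpaired dataset from per-algorithm label lists."""
    n = len(next(iter(predictions.values())))
    return UnpairedDataset(
        death_id=tuple(f"u{i:06d}" for i in range(n)),
        predictions=pd.DataFrame(predictions, columns=list(predictions)),
        algorithms=tuple(predictions),
        causes=causes,
    )


def make_paired(
    reference: list, predictions: dict[str, list], causes: CauseList
) -> PairedDataset:
    """Build a paired dataset from a reference list and per-algorithm labels."""
    n = len(reference)
    return PairedDataset(
        death_id=tuple(f"p{i:06d}" for i in range(n)),
        reference_cause=tuple(reference),
        predictions=pd.DataFrame(predictions, columns=list(predictions)),
        algorithms=tuple(predictions),
        causes=causes,
    )


@pytest.fixture
def two_causes() -> CauseList:
    return CauseList(("cause_a", "cause_b"))


@pytest.fixture
def three_causes() -> CauseList:
    return CauseList(("alpha", "beta", "gamma"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
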
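"""Readers, writers and filters for the unpaired and paired VA datasets.

The *unpaired* dataset plays the population-survey role: one predicted broad
cause per CCVA algorithm per death, no reference cause. The *paired* dataset
plays the reference-standard role: each death additionally carries a
reference cause (e.g. from minimally invasive tissue sampling) used to learn
algorithm misclassification rates.

CSV dialect is fixed: UTF-8, comma-separated, mandatory header. Missing
(inconclusive) predictions are an empty cell or the literal token "NA".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cause_space import CauseList

__all__ = [
    "UnpairedDataset",
    "PairedDataset",
    "read_unpaired",
    "read_paired",
    "write_unpaired",
    "write_paired",
    "complete_case_filter",
    "MISSING_TOKENS",
]

MISSING_TOKENS = ("", "NA")


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() in MISSING_TOKENS
    )


def _validate_predictions(
    df: pd.DataFrame,
    causes: CauseList,
    columns: Sequence[str],
    *,
    allow_missing: bool,
    source: str,
) -> pd.DataFrame:
    """Canonicalize cause labels in ``columns``; missing -> None.

    Errors cite the 1-based CSV data row (header excluded).
    """
    out = df.copy()
    for col in columns:
        cleaned = []
        for pos, value in enumerate(df[col]):
            if _is_missing(value):
                if not allow_missing:
                    raise ValueError(
                        f"{source}: column {col!r}, row {pos + 1}: value is "
                        "missing but this column may not contain missing values"
                    )
                cleaned.append(None)
            elif value not in causes:
                raise ValueError(
                    f"{source}: column {col!r}, row {pos + 1}: unknown cause "
                    f"label {str(value).strip()!r}; known causes: "
                    f"{list(causes.labels)}"
                )
            else:
                cleaned.append(causes.canonicalize(value))
        out[col] = pd.array(cleaned, dtype="object")
    return out


def _check_ids(ids: pd.Series, source: str) -> list[str]:
    ids = ids.astype(str).str.strip()
    if (ids == "").any():
        raise ValueError(f"{source}: empty death_id value")
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{source}: duplicate death_id values: {sorted(dup)[:10]}")
    return list(ids)


@dataclass(frozen=True)
class UnpairedDataset:
    """Per-death CCVA predictions with no reference cause (survey role)."""

    death_id: tuple[str, ...]
    predictions: pd.DataFrame  # one object column per algorithm; None = missing
    algorithms: tuple[str, ...]
    causes: CauseList

    def __post_init__(self) -> None:
        if list(self.predictions.columns) != list(self.algorithms):
            raise ValueError("prediction columns must match the algorithm list")
        if len(self.predictions) != len(self.death_id):
            raise ValueError("death_id and predictions disagree in length")

    @property
    def n_records(self) -> int:
        return len(self.death_id)

    def __len__(self) -> int:
        return self.n_records

    def to_frame(self) -> pd.DataFrame:
        df = self.predictions.copy()
        df.insert(0, "death_id", list(self.death_id))
        return df.reset_index(drop=True)


@dataclass(frozen=True)
class PairedDataset:
    """Per-death reference cause plus CCVA predictions (reference-standard role)."""

    death_id: tuple[str, ...]
    reference_cause: tuple[str, ...]  # never missing
    predictions: pd.DataFrame
    algorithms: tuple[str, ...]
    causes: CauseList

    def __post_init__(self) -> None:
        if list(self.predictions.columns) != list(self.algorithms):
            raise ValueError("prediction columns must match the algorithm list")
        if not (len(self.predictions) == len(self.death_id) == len(self.reference_cause)):
            raise ValueError("death_id, reference_cause and predictions disagree in length")

    @property
    def n_records(self) -> int:
        return len(self.death_id)

    def __len__(self) -> int:
        return self.n_records

    def to_frame(self) -> pd.DataFrame:
        df = self.predictions.copy()
        df.insert(0, "reference_cause", list(self.reference_cause))
        df.insert(0, "death_id", list(self.death_id))
        return df.reset_index(drop=True)


def _read_csv(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False so "NA" and "" reach our own missing-value logic
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_unpaired(
    path: str | Path, causes: CauseList, algorithms: Sequence[str]
) -> UnpairedDataset:
    """Read and validate an unpaired-dataset CSV.

    Expects columns ``death_id, <algorithm_1>, ..., <algorithm_K>``.
    """
    source = str(path)
    df = _read_csv(path)
    required = ["death_id", *algorithms]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{source}: missing required columns {missing_cols}")
    ids = _check_ids(df["death_id"], source)
    df = _validate_predictions(df, causes, list(algorithms), allow_missing=True, source=source)
    return UnpairedDataset(
        death_id=tuple(ids),
        predictions=df[list(algorithms)].reset_index(drop=True),
        algorithms=tuple(algorithms),
        causes=causes,
    )


def read_paired(
    path: str | Path, causes: CauseList, algorithms: Sequence[str]
) -> PairedDataset:
    """Read and validate a paired-dataset CSV.

    Expects columns ``death_id, reference_cause, <algorithm_1>, ...``; the
    reference cause may never be missing.
    """
    source = str(path)
    df = _read_csv(path)
    required = ["death_id", "reference_cause", *algorithms]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{source}: missing required columns {missing_cols}")
    ids = _check_ids(df["death_id"], source)
    df = _validate_predictions(
        df, causes, ["reference_cause"], allow_missing=False, source=source
    )
    df = _validate_predictions(df, causes, list(algorithms), allow_missing=True, source=source)
    return PairedDataset(
        death_id=tuple(ids),
        reference_cause=tuple(df["reference_cause"]),
        predictions=df[list(algorithms)].reset_index(drop=True),
        algorithms=tuple(algorithms),
        causes=causes,
    )


def _write(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    for col in df.columns:
        df[col] = ["" if v is None else v for v in df[col]]
    df.to_csv(path, index=False, encoding="utf-8")


def write_unpaired(dataset: UnpairedDataset, path: str | Path) -> None:
    _write(dataset.to_frame(), path)


def write_paired(dataset: PairedDataset, path: str | Path) -> None:
    _write(dataset.to_frame(), path)


def complete_case_filter(
    dataset: UnpairedDataset | PairedDataset,
    algorithms_required: Sequence[str] | None = None,
):
    """Drop records missing a prediction for any required algorithm.

    Complete-case analysis keeps exactly the records with a conclusive
    prediction from every algorithm in ``algorithms_required`` (default: all
    algorithms in the dataset), so single-algorithm and ensemble runs use the
    same records. Pass a single-algorithm subset for per-algorithm filtering.

    Returns ``(filtered_dataset, n_excluded)``.
    """
    required = tuple(algorithms_required) if algorithms_required is not None else dataset.algorithms
    unknown = [a for a in required if a not in dataset.algorithms]
    if unknown:
        raise ValueError(
            f"algorithms {unknown} not in dataset (has {list(dataset.algorithms)})"
        )
    keep = np.ones(len(dataset), dtype=bool)
    for alg in required:
        keep &= np.array([v is not None for v in dataset.predictions[alg]])
    n_excluded = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("complete_case_filter removed every record", stacklevel=2)
    preds = dataset.predictions.loc[keep].reset_index(drop=True)
    ids = tuple(i for i, k in zip(dataset.death_id, keep) if k)
    if isinstance(dataset, PairedDataset):
        refs = tuple(r for r, k in zip(dataset.reference_cause, keep) if k)
        out = PairedDataset(ids, refs, preds, dataset.algorithms, dataset.causes)
    else:
        out = UnpairedDataset(ids, preds, dataset.algorithms, dataset.causes)
    return out, n_excluded
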
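"""Broad cause-of-death categories and fine-to-broad cause mapping.

Every downstream object (CSMF vectors, misclassification matrices, posterior
draws) indexes causes by the canonical order of a :class:`CauseList`, so the
cause list is fixed once per analysis and shared everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CauseList",
    "CauseMap",
    "builtin_cause_list",
    "builtin_cause_map",
    "apply_cause_map",
    "read_cause_map",
    "CHILD_BROAD_CAUSES",
    "NEONATE_BROAD_CAUSES",
]

#: Broad causes for children aged 1-59 months, in canonical order.
CHILD_BROAD_CAUSES: tuple[str, ...] = (
    "pneumonia",
    "malaria",
    "diarrhea",
    "severe malnutrition",
    "hiv",
    "other infections",
    "other",
)

#: Broad causes for neonates, in canonical order.
NEONATE_BROAD_CAUSES: tuple[str, ...] = (
    "congenital malformation",
    "infection",
    "ipre",
    "prematurity",
    "other",
)

_AGE_GROUPS = ("child", "neonate")


def _norm(label: str) -> str:
    """Normalise a cause label: trim whitespace, casefold."""
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class CauseList:
    """Ordered list of distinct broad cause labels.

    Defines the dimension ``C`` of the CSMF simplex and the row/column index
    convention of every misclassification matrix. Label matching is
    case-insensitive after whitespace trimming.
    """

    labels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x).strip() for x in self.labels)
        if len(labels) < 2:
            raise ValueError("a CauseList needs at least 2 causes")
        if any(not x for x in labels):
            raise ValueError("cause labels must be non-empty strings")
        index = {_norm(x): i for i, x in enumerate(labels)}
        if len(index) != len(labels):
            raise ValueError(f"cause labels are not unique: {labels}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_index", index)

    @property
    def C(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return isinstance(label, str) and _norm(label) in self._index

    def index(self, label: str) -> int:
        """Position of ``label`` in canonical order (case/space-insensitive)."""
        try:
            return self._index[_norm(label)]
        except KeyError:
            raise KeyError(
                f"unknown cause {label!r}; known causes: {list(self.labels)}"
            ) from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(x) for x in labels]

    def canonicalize(self, label: str) -> str:
        """Return the canonical spelling of ``label``."""
        return self.labels[self.index(label)]


@dataclass(frozen=True)
class CauseMap:
    """Total mapping from fine cause names to broad categories.

    ``entries`` keys and values are matched case-insensitively; every value
    must be a member of ``target``. Totality over a given dataset is enforced
    when the map is applied, not at construction.
    """

    entries: Mapping[str, str]
    target: CauseList
    _lookup: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for fine, broad in self.entries.items():
            if broad not in self.target:
                raise ValueError(
                    f"cause map sends {fine!r} to {broad!r}, which is not in the "
                    f"target cause list {list(self.target.labels)}"
                )
            lookup[_norm(fine)] = self.target.canonicalize(broad)
        object.__setattr__(self, "_lookup", lookup)

    def __contains__(self, fine: object) -> bool:
        return isinstance(fine, str) and _norm(fine) in self._lookup

    def __getitem__(self, fine: str) -> str:
        return self._lookup[_norm(fine)]


def builtin_cause_list(age_group: str) -> CauseList:
    """Canonical broad cause list for an age group.

    Children (1-59 months) use seven broad causes; neonates use five.
    """
    key = _norm(age_group)
    if key == "child":
        return CauseList(CHILD_BROAD_CAUSES)
    if key == "neonate":
        return CauseList(NEONATE_BROAD_CAUSES)
    raise ValueError(
        f"unknown age_group {age_group!r}; supported values: {list(_AGE_GROUPS)}"
    )


# Fine causes named in the study's aggregation scheme. Each broad label also
# maps to itself so already-aggregated data pass through unchanged. The fine
# vocabularies of real CCVA algorithms are larger; users extend these via a
# cause-map CSV.
_CHILD_FINE = {
    "meningitis": "other infections",
    "typhoid fever": "other infections",
    "hepatitis": "other infections",
    "cancer": "other",
    "injury": "other",
    "congenital malformation": "other",
}
_NEONATE_FINE = {
    "neonatal tetanus": "infection",
    "meningitis and encephalitis": "infection",
    "diarrhea": "infection",
    "pneumonia": "infection",
    "sepsis": "infection",
    "injury": "other",
}


def builtin_cause_map(age_group: str) -> CauseMap:
    """Default fine-to-broad map for an age group (identity on broad labels)."""
    target = builtin_cause_list(age_group)
    fine = _CHILD_FINE if _norm(age_group) == "child" else _NEONATE_FINE
    entries = {lab: lab for lab in target.labels}
    entries.update(fine)
    return CauseMap(entries, target)


def apply_cause_map(labels: Sequence[str], cause_map: CauseMap) -> list[str]:
    """Map a sequence of fine cause names to broad categories.

    Preserves length and order. Every input label must have an entry;
    unmapped labels raise with the full offending list rather than being
    dropped silently.
    """
    missing = sorted({lab for lab in labels if lab not in cause_map})
    if missing:
        raise KeyError(
            f"cause map has no entry for {len(missing)} fine cause(s): {missing}"
        )
    return [cause_map[lab] for lab in labels]


def read_cause_map(path: str | Path, target: CauseList) -> CauseMap:
    """Read a two-column (fine_cause, broad_cause) CSV with a header row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: cause map CSV needs two columns, got {df.shape[1]}")
    fine_col, broad_col = df.columns[:2]
    entries = dict(zip(df[fine_col].str.strip(), df[broad_col].str.strip()))
    return CauseMap(entries, target)
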
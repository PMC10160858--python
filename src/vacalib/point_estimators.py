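"""Deterministic estimators: raw CSMFs, misclassification matrices, the
linear back-solve calibration, and the equally weighted ensemble.

Conventions. A CSMF is a point on the C-simplex. A misclassification matrix
``M`` is row-stochastic with rows indexed by the *reference* cause and
columns by the *predicted* cause, so its diagonal holds the cause-specific
sensitivities. The predicted-cause marginal implied by a true CSMF ``p`` is
``q = M' p`` (entrywise ``q_j = sum_i p_i M_ij``); calibration inverts this
relation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cause_space import CauseList
from .datasets_io import PairedDataset

__all__ = [
    "CSMF",
    "MisclassificationMatrix",
    "BacksolveResult",
    "raw_csmf",
    "raw_csmf_from_counts",
    "estimate_misclassification",
    "forward_marginal",
    "backsolve_csmf",
    "ensemble_uncalibrated",
    "write_csmf",
    "write_misclassification",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class CSMF:
    """Cause-specific mortality fractions: a probability vector over causes.

    ``counts`` optionally retains the integer predicted-cause counts the
    fractions were computed from, for reporting.
    """

    causes: CauseList
    p: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.causes.C,):
            raise ValueError(f"p has shape {p.shape}, expected ({self.causes.C},)")
        if np.any(p < -_SIMPLEX_TOL) or np.any(p > 1 + _SIMPLEX_TOL):
            raise ValueError(f"CSMF entries outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"CSMF entries sum to {p.sum():.12f}, not 1")
        object.__setattr__(self, "p", p)
        if self.counts is not None:
            object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))

    def __getitem__(self, cause: str) -> float:
        return float(self.p[self.causes.index(cause)])

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Fractions as percentages rounded for table display."""
        return {
            lab: round(100 * float(v), decimals)
            for lab, v in zip(self.causes.labels, self.p)
        }


@dataclass(frozen=True)
class MisclassificationMatrix:
    """Row-stochastic matrix of CCVA misclassification rates.

    Entry (i, j) is the estimated probability that the algorithm predicts
    cause j for a death whose reference cause is i. ``row_counts`` records
    how many paired deaths informed each row; rows with zero paired deaths
    are filled with the uniform distribution and carry ``row_counts == 0``
    so downstream consumers can treat them as uninformed.
    """

    causes: CauseList
    M: np.ndarray
    row_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        C = self.causes.C
        if M.shape != (C, C):
            raise ValueError(f"M has shape {M.shape}, expected ({C}, {C})")
        if np.any(M < -_SIMPLEX_TOL) or np.any(M > 1 + _SIMPLEX_TOL):
            raise ValueError("misclassification rates outside [0, 1]")
        rc = self.row_counts
        rc = np.zeros(C, dtype=int) + 1 if rc is None else np.asarray(rc, dtype=int)
        if rc.shape != (C,) or np.any(rc < 0):
            raise ValueError("row_counts must be C non-negative integers")
        bad = (rc > 0) & (np.abs(M.sum(axis=1) - 1.0) > _SIMPLEX_TOL)
        if np.any(bad):
            raise ValueError(f"rows {np.flatnonzero(bad)} do not sum to 1")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "row_counts", rc)

    @property
    def sensitivities(self) -> np.ndarray:
        return np.diag(self.M).copy()


def raw_csmf(predictions: Sequence[str], causes: CauseList) -> CSMF:
    """Raw (uncalibrated) CSMF: the fraction of records predicted as each cause.

    For cause j this is (number of records predicted j) / (total records).
    """
    if len(predictions) == 0:
        raise ValueError("cannot compute a raw CSMF from an empty prediction list")
    counts = np.zeros(causes.C, dtype=int)
    for idx in causes.indices(predictions):
        counts[idx] += 1
    return CSMF(causes, counts / counts.sum(), counts=counts)


def raw_csmf_from_counts(counts: Sequence[int], causes: CauseList) -> CSMF:
    """Raw CSMF from per-cause predicted counts in canonical order."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (causes.C,) or counts.sum() <= 0:
        raise ValueError("counts must be C non-negative integers with positive sum")
    return CSMF(causes, counts / counts.sum(), counts=counts)


def estimate_misclassification(
    paired: PairedDataset, algorithm: str
) -> MisclassificationMatrix:
    """Empirical misclassification matrix of one algorithm from paired data.

    Row i is the empirical distribution of the algorithm's predictions among
    paired deaths with reference cause i. Records with a missing prediction
    for this algorithm are ignored. Reference causes with no usable record
    get a uniform row, flagged via ``row_counts = 0``.
    """
    if algorithm not in paired.algorithms:
        raise ValueError(
            f"algorithm {algorithm!r} not in dataset (has {list(paired.algorithms)})"
        )
    C = paired.causes.C
    counts = np.zeros((C, C), dtype=int)
    n_used = 0
    for ref, pred in zip(paired.reference_cause, paired.predictions[algorithm]):
        if pred is None:
            continue
        counts[paired.causes.index(ref), paired.causes.index(pred)] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no paired record has a conclusive {algorithm!r} prediction"
        )
    row_counts = counts.sum(axis=1)
    M = np.full((C, C), 1.0 / C)
    nz = row_counts > 0
    M[nz] = counts[nz] / row_counts[nz, None]
    return MisclassificationMatrix(paired.causes, M, row_counts)


def _check_shared_causes(a: CauseList, b: CauseList) -> None:
    if a.labels != b.labels:
        raise ValueError(
            f"cause lists differ: {list(a.labels)} vs {list(b.labels)}"
        )


def forward_marginal(p: CSMF, M: MisclassificationMatrix) -> CSMF:
    """Predicted-cause marginal q with q_j = sum_i p_i * M_ij.

    This is the distribution of algorithm predictions implied by true CSMF
    ``p`` under misclassification ``M``; for row-stochastic M it maps the
    simplex to itself.
    """
    _check_shared_causes(p.causes, M.causes)
    q = M.M.T @ p.p
    return CSMF(p.causes, q / q.sum())


class BacksolveResult(NamedTuple):
    """Back-solved CSMF with feasibility flag (p unclipped when infeasible)."""

    p: np.ndarray
    feasible: bool
    causes: CauseList

    def to_csmf(self) -> CSMF:
        if not self.feasible:
            raise ValueError(
                "back-solved CSMF is infeasible (entries outside [0, 1]); "
                "use the Bayesian calibration instead"
            )
        return CSMF(self.causes, np.clip(self.p, 0.0, 1.0) / np.clip(self.p, 0.0, 1.0).sum())


def backsolve_csmf(
    q: CSMF, M: MisclassificationMatrix, cond_bound: float = 1e8
) -> BacksolveResult:
    """Deterministically calibrate a raw CSMF by solving q = M' p for p.

    This is the direct linear-algebra calibration. With more than two causes
    it can produce entries outside [0, 1]; such solutions are returned
    unclipped with ``feasible=False`` — the failure mode that motivates the
    Bayesian model.
    """
    _check_shared_causes(q.causes, M.causes)
    A = M.M.T
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_bound:
        raise np.linalg.LinAlgError(
            f"misclassification matrix is ill-conditioned (cond={cond:.3g} > "
            f"{cond_bound:.3g}); the linear back-solve is unreliable — use the "
            "Bayesian calibration"
        )
    p = np.linalg.solve(A, q.p)
    feasible = bool(np.all(p >= -_SIMPLEX_TOL) and np.all(p <= 1 + _SIMPLEX_TOL))
    return BacksolveResult(p=p, feasible=feasible, causes=q.causes)


def ensemble_uncalibrated(csmfs: Sequence[CSMF]) -> CSMF:
    """Equally weighted average of per-algorithm raw CSMFs."""
    if len(csmfs) == 0:
        raise ValueError("need at least one CSMF")
    causes = csmfs[0].causes
    for c in csmfs[1:]:
        _check_shared_causes(causes, c.causes)
    p = np.mean([c.p for c in csmfs], axis=0)
    return CSMF(causes, p / p.sum())


def write_csmf(csmf: CSMF, path: str | Path) -> None:
    """Write a CSMF as CSV: cause, estimate[, count]."""
    df = pd.DataFrame({"cause": csmf.causes.labels, "estimate": csmf.p})
    if csmf.counts is not None:
        df["count"] = csmf.counts
    df.to_csv(path, index=False)


def write_misclassification(m: MisclassificationMatrix, path: str | Path) -> None:
    """Write a misclassification matrix as CSV: reference_cause, per-cause columns, row_count."""
    df = pd.DataFrame(m.M, columns=list(m.causes.labels))
    df.insert(0, "reference_cause", list(m.causes.labels))
    df["row_count"] = m.row_counts
    df.to_csv(path, index=False)
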
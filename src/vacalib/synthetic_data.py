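"""Synthetic survey-style (unpaired) and reference-standard (paired) data.

The generator emulates the two data sources of a national VA calibration
study: a large community VA dataset whose deaths carry only CCVA-predicted
causes, and a small hospital-based reference dataset pairing each death's
predicted causes with a reference cause determined from comprehensive
postmortem information. Ground truth (the true CSMF, each algorithm's
misclassification matrix, and every latent true cause) is known, so every
pipeline stage is testable end-to-end.

Unpaired deaths are drawn generatively: a true cause from ``p_true``, then
per-algorithm predictions from the matching misclassification row,
independently across algorithms (optionally with a shared-confusion
correlation), then masked as inconclusive at a configurable rate. Paired
data use fixed per-reference-cause record counts rather than sampling the
reference composition — calibration depends only on the per-cause
misclassification rates, not on the reference deaths' cause mix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cause_space import CauseList, builtin_cause_list
from .datasets_io import (
    PairedDataset,
    UnpairedDataset,
    write_paired,
    write_unpaired,
)
from .point_estimators import CSMF, MisclassificationMatrix

__all__ = ["SyntheticScenario", "generate", "preset_scenarios", "write_scenario_outputs", "PRESET_NAMES"]

PRESET_NAMES = ("two_cause_worked_example", "child_like", "neonate_like")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of a synthetic calibration study.

    ``paired_per_cause`` gives the fixed number of reference-standard
    records per reference cause (length C). ``inconclusive_rate`` maps each
    algorithm to its probability of an inconclusive (missing) prediction.
    ``shared_confusion`` in [0, 1) is the per-death probability that all
    algorithms report one common draw from the average misclassification
    row, violating the calibration model's conditional-independence
    assumption (for robustness stress-tests; default off).
    """

    causes: CauseList
    p_true: CSMF
    M_true: Mapping[str, MisclassificationMatrix]
    n_unpaired: int
    paired_per_cause: np.ndarray
    inconclusive_rate: Mapping[str, float] = field(default_factory=dict)
    shared_confusion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_true.causes.labels != self.causes.labels:
            raise ValueError("p_true uses a different cause list")
        for name, m in self.M_true.items():
            if m.causes.labels != self.causes.labels:
                raise ValueError(f"M_true[{name!r}] uses a different cause list")
        ppc = np.asarray(self.paired_per_cause, dtype=int)
        if ppc.shape != (self.causes.C,) or np.any(ppc < 0):
            raise ValueError("paired_per_cause must be C non-negative integers")
        object.__setattr__(self, "paired_per_cause", ppc)
        if self.n_unpaired < 1:
            raise ValueError("n_unpaired must be positive")
        for alg, r in self.inconclusive_rate.items():
            if not 0 <= r < 1:
                raise ValueError(f"inconclusive rate for {alg!r} outside [0, 1)")
        if not 0 <= self.shared_confusion < 1:
            raise ValueError("shared_confusion must be in [0, 1)")

    @property
    def algorithms(self) -> tuple[str, ...]:
        return tuple(self.M_true.keys())


def _draw_predictions(
    rng: np.random.Generator,
    z: np.ndarray,
    scenario: SyntheticScenario,
) -> np.ndarray:
    """Per-algorithm predicted-cause codes for deaths with true causes ``z``."""
    algs = scenario.algorithms
    n, K, C = len(z), len(algs), scenario.causes.C
    rows = np.stack([scenario.M_true[a].M for a in algs])  # (K, C, C)
    cum = rows.cumsum(axis=2)
    out = np.empty((n, K), dtype=np.int64)
    u = rng.random((n, K))
    for k in range(K):
        # inverse-CDF draw; clip guards the float edge where a row's
        # cumulative sum falls a ulp short of 1
        out[:, k] = np.clip((u[:, k : k + 1] >= cum[k][z]).sum(axis=1), 0, C - 1)
    if scenario.shared_confusion > 0 and K > 1:
        shared = rng.random(n) < scenario.shared_confusion
        if shared.any():
            avg = rows.mean(axis=0)  # average misclassification row
            cum_avg = avg.cumsum(axis=1)
            a_shared = (rng.random((shared.sum(), 1)) >= cum_avg[z[shared]]).sum(axis=1)
            out[shared] = a_shared[:, None]
    return out


def generate(
    scenario: SyntheticScenario,
) -> tuple[UnpairedDataset, PairedDataset, pd.DataFrame]:
    """Generate one synthetic study; returns (unpaired, paired, truth).

    The truth table records the latent true cause of every unpaired death
    (columns death_id, true_cause). Same seed, same scenario: byte-identical
    output.
    """
    rng = np.random.default_rng(scenario.seed)
    causes = scenario.causes
    labels = np.array(causes.labels, dtype=object)
    algs = scenario.algorithms

    # unpaired survey data
    z = rng.choice(causes.C, size=scenario.n_unpaired, p=scenario.p_true.p)
    preds = _draw_predictions(rng, z, scenario)
    pred_labels: dict[str, list] = {}
    for k, alg in enumerate(algs):
        col = labels[preds[:, k]].tolist()
        rate = scenario.inconclusive_rate.get(alg, 0.0)
        if rate > 0:
            mask = rng.random(scenario.n_unpaired) < rate
            col = [None if m else v for v, m in zip(col, mask)]
        pred_labels[alg] = col
    ids = tuple(f"u{i:06d}" for i in range(scenario.n_unpaired))
    unpaired = UnpairedDataset(
        death_id=ids,
        predictions=pd.DataFrame(pred_labels, columns=list(algs)),
        algorithms=algs,
        causes=causes,
    )
    truth = pd.DataFrame({"death_id": list(ids), "true_cause": labels[z]})

    # paired reference-standard data: fixed counts per reference cause
    ref = np.repeat(np.arange(causes.C), scenario.paired_per_cause)
    preds_p = _draw_predictions(rng, ref, scenario)
    pred_labels_p: dict[str, list] = {}
    for k, alg in enumerate(algs):
        col = labels[preds_p[:, k]].tolist()
        rate = scenario.inconclusive_rate.get(alg, 0.0)
        if rate > 0:
            mask = rng.random(len(ref)) < rate
            col = [None if m else v for v, m in zip(col, mask)]
        pred_labels_p[alg] = col
    paired = PairedDataset(
        death_id=tuple(f"p{i:05d}" for i in range(len(ref))),
        reference_cause=tuple(labels[ref]),
        predictions=pd.DataFrame(pred_labels_p, columns=list(algs)),
        algorithms=algs,
        causes=causes,
    )
    return unpaired, paired, truth


def _matrix(causes: CauseList, rows: list[list[float]]) -> MisclassificationMatrix:
    return MisclassificationMatrix(causes, np.array(rows), np.ones(causes.C, dtype=int))


def _child_like() -> SyntheticScenario:
    causes = builtin_cause_list("child")
    # order: pneumonia, malaria, diarrhea, severe malnutrition, hiv,
    #        other infections, other
    p_true = CSMF(causes, np.array([0.08, 0.27, 0.19, 0.04, 0.03, 0.36, 0.03]))
    # low-to-moderate sensitivities (~0.1-0.6), heavy leakage between the
    # big infectious categories, as reference-vs-CCVA comparisons show
    m_a = [
        [0.55, 0.05, 0.20, 0.02, 0.03, 0.10, 0.05],
        [0.23, 0.44, 0.10, 0.02, 0.02, 0.15, 0.04],
        [0.10, 0.05, 0.60, 0.05, 0.03, 0.12, 0.05],
        [0.15, 0.10, 0.20, 0.10, 0.10, 0.25, 0.10],
        [0.10, 0.05, 0.15, 0.10, 0.40, 0.15, 0.05],
        [0.25, 0.10, 0.10, 0.03, 0.04, 0.40, 0.08],
        [0.10, 0.08, 0.10, 0.04, 0.04, 0.24, 0.40],
    ]
    m_b = [
        [0.45, 0.03, 0.15, 0.05, 0.15, 0.12, 0.05],
        [0.20, 0.30, 0.12, 0.04, 0.05, 0.25, 0.04],
        [0.12, 0.04, 0.50, 0.08, 0.06, 0.15, 0.05],
        [0.10, 0.05, 0.15, 0.12, 0.15, 0.28, 0.15],
        [0.08, 0.03, 0.10, 0.06, 0.60, 0.08, 0.05],
        [0.28, 0.06, 0.08, 0.04, 0.06, 0.42, 0.06],
        [0.12, 0.06, 0.08, 0.05, 0.05, 0.20, 0.44],
    ]
    return SyntheticScenario(
        causes=causes,
        p_true=p_true,
        M_true={"insilicova": _matrix(causes, m_a), "eava": _matrix(causes, m_b)},
        n_unpaired=1589,
        paired_per_cause=np.full(7, 56),
        seed=20230410,
    )


def _neonate_like() -> SyntheticScenario:
    causes = builtin_cause_list("neonate")
    # order: congenital malformation, infection, ipre, prematurity, other
    p_true = CSMF(causes, np.array([0.04, 0.62, 0.22, 0.08, 0.04]))
    # prematurity over-diagnosed by both algorithms; one algorithm confuses
    # ipre with infection heavily
    m_a = [
        [0.25, 0.20, 0.15, 0.30, 0.10],
        [0.02, 0.50, 0.15, 0.28, 0.05],
        [0.03, 0.20, 0.50, 0.22, 0.05],
        [0.02, 0.08, 0.03, 0.85, 0.02],
        [0.05, 0.25, 0.20, 0.30, 0.20],
    ]
    m_b = [
        [0.30, 0.25, 0.10, 0.25, 0.10],
        [0.03, 0.55, 0.12, 0.25, 0.05],
        [0.02, 0.52, 0.30, 0.13, 0.03],
        [0.03, 0.25, 0.05, 0.63, 0.04],
        [0.06, 0.30, 0.14, 0.30, 0.20],
    ]
    return SyntheticScenario(
        causes=causes,
        p_true=p_true,
        M_true={"insilicova": _matrix(causes, m_a), "eava": _matrix(causes, m_b)},
        n_unpaired=632,
        paired_per_cause=np.full(5, 90),
        seed=20230411,
    )


def _two_cause() -> SyntheticScenario:
    causes = CauseList(("cause_a", "cause_b"))
    p_true = CSMF(causes, np.array([0.30, 0.70]))
    M = _matrix(causes, [[0.95, 0.05], [0.35, 0.65]])
    return SyntheticScenario(
        causes=causes,
        p_true=p_true,
        M_true={"ccva": M},
        n_unpaired=20_000,
        paired_per_cause=np.array([2000, 2000]),
        seed=20230412,
    )


def preset_scenarios(name: str) -> SyntheticScenario:
    """Named study-like scenarios with fixed default seeds.

    ``child_like``: 7 broad causes, 1,589 survey deaths, two algorithms with
    low-to-moderate sensitivities, 56 reference records per cause.
    ``neonate_like``: 5 broad causes, 632 survey deaths, 90 reference
    records per cause. ``two_cause_worked_example``: the two-cause textbook
    case with sensitivities (0.95, 0.65) and true CSMF (0.30, 0.70) at
    large n.
    """
    presets = {
        "two_cause_worked_example": _two_cause,
        "child_like": _child_like,
        "neonate_like": _neonate_like,
    }
    key = name.strip().casefold()
    if key not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {list(PRESET_NAMES)}")
    return presets[key]()


def write_scenario_outputs(
    unpaired: UnpairedDataset,
    paired: PairedDataset,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write unpaired.csv, paired.csv and truth.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "unpaired": outdir / "unpaired.csv",
        "paired": outdir / "paired.csv",
        "truth": outdir / "truth.csv",
    }
    write_unpaired(unpaired, paths["unpaired"])
    write_paired(paired, paths["paired"])
    truth.to_csv(paths["truth"], index=False)
    return paths
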
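"""WAIC model comparison for calibrated versus uncalibrated CSMF models.

WAIC estimates out-of-sample predictive accuracy from within-sample draws:
``waic = -2 * (lppd - p_waic)`` where ``lppd`` is the log pointwise
predictive density summed over records and ``p_waic`` the sum of per-record
posterior variances of the log density (the effective parameter count).
Lower is better. Both data sources contribute records: each unpaired death
enters through its marginal likelihood under (p, M) and each paired death
through its prediction likelihood given the observed reference cause.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bayes_calibration import CalibrationConfig, CSMFPosterior, run_calibration
from .datasets_io import PairedDataset, UnpairedDataset
from .point_estimators import ensemble_uncalibrated, raw_csmf

__all__ = [
    "WAICResult",
    "compute_waic",
    "pointwise_logdensity",
    "compare_calibrated_uncalibrated",
]


@dataclass(frozen=True)
class WAICResult:
    """Widely applicable information criterion summary for one model."""

    lppd: float
    p_waic: float
    waic: float
    n_records: int


def compute_waic(pointwise_logdens: np.ndarray) -> WAICResult:
    """WAIC from an (S draws x n records) matrix of log pointwise densities.

    ``lppd = sum_d log mean_s exp(logdens[s, d])`` (stable log-sum-exp) and
    ``p_waic = sum_d var_s logdens[s, d]`` (sample variance, ddof=1).
    """
    ld = np.asarray(pointwise_logdens, dtype=float)
    if ld.ndim != 2 or ld.shape[0] < 2:
        raise ValueError("need an (S >= 2, n_records) array of log densities")
    finite = np.isfinite(ld)
    if not finite.all():
        bad = np.flatnonzero(~finite.all(axis=0))
        raise ValueError(f"non-finite log densities for record(s) {bad.tolist()[:10]}")
    S = ld.shape[0]
    lppd = float(np.sum(logsumexp(ld, axis=0) - np.log(S)))
    p_waic = float(np.sum(ld.var(axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return WAICResult(lppd=lppd, p_waic=p_waic, waic=waic, n_records=ld.shape[1])


def _encode_col(ds, alg):
    col = ds.predictions[alg]
    if any(v is None for v in col):
        raise ValueError(
            f"{alg!r} has missing predictions; run complete_case_filter first"
        )
    return np.array(ds.causes.indices(col), dtype=np.int64)


def _pointwise_from_draws(
    p_draws: np.ndarray,  # (S, C) or None when p is fixed
    M_draws: np.ndarray,  # (S, K, C, C)
    unpaired: UnpairedDataset,
    paired: PairedDataset,
    algorithms: Sequence[str],
    p_fixed: np.ndarray | None = None,
) -> np.ndarray:
    S, K = M_draws.shape[0], M_draws.shape[1]
    A = np.column_stack([_encode_col(unpaired, a) for a in algorithms])
    B = np.array(paired.causes.indices(paired.reference_cause), dtype=np.int64)
    P = np.column_stack([_encode_col(paired, a) for a in algorithms])
    out = np.empty((S, A.shape[0] + B.shape[0]))

    # unpaired: log sum_i p_i prod_k M^k[i, a_dk]; grouped by unique pattern
    patterns, inverse = np.unique(A, axis=0, return_inverse=True)
    for u, pat in enumerate(patterns):
        like = np.ones((S, M_draws.shape[2]))
        for k in range(K):
            like *= M_draws[:, k, :, pat[k]]
        p = p_draws if p_fixed is None else p_fixed[None, :]
        dens = (like * p).sum(axis=1)
        out[:, np.flatnonzero(inverse == u)] = np.log(dens)[:, None]

    # paired: log prod_k M^k[b_m, a_mk]
    m0 = A.shape[0]
    ld = np.zeros((S, B.shape[0]))
    for k in range(K):
        ld += np.log(M_draws[:, k, B, P[:, k]])
    out[:, m0:] = ld
    return out


def pointwise_logdensity(
    fit: CSMFPosterior,
    unpaired: UnpairedDataset,
    paired: PairedDataset,
) -> np.ndarray:
    """Per-draw log density of every record under a calibration fit.

    Returns (S, n_unpaired + n_paired), unpaired records first, aligned by
    iteration with the fit's pooled draws. Also attaches the result to
    ``fit.pointwise_logdens``.
    """
    if fit.M_draws is None:
        raise ValueError("fit carries no misclassification draws")
    ld = _pointwise_from_draws(
        fit.draws, fit.M_draws, unpaired, paired, fit.algorithms
    )
    fit.pointwise_logdens = ld
    return ld


def _sample_M_conjugate(
    paired: PairedDataset,
    algorithms: Sequence[str],
    config: CalibrationConfig,
    S: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws of M from Dirichlet(prior + paired cross-tab), no latent data."""
    C = paired.causes.C
    B = np.array(paired.causes.indices(paired.reference_cause), dtype=np.int64)
    K = len(algorithms)
    conc = np.full((K, C, C), config.M_prior_offdiag)
    for k in range(K):
        np.fill_diagonal(conc[k], config.M_prior_diag)
        np.add.at(conc[k], (B, _encode_col(paired, algorithms[k])), 1.0)
    G = rng.standard_gamma(np.broadcast_to(conc, (S, K, C, C)))
    return G / G.sum(axis=3, keepdims=True)


def compare_calibrated_uncalibrated(
    unpaired: UnpairedDataset,
    paired: PairedDataset,
    config: CalibrationConfig,
    algorithms: Sequence[str] | None = None,
    comparator: str = "fixed_p",
) -> pd.DataFrame:
    """Fit the calibrated model and an uncalibrated comparator; report WAICs.

    The calibrated arm is the full joint model. The default uncalibrated
    comparator (``"fixed_p"``) fixes the CSMF at the raw point estimate (the
    equally weighted average across algorithms for ensembles) while M is
    still drawn from its conjugate posterior given the prior and the paired
    cross-tab. The alternative ``"fixed_marginal"`` comparator instead
    models each unpaired prediction directly by its algorithm's raw
    predicted-cause distribution.

    Returns a table with one row per model: model, waic, lppd, p_waic,
    delta_waic (relative to the best model).
    """
    if comparator not in ("fixed_p", "fixed_marginal"):
        raise ValueError("comparator must be 'fixed_p' or 'fixed_marginal'")
    algs = tuple(algorithms) if algorithms is not None else unpaired.algorithms

    fit = run_calibration(unpaired, paired, config, algorithms=algs)
    ld_cal = pointwise_logdensity(fit, unpaired, paired)
    waic_cal = compute_waic(ld_cal)

    S = fit.draws.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    M_unc = _sample_M_conjugate(paired, algs, config, S, rng)

    raws = [raw_csmf(list(unpaired.predictions[a]), unpaired.causes) for a in algs]
    if comparator == "fixed_p":
        p_fix = ensemble_uncalibrated(raws).p
        ld_unc = _pointwise_from_draws(
            None, M_unc, unpaired, paired, algs, p_fixed=p_fix
        )
    else:
        # unpaired records modelled by the raw per-algorithm marginals
        A = np.column_stack([_encode_col(unpaired, a) for a in algs])
        ld_marg = np.zeros(A.shape[0])
        for k, r in enumerate(raws):
            ld_marg += np.log(r.p[A[:, k]])
        B = np.array(paired.causes.indices(paired.reference_cause), dtype=np.int64)
        P = np.column_stack([_encode_col(paired, a) for a in algs])
        ld_pair = np.zeros((S, B.shape[0]))
        for k in range(len(algs)):
            ld_pair += np.log(M_unc[:, k, B, P[:, k]])
        ld_unc = np.concatenate(
            [np.broadcast_to(ld_marg, (S, A.shape[0])), ld_pair], axis=1
        )
    waic_unc = compute_waic(ld_unc)

    rows = [
        ("calibrated", waic_cal),
        ("uncalibrated", waic_unc),
    ]
    best = min(w.waic for _, w in rows)
    return pd.DataFrame(
        [
            {
                "model": name,
                "waic": w.waic,
                "lppd": w.lppd,
                "p_waic": w.p_waic,
                "n_records": w.n_records,
                "delta_waic": w.waic - best,
            }
            for name, w in rows
        ]
    )
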
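"""Bayesian joint calibration of CSMFs and misclassification matrices.

The model. Each unpaired death d carries a latent true cause
``z_d ~ Categorical(p)`` where ``p`` is the calibrated CSMF; algorithm k's
observed prediction is ``a_dk | z_d = i ~ Categorical(M^(k) row i)``,
conditionally independent across algorithms given the true cause. Each
paired death m has an observed reference cause ``b_m``, and its predictions
follow the same per-algorithm misclassification rows. Priors are conjugate:
``p ~ Dirichlet(p_prior)`` and each row i of ``M^(k)`` Dirichlet with a
larger concentration on the diagonal entry, shrinking sparse rows toward
"the algorithm is right".

Inference is a data-augmented Gibbs sampler. All full conditionals are
closed-form: the latent causes are categorical, and ``p`` and every
misclassification row are Dirichlet given the latent/observed cross-tabs.
Unpaired records with identical prediction vectors share a conditional, so
the z-update is blocked over unique prediction patterns and drawn with one
vectorised multinomial — the per-iteration cost is independent of the number
of deaths.

With one algorithm this is single-algorithm calibration; with several it is
the ensemble, which shares one ``p`` across algorithms and thereby weights
the more accurate algorithms' evidence more heavily.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cause_space import CauseList
from .datasets_io import PairedDataset, UnpairedDataset

__all__ = [
    "CalibrationConfig",
    "CSMFPosterior",
    "run_calibration",
    "summarize_posterior",
    "convergence_diagnostics",
    "split_rhat",
    "draws_to_frame",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """MCMC and prior settings for the calibration model.

    Parameters
    ----------
    seed
        Base seed; per-chain streams are spawned from it deterministically.
    n_chains, n_iter, n_burnin
        Chains, iterations per chain, and discarded burn-in iterations.
    p_prior
        Dirichlet concentration vector for the CSMF (default: all ones).
    M_prior_diag, M_prior_offdiag
        Dirichlet concentrations for each misclassification row: the
        diagonal entry gets ``M_prior_diag``, off-diagonals
        ``M_prior_offdiag``. The default (5, 0.5) shrinks rows with few
        paired deaths toward the identity; set both to 1 for a flat prior.
    credible_level
        Equal-tailed credible-interval level, in (0, 1).
    """

    seed: int
    n_chains: int = 4
    n_iter: int = 10_000
    n_burnin: int = 5_000
    p_prior: np.ndarray | None = None
    M_prior_diag: float = 5.0
    M_prior_offdiag: float = 0.5
    credible_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1:
            raise ValueError("n_chains and n_iter must be positive")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must be in (0, 1)")
        if self.M_prior_diag <= 0 or self.M_prior_offdiag <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.p_prior is not None:
            pp = np.asarray(self.p_prior, dtype=float)
            if np.any(pp <= 0):
                raise ValueError("p_prior concentrations must be positive")
            object.__setattr__(self, "p_prior", pp)


@dataclass
class CSMFPosterior:
    """Posterior draws of the calibrated CSMF and misclassification matrices.

    ``chain_p`` has shape (n_chains, n_kept, C); ``chain_M`` has shape
    (n_chains, n_kept, K, C, C). Pooled views concatenate chains in order.
    ``pointwise_logdens`` (S x n_records, unpaired then paired) is attached
    when a WAIC computation requests it.
    """

    causes: CauseList
    algorithms: tuple[str, ...]
    chain_p: np.ndarray
    chain_M: np.ndarray | None = None
    config: CalibrationConfig | None = None
    pointwise_logdens: np.ndarray | None = None
    prior_driven_causes: tuple[str, ...] = ()
    _n_unpaired: int = 0
    _n_paired: int = 0

    @property
    def draws(self) -> np.ndarray:
        """All post-burn-in CSMF draws pooled across chains, (S, C)."""
        return self.chain_p.reshape(-1, self.chain_p.shape[-1])

    @property
    def M_draws(self) -> np.ndarray | None:
        """Pooled misclassification draws, (S, K, C, C)."""
        if self.chain_M is None:
            return None
        return self.chain_M.reshape(-1, *self.chain_M.shape[2:])

    @property
    def point(self) -> np.ndarray:
        """Posterior mean CSMF."""
        return self.draws.mean(axis=0)

    @property
    def interval(self) -> np.ndarray:
        """Equal-tailed credible bounds, (C, 2), at the configured level."""
        level = self.config.credible_level if self.config is not None else 0.95
        lo = (1 - level) / 2
        return np.quantile(self.draws, [lo, 1 - lo], axis=0).T


def _encode(
    unpaired: UnpairedDataset,
    paired: PairedDataset,
    algorithms: Sequence[str] | None,
):
    """Validate inputs and encode them as integer arrays / cross-tabs."""
    if unpaired.causes.labels != paired.causes.labels:
        raise ValueError(
            "unpaired and paired datasets use different cause lists: "
            f"{list(unpaired.causes.labels)} vs {list(paired.causes.labels)}"
        )
    algs = tuple(algorithms) if algorithms is not None else unpaired.algorithms
    for a in algs:
        if a not in unpaired.algorithms or a not in paired.algorithms:
            raise ValueError(f"algorithm {a!r} must be present in both datasets")
    causes = unpaired.causes
    C = causes.C

    def _codes(ds, alg):
        col = ds.predictions[alg]
        if any(v is None for v in col):
            raise ValueError(
                f"{alg!r} has missing predictions; run complete_case_filter first"
            )
        return np.array(causes.indices(col), dtype=np.int64)

    A = np.column_stack([_codes(unpaired, a) for a in algs])  # (n, K)
    B = np.array(causes.indices(paired.reference_cause), dtype=np.int64)
    P = np.column_stack([_codes(paired, a) for a in algs])  # (m, K)
    # per-algorithm paired cross-tabs T[k][i, j]
    T = np.zeros((len(algs), C, C), dtype=np.int64)
    for k in range(len(algs)):
        np.add.at(T[k], (B, P[:, k]), 1)
    return algs, causes, A, B, P, T


def run_calibration(
    unpaired: UnpairedDataset,
    paired: PairedDataset,
    config: CalibrationConfig,
    algorithms: Sequence[str] | None = None,
) -> CSMFPosterior:
    """Jointly estimate the calibrated CSMF and per-algorithm misclassification.

    Both datasets must share the cause list and contain every requested
    algorithm with no missing predictions (apply
    :func:`~vacalib.datasets_io.complete_case_filter` upstream). Returns the
    posterior over the CSMF ``p`` and each algorithm's matrix ``M``.
    """
    algs, causes, A, B, P, T = _encode(unpaired, paired, algorithms)
    C, K = causes.C, len(algs)
    n = A.shape[0]
    if n == 0:
        raise ValueError("unpaired dataset is empty")

    alpha_p = (
        np.ones(C) if config.p_prior is None else np.asarray(config.p_prior, float)
    )
    if alpha_p.shape != (C,):
        raise ValueError(f"p_prior must have length {C}")
    alpha_M = np.full((C, C), config.M_prior_offdiag)
    np.fill_diagonal(alpha_M, config.M_prior_diag)

    # causes with no evidence anywhere are recovered prior-driven
    seen = np.zeros(C, dtype=bool)
    seen[np.unique(A)] = True
    seen[np.unique(B)] = True
    seen[np.unique(P)] = True
    prior_driven = tuple(causes.labels[i] for i in np.flatnonzero(~seen))
    for lab in prior_driven:
        warnings.warn(
            f"cause {lab!r} has no evidence in either dataset; its posterior "
            "is driven by the prior",
            stacklevel=2,
        )

    # block the latent-cause update over unique prediction patterns
    patterns, pat_counts = np.unique(A, axis=0, return_counts=True)
    U = patterns.shape[0]

    n_kept = config.n_iter - config.n_burnin
    chain_p = np.empty((config.n_chains, n_kept, C))
    chain_M = np.empty((config.n_chains, n_kept, K, C, C))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    for c_idx, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        # warm start: latent causes at algorithm 1's prediction
        Z = np.zeros((U, C), dtype=np.int64)
        Z[np.arange(U), patterns[:, 0]] = pat_counts
        for it in range(config.n_iter):
            # p | z ~ Dirichlet(prior + latent-cause counts)
            p = rng.dirichlet(alpha_p + Z.sum(axis=0))
            # M^(k) row i | . ~ Dirichlet(prior + paired cross-tab + latent cross-tab)
            conc = alpha_M[None, :, :] + T.astype(float)
            for k in range(K):
                scatter = np.zeros((C, C))
                np.add.at(scatter, patterns[:, k], Z)  # rows = predicted cause
                conc[k] += scatter.T
            G = rng.standard_gamma(conc)  # (K, C, C)
            M = G / G.sum(axis=2, keepdims=True)
            # z | p, M, blocked by pattern: mass prop. to p_i * prod_k M^k[i, a_uk]
            like = np.ones((U, C))
            for k in range(K):
                like *= M[k][:, patterns[:, k]].T
            W = like * p
            W /= W.sum(axis=1, keepdims=True)
            Z = rng.multinomial(pat_counts, W)
            if it >= config.n_burnin:
                chain_p[c_idx, it - config.n_burnin] = p
                chain_M[c_idx, it - config.n_burnin] = M

    return CSMFPosterior(
        causes=causes,
        algorithms=algs,
        chain_p=chain_p,
        chain_M=chain_M,
        config=config,
        prior_driven_causes=prior_driven,
        _n_unpaired=n,
        _n_paired=B.shape[0],
    )


def summarize_posterior(
    posterior: CSMFPosterior, level: float | None = None
) -> pd.DataFrame:
    """Posterior mean and equal-tailed credible interval per cause."""
    if level is None:
        level = (
            posterior.config.credible_level if posterior.config is not None else 0.95
        )
    if not 0 < level < 1:
        raise ValueError(f"credible level must be in (0, 1), got {level}")
    draws = posterior.draws
    if draws.size == 0:
        raise ValueError("posterior has no draws")
    lo = (1 - level) / 2
    q = np.quantile(draws, [lo, 1 - lo], axis=0)
    return pd.DataFrame(
        {
            "cause": list(posterior.causes.labels),
            "mean": draws.mean(axis=0),
            "lower": q[0],
            "upper": q[1],
            "level": level,
        }
    )


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws). Each chain is split in half; the
    classic between/within variance ratio is returned. Degenerate cases:
    all half-chains constant and equal -> 1.0; constant but different ->
    infinity.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    half = chains.shape[1] // 2
    if half < 1:
        return float("nan")
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    nn = halves.shape[1]
    means = halves.mean(axis=1)
    W = float(halves.var(axis=1, ddof=1).mean()) if nn > 1 else 0.0
    B_over_n = float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    var_plus = (nn - 1) / nn * W + B_over_n
    return float(np.sqrt(var_plus / W))


def convergence_diagnostics(
    posterior: CSMFPosterior, rhat_warn: float = 1.01
) -> pd.DataFrame:
    """Per-cause split-R-hat and effective sample size for the CSMF draws.

    R-hat needs at least two chains; with a single chain it is reported as
    NaN with a notice. Coordinates with R-hat above ``rhat_warn`` trigger a
    non-convergence warning.
    """
    chain_p = posterior.chain_p
    n_chains = chain_p.shape[0]
    C = chain_p.shape[-1]
    if n_chains < 2:
        warnings.warn(
            "split-R-hat requires at least 2 chains; reporting NaN", stacklevel=2
        )
        rhats = [float("nan")] * C
    else:
        rhats = [split_rhat(chain_p[:, :, j]) for j in range(C)]
    try:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = az.ess(
                az.convert_to_dataset({"p": chain_p})
            )["p"].values.astype(float)
    except Exception:
        ess = np.full(C, np.nan)
    out = pd.DataFrame(
        {"cause": list(posterior.causes.labels), "rhat": rhats, "ess": ess}
    )
    bad = out[np.asarray(rhats) > rhat_warn]["cause"].tolist() if n_chains >= 2 else []
    if bad:
        warnings.warn(
            f"possible non-convergence (R-hat > {rhat_warn}) for causes: {bad}",
            stacklevel=2,
        )
    return out


def draws_to_frame(posterior: CSMFPosterior) -> pd.DataFrame:
    """CSMF draws in long format (chain, iteration, cause, value) for export."""
    n_chains, n_kept, C = posterior.chain_p.shape
    chain = np.repeat(np.arange(n_chains), n_kept * C)
    iteration = np.tile(np.repeat(np.arange(n_kept), C), n_chains)
    cause = np.tile(np.array(posterior.causes.labels), n_chains * n_kept)
    return pd.DataFrame(
        {
            "chain": chain,
            "iteration": iteration,
            "cause": cause,
            "value": posterior.chain_p.reshape(-1),
        }
    )
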
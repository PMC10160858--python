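"""Bayesian joint calibration: recovery, invariants, summaries, diagnostics."""
import numpy as np
import pandas as pd
import pytest

from vacalib import (
    CalibrationConfig,
    CauseList,
    CSMF,
    CSMFPosterior,
    MisclassificationMatrix,
    SyntheticScenario,
    convergence_diagnostics,
    generate,
    raw_csmf,
    run_calibration,
    summarize_posterior,
)
from vacalib.bayes_calibration import draws_to_frame, split_rhat
from conftest import make_paired, make_unpaired


def exact_two_cause_data():
    """Exact-count datasets matching the two-cause textbook scenario.

    Paired rows reproduce M = [[.95, .05], [.35, .65]] at 2,000 records per
    reference cause; unpaired predictions are exactly 53% / 47% of 20,000.
    """
    causes = CauseList(("cause_a", "cause_b"))
    ref = ["cause_a"] * 2000 + ["cause_b"] * 2000
    pred = ["cause_a"] * 1900 + ["cause_b"] * 100 + ["cause_a"] * 700 + ["cause_b"] * 1300
    paired = make_paired(ref, {"ccva": pred}, causes)
    upred = ["cause_a"] * 10600 + ["cause_b"] * 9400
    unpaired = make_unpaired({"ccva": upred}, causes)
    return causes, unpaired, paired


class TestRunCalibration:
    def test_two_cause_large_n_recovers_truth(self):
        _, unpaired, paired = exact_two_cause_data()
        cfg = CalibrationConfig(seed=7, n_chains=2, n_iter=2500, n_burnin=1000)
        fit = run_calibration(unpaired, paired, cfg)
        np.testing.assert_allclose(fit.point, [0.30, 0.70], atol=0.02)

    def test_identity_misclassification_leaves_raw_csmf(self, three_causes):
        # predictions equal the reference for every paired death
        ref = ["alpha"] * 200 + ["beta"] * 200 + ["gamma"] * 200
        paired = make_paired(ref, {"ccva": list(ref)}, three_causes)
        upred = ["alpha"] * 250 + ["beta"] * 150 + ["gamma"] * 100
        unpaired = make_unpaired({"ccva": upred}, three_causes)
        cfg = CalibrationConfig(seed=11, n_chains=2, n_iter=2000, n_burnin=800)
        fit = run_calibration(unpaired, paired, cfg)
        raw = raw_csmf(upred, three_causes)
        np.testing.assert_allclose(fit.point, raw.p, atol=0.02)

    def test_draws_stay_on_simplices(self):
        _, unpaired, paired = exact_two_cause_data()
        cfg = CalibrationConfig(seed=5, n_chains=1, n_iter=300, n_burnin=100)
        fit = run_calibration(unpaired, paired, cfg)
        p = fit.draws
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1, atol=1e-9)
        M = fit.M_draws
        assert np.all(M >= 0) and np.allclose(M.sum(axis=3), 1, atol=1e-9)

    def test_same_seed_reproduces_draws_exactly(self):
        _, unpaired, paired = exact_two_cause_data()
        cfg = CalibrationConfig(seed=42, n_chains=2, n_iter=300, n_burnin=100)
        a = run_calibration(unpaired, paired, cfg)
        b = run_calibration(unpaired, paired, cfg)
        np.testing.assert_array_equal(a.chain_p, b.chain_p)
        np.testing.assert_array_equal(a.chain_M, b.chain_M)

    def test_large_data_consistency_error_shrinks(self):
        # same truth at two nested sizes: posterior-mean L1 error decreases
        causes = CauseList(("x", "y", "z"))
        p_true = CSMF(causes, np.array([0.5, 0.3, 0.2]))
        M = MisclassificationMatrix(
            causes,
            np.array([[0.6, 0.25, 0.15], [0.2, 0.65, 0.15], [0.15, 0.25, 0.6]]),
        )
        errors = []
        for n_unpaired, per_cause, seed in [(300, 20, 21), (6000, 400, 22)]:
            scenario = SyntheticScenario(
                causes=causes,
                p_true=p_true,
                M_true={"ccva": M},
                n_unpaired=n_unpaired,
                paired_per_cause=np.full(3, per_cause),
                seed=seed,
            )
            unpaired, paired, _ = generate(scenario)
            cfg = CalibrationConfig(seed=seed, n_chains=1, n_iter=2500, n_burnin=1000)
            fit = run_calibration(unpaired, paired, cfg)
            errors.append(np.abs(fit.point - p_true.p).sum())
        assert errors[1] < errors[0]

    def test_ensemble_beats_poor_single_algorithm(self):
        # algorithm "good" is near-perfect, "noisy" near-uniform: the joint
        # fit with both must land closer to the truth than "noisy" alone
        causes = CauseList(("x", "y", "z"))
        p_true = CSMF(causes, np.array([0.5, 0.3, 0.2]))
        M_good = MisclassificationMatrix(
            causes, 0.9 * np.eye(3) + 0.1 / 3 * np.ones((3, 3))
        )
        M_noisy = MisclassificationMatrix(
            causes, 0.1 * np.eye(3) + 0.9 / 3 * np.ones((3, 3))
        )
        scenario = SyntheticScenario(
            causes=causes,
            p_true=p_true,
            M_true={"good": M_good, "noisy": M_noisy},
            n_unpaired=1200,
            paired_per_cause=np.full(3, 120),
            seed=31,
        )
        unpaired, paired, _ = generate(scenario)
        cfg = CalibrationConfig(seed=31, n_chains=1, n_iter=2500, n_burnin=1000)
        both = run_calibration(unpaired, paired, cfg, algorithms=["good", "noisy"])
        noisy_only = run_calibration(unpaired, paired, cfg, algorithms=["noisy"])
        err_both = np.abs(both.point - p_true.p).sum()
        err_noisy = np.abs(noisy_only.point - p_true.p).sum()
        assert err_both < err_noisy

    def test_mismatched_cause_lists_rejected(self, two_causes, three_causes):
        unpaired = make_unpaired({"ccva": ["cause_a"]}, two_causes)
        paired = make_paired(["alpha"], {"ccva": ["alpha"]}, three_causes)
        with pytest.raises(ValueError, match="different cause lists"):
            run_calibration(
                unpaired, paired, CalibrationConfig(seed=0, n_chains=1, n_iter=10, n_burnin=1)
            )

    def test_missing_predictions_rejected(self, two_causes):
        unpaired = make_unpaired({"ccva": ["cause_a", None]}, two_causes)
        paired = make_paired(["cause_a"], {"ccva": ["cause_a"]}, two_causes)
        with pytest.raises(ValueError, match="complete_case_filter"):
            run_calibration(
                unpaired, paired, CalibrationConfig(seed=0, n_chains=1, n_iter=10, n_burnin=1)
            )

    def test_zero_evidence_cause_warns(self, three_causes):
        unpaired = make_unpaired({"ccva": ["alpha"] * 5 + ["beta"] * 5}, three_causes)
        paired = make_paired(
            ["alpha", "beta"], {"ccva": ["alpha", "beta"]}, three_causes
        )
        with pytest.warns(UserWarning, match="gamma"):
            fit = run_calibration(
                unpaired, paired,
                CalibrationConfig(seed=0, n_chains=1, n_iter=50, n_burnin=10),
            )
        assert fit.prior_driven_causes == ("gamma",)


class TestCalibrationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_burnin=10, n_iter=10),
            dict(credible_level=1.0),
            dict(M_prior_diag=0.0),
            dict(p_prior=np.array([1.0, 0.0])),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        base = dict(seed=0, n_chains=1, n_iter=10, n_burnin=2)
        base.update(kwargs)
        with pytest.raises(ValueError):
            CalibrationConfig(**base)


def posterior_from_draws(causes, draws, level=0.95):
    cfg = CalibrationConfig(seed=0, n_chains=1, n_iter=2, n_burnin=1, credible_level=level)
    return CSMFPosterior(
        causes=causes, algorithms=("ccva",), chain_p=draws[None, :, :], config=cfg
    )


class TestSummarizePosterior:
    def test_constant_draws_zero_width(self, two_causes):
        draws = np.tile([0.4, 0.6], (50, 1))
        table = summarize_posterior(posterior_from_draws(two_causes, draws))
        np.testing.assert_allclose(table["mean"], [0.4, 0.6])
        np.testing.assert_allclose(table["upper"] - table["lower"], 0.0)

    def test_flat_dirichlet_mean_matches_closed_form(self, two_causes, rng):
        # Dirichlet(1, 1) has mean (1/2, 1/2)
        draws = rng.dirichlet((1.0, 1.0), size=100_000)
        table = summarize_posterior(posterior_from_draws(two_causes, draws))
        np.testing.assert_allclose(table["mean"], [0.5, 0.5], atol=0.01)

    def test_interval_nesting_across_levels(self, two_causes, rng):
        draws = rng.dirichlet((2.0, 3.0), size=5000)
        post = posterior_from_draws(two_causes, draws)
        narrow = summarize_posterior(post, level=0.5)
        wide = summarize_posterior(post, level=0.95)
        assert (narrow["lower"] >= wide["lower"]).all()
        assert (narrow["upper"] <= wide["upper"]).all()

    def test_invalid_level_rejected(self, two_causes):
        draws = np.tile([0.4, 0.6], (10, 1))
        with pytest.raises(ValueError, match="level"):
            summarize_posterior(posterior_from_draws(two_causes, draws), level=1.5)


class TestConvergenceDiagnostics:
    def test_identical_constant_chains_give_one(self):
        chains = np.ones((2, 100))
        assert split_rhat(chains) == 1.0

    def test_chains_at_different_constants_diverge(self):
        chains = np.vstack([np.zeros(100), np.ones(100)])
        assert split_rhat(chains) > 10

    def test_independent_draws_converge_below_threshold(self, rng, two_causes):
        draws = rng.dirichlet((5.0, 5.0), size=(4, 5000))
        cfg = CalibrationConfig(seed=0, n_chains=4, n_iter=2, n_burnin=1)
        post = CSMFPosterior(
            causes=two_causes, algorithms=("ccva",), chain_p=draws, config=cfg
        )
        table = convergence_diagnostics(post)
        assert (table["rhat"] < 1.01).all()
        assert (table["ess"] > 1000).all()

    def test_single_chain_reports_nan_with_notice(self, two_causes, rng):
        draws = rng.dirichlet((5.0, 5.0), size=(1, 200))
        cfg = CalibrationConfig(seed=0, n_chains=1, n_iter=2, n_burnin=1)
        post = CSMFPosterior(
            causes=two_causes, algorithms=("ccva",), chain_p=draws, config=cfg
        )
        with pytest.warns(UserWarning, match="2 chains"):
            table = convergence_diagnostics(post)
        assert table["rhat"].isna().all()


def test_draws_export_long_format(two_causes, rng):
    draws = rng.dirichlet((2.0, 2.0), size=(2, 5))
    cfg = CalibrationConfig(seed=0, n_chains=2, n_iter=6, n_burnin=1)
    post = CSMFPosterior(
        causes=two_causes, algorithms=("ccva",), chain_p=draws, config=cfg
    )
    frame = draws_to_frame(post)
    assert list(frame.columns) == ["chain", "iteration", "cause", "value"]
    assert len(frame) == 2 * 5 * 2
    sub = frame[(frame.chain == 1) & (frame.iteration == 3)]
    np.testing.assert_allclose(sub["value"].to_numpy(), draws[1, 3])
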
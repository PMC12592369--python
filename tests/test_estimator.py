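"""Fitting machinery: EM updates, gradient steps, multi-restart fit, transfer."""

import numpy as np
import pytest

from dpmost.estimator import (
    DPMoSt,
    _gradients,
    default_hyperparams,
    fit,
    fit_new_subjects,
    gradient_step_tau,
    gradient_step_theta_sigma,
    initialize,
    update_pi,
    update_xi,
)
from dpmost.model import (
    Hyperparams,
    LongitudinalDataset,
    _forward,
    log_posterior,
)
from dpmost.simulate import SimulationConfig, generate_dataset

from .conftest import random_instance


def _hyper(**kw):
    kw.setdefault("beta_sigma", 2.0)
    kw.setdefault("beta_xi", 1.0)
    kw.setdefault("beta_tau", 0.01)
    return Hyperparams(**kw)


class TestDefaultHyperparams:
    def test_fifteen_percent_rule(self):
        h = default_hyperparams(50)
        assert h.beta_xi == pytest.approx(7.5)
        assert h.beta_sigma == pytest.approx(7.5)

    def test_beta_tau_from_forty_unit_sd(self):
        assert default_hyperparams(50).beta_tau == pytest.approx(3.125e-4)

    def test_admissibility_at_large_cohort(self):
        h = default_hyperparams(200)
        assert 0 < h.beta_xi < 200

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="beta_sigma"):
            default_hyperparams(5)

    def test_inadmissible_beta_xi_rejected(self):
        with pytest.raises(ValueError, match="admissibility"):
            default_hyperparams(50, beta_xi=60.0)


class TestInitialize:
    def test_uninformative_probabilities(self, rng):
        ds, _ = random_instance(rng, J=5, B=3, h=4)
        p = initialize(ds, _hyper(), rng)
        assert np.all(p.xi1 == 0.5)
        assert np.all(p.pi1 == 0.5)
        assert np.all(p.tau == 0.0)

    def test_sigma_matches_pooled_sd(self, rng):
        ds, _ = random_instance(rng, J=10, B=2, h=5)
        p = initialize(ds, _hyper(), rng)
        for b in range(2):
            pooled = np.concatenate([v[b] for v in ds.values])
            assert p.sigma[b] == pytest.approx(pooled.std())

    def test_positivity_and_determinism(self, rng):
        ds, _ = random_instance(rng, J=5, B=3, h=4)
        p1 = initialize(ds, _hyper(), np.random.default_rng(7))
        p2 = initialize(ds, _hyper(), np.random.default_rng(7))
        assert np.all(p1.growth_rate > 0) and np.all(p1.supremum > 0)
        np.testing.assert_array_equal(p1.midpoint, p2.midpoint)
        np.testing.assert_array_equal(p1.growth_rate, p2.growth_rate)

    def test_degenerate_biomarker_rejected(self, rng):
        ds = LongitudinalDataset(
            ["s1", "s2"],
            [np.array([0.0, 1.0])] * 2,
            [np.full((1, 2), 3.0)] * 2,
            ["flat"],
        )
        with pytest.raises(ValueError, match="distinct"):
            initialize(ds, _hyper(), rng)


class TestUpdateXi:
    def test_plain_em_limit(self, rng):
        # with beta_xi -> 0 the fixed point is R_b / J
        ds, p = random_instance(rng, J=8, B=2, h=3)
        h = _hyper(beta_xi=1e-12)
        fw = _forward(ds, p)
        R = fw["resp"][:, :, 0].sum(axis=0)
        np.testing.assert_allclose(update_xi(ds, p, h), R / 8, rtol=1e-9)

    def test_printed_fixed_point_value(self):
        # J=10, R=8, beta=2, xi=0.5 -> 8 / (10 - 1) = 0.8889
        xi_new = 8.0 / (10 + (0.5 - 1.0) * 2.0)
        assert xi_new == pytest.approx(0.888888888, rel=1e-6)

    def test_fixed_point_solution_in_unit_interval_when_admissible(self):
        # the stationary point of the penalized M-step objective solves
        # beta*xi^2 + (J - beta)*xi - R = 0; for 0 < beta < J and responsibility
        # mass R in [0, J] its positive root lies in [0, 1].  (A single
        # iterate of the update can overshoot 1, hence the clamp.)
        rng = np.random.default_rng(0)
        for trial in range(300):
            J = int(rng.integers(2, 30))
            beta = rng.uniform(1e-6, J - 1e-6)
            R = rng.uniform(0, J)
            root = (-(J - beta) + np.sqrt((J - beta) ** 2 + 4 * beta * R)) / (2 * beta)
            assert -1e-12 <= root <= 1 + 1e-12
            # and the root is indeed a fixed point of the printed update
            assert root == pytest.approx(R / (J + (root - 1) * beta), rel=1e-9)

    def test_inadmissible_beta_rejected(self, rng):
        ds, p = random_instance(rng, J=3, B=2, h=2)
        with pytest.raises(ValueError, match="admissibility"):
            update_xi(ds, p, _hyper(beta_xi=5.0))


class TestUpdatePi:
    def test_all_split_mass_on_branch1(self, rng):
        ds, p = random_instance(rng, J=4, B=2, h=3)
        p.xi1 = np.zeros(2)
        # branch 2 predicts absurd values everywhere -> its density vanishes
        p.midpoint[:, 2] = -100.0
        p.growth_rate[:, 2] = 1.0
        p.supremum[:, 2] = 1000.0
        pi_new = update_pi(ds, p)
        np.testing.assert_allclose(pi_new, 1.0, atol=1e-12)

    def test_identical_branches_from_symmetric_start(self, rng):
        ds, p = random_instance(rng, J=4, B=2, h=3)
        for arr in (p.midpoint, p.growth_rate, p.supremum):
            arr[:, 2] = arr[:, 1]
        p.pi1 = np.full(4, 0.5)
        np.testing.assert_allclose(update_pi(ds, p), 0.5, atol=1e-12)

    def test_normalization_arithmetic(self, rng):
        # independently computed from the responsibility normalization:
        # pi <- sum_b w1 / sum_b (w1 + w2)
        ds, p = random_instance(rng, J=3, B=2, h=2)
        fw = _forward(ds, p)
        w1 = fw["resp"][:, :, 1].sum(axis=1)
        w2 = fw["resp"][:, :, 2].sum(axis=1)
        np.testing.assert_allclose(update_pi(ds, p, fw), w1 / (w1 + w2), rtol=1e-9)

    def test_zero_denominator_keeps_current(self, rng):
        ds, p = random_instance(rng, J=4, B=2, h=3)
        p.xi1 = np.ones(2)  # no split mass anywhere
        np.testing.assert_allclose(update_pi(ds, p), p.pi1)


class TestGradients:
    @pytest.mark.parametrize("seed", range(3))
    def test_match_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        ds, p = random_instance(rng, J=4, B=2, h=3)
        h = _hyper()
        g = _gradients(ds, p, h)
        eps = 1e-6

        def fd(mutate):
            q1, q2 = p.copy(), p.copy()
            mutate(q1, +eps)
            mutate(q2, -eps)
            return (log_posterior(ds, q1, h) - log_posterior(ds, q2, h)) / (2 * eps)

        for name in ("midpoint", "growth_rate", "supremum"):
            for b in range(2):
                for c in range(3):
                    num = fd(lambda q, e: getattr(q, name).__setitem__((b, c), getattr(q, name)[b, c] + e))
                    assert g[name][b, c] == pytest.approx(num, rel=1e-5, abs=1e-6)
        for b in range(2):
            num = fd(lambda q, e: q.sigma.__setitem__(b, q.sigma[b] + e))
            assert g["sigma"][b] == pytest.approx(num, rel=1e-5, abs=1e-6)
        for j in range(4):
            num = fd(lambda q, e: q.tau.__setitem__(j, q.tau[j] + e))
            assert g["tau"][j] == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_tau_pinned_by_dominant_penalty(self, rng):
        # with the quadratic shift penalty dominating the likelihood, repeated
        # ascent steps drive tau (back) to essentially zero
        ds, p = random_instance(rng, J=4, B=2, h=3)
        p.tau = np.ones(4)
        h = _hyper(beta_tau=1e4, lambda_tau=1e-4)
        for _ in range(500):
            p.tau = gradient_step_tau(ds, p, h)
        np.testing.assert_allclose(p.tau, 0.0, atol=1e-3)

    def test_positivity_preserved(self, rng):
        ds, p = random_instance(rng, J=4, B=2, h=3)
        h = _hyper(lambda_theta=0.8, lambda_sigma=0.8)
        for _ in range(50):
            p = gradient_step_theta_sigma(ds, p, h)
        assert np.all(p.sigma > 0)
        assert np.all(p.growth_rate > 0)
        assert np.all(p.supremum > 0)

    def test_stationary_at_noise_free_optimum(self):
        # dense noise-free data generated from the parameter state itself:
        # the likelihood gradient vanishes at the generating parameters
        rng = np.random.default_rng(5)
        from dpmost.model import sigmoid_value, SigmoidParams

        truth = SigmoidParams(5.0, 0.8, 2.0)
        t = np.linspace(0, 10, 200)
        values = [sigmoid_value(t, truth)[None, :] for _ in range(3)]
        ds = LongitudinalDataset(["a", "b", "c"], [t] * 3, values, ["m"])
        p = initialize(ds, _hyper(), rng)
        for arr, v in (
            (p.midpoint, 5.0),
            (p.growth_rate, 0.8),
            (p.supremum, 2.0),
        ):
            arr[:] = v
        p.tau = np.zeros(3)
        g = _gradients(ds, p, Hyperparams(beta_sigma=2.0, beta_xi=1e-9, beta_tau=0.0))
        # theta gradients vanish; sigma keeps a prior term
        assert abs(g["midpoint"]).max() < 1e-6
        assert abs(g["growth_rate"]).max() < 1e-6
        assert abs(g["supremum"]).max() < 1e-6
        assert abs(g["tau"]).max() < 1e-6

    def test_tau_recovers_known_shift(self):
        # data generated with a known shift; repeated tau-only ascent from 0
        # moves the estimate toward the true shift
        from dpmost.model import ModelParamsM2, sigmoid_value, SigmoidParams

        truth = SigmoidParams(8.0, 0.7, 2.0)
        delta = 3.0
        t = np.linspace(0, 6, 12)
        ds = LongitudinalDataset(
            ["s"], [t], [sigmoid_value(t + delta, truth)[None, :]], ["m"]
        )
        p = ModelParamsM2(
            midpoint=np.full((1, 3), 8.0),
            growth_rate=np.full((1, 3), 0.7),
            supremum=np.full((1, 3), 2.0),
            sigma=np.array([0.3]),
            xi1=np.array([1.0]),
            tau=np.array([0.0]),
            pi1=np.array([0.5]),
        )
        h = _hyper(beta_tau=0.0, lambda_tau=1.0)
        for _ in range(300):
            p.tau = gradient_step_tau(ds, p, h)
        assert p.tau[0] == pytest.approx(delta, abs=0.05)


class TestEmMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_xi_pi_pair_does_not_decrease_objective(self, seed):
        rng = np.random.default_rng(seed)
        ds, p = random_instance(rng, J=8, B=3, h=3)
        h = _hyper(beta_xi=1.2)
        before = log_posterior(ds, p, h)
        q = p.copy()
        fw = _forward(ds, q)
        q.xi1 = update_xi(ds, q, h, fw)
        q.pi1 = update_pi(ds, q, fw)
        after = log_posterior(ds, q, h)
        assert after >= before - 1e-9


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(
        n_subjects=20, n_biomarkers=2, n_timepoints=5, noise_variance=0.2, seed=3
    )
    ds, truth = generate_dataset(cfg)
    est = DPMoSt(random_state=0, n_restarts=2, n_outer=60).fit(ds)
    return ds, truth, est


@pytest.fixture(scope="module")
def frozen():
    # train on the absolute disease axis; held-out subjects then arrive
    # with their own clocks (time since their first visit) and must be
    # staged back onto the trained axis through tau
    cfg = SimulationConfig(
        n_subjects=40, n_biomarkers=5, n_timepoints=5,
        noise_variance=0.2, seed=7,
    )
    ds, truth = generate_dataset(cfg)
    train_idx = list(range(0, 30))
    test_idx = list(range(30, 40))
    est = DPMoSt(random_state=0, n_restarts=3, n_outer=120).fit(
        ds.subset_subjects(train_idx)
    )
    return ds, truth, est, test_idx


class TestFit:

    def test_ascent_over_run(self, fitted):
        _, _, est = fitted
        assert est.objective_trace_[-1] >= est.objective_trace_[0]

    def test_probabilities_valid(self, fitted):
        _, _, est = fitted
        assert est.split_probability_.between(0, 1).all()
        assert est.subtype_probability_.between(0, 1).all()

    def test_trace_finite(self, fitted):
        _, _, est = fitted
        assert np.all(np.isfinite(est.objective_trace_))

    def test_determinism(self):
        cfg = SimulationConfig(
            n_subjects=16, n_biomarkers=2, n_timepoints=4,
            noise_variance=0.3, n_specific=1, seed=11,
        )
        ds, _ = generate_dataset(cfg)
        a = DPMoSt(random_state=5, n_restarts=2, n_outer=30).fit(ds)
        b = DPMoSt(random_state=5, n_restarts=2, n_outer=30).fit(ds)
        assert a.objective_trace_ == b.objective_trace_
        np.testing.assert_array_equal(a.params_.tau, b.params_.tau)
        np.testing.assert_array_equal(a.params_.xi1, b.params_.xi1)

    def test_branch_relabelling_canonical(self, fitted):
        _, _, est = fitted
        b_star = int(np.argmax(est.split_probability_.to_numpy()))
        assert (
            est.params_.growth_rate[b_star, 1] <= est.params_.growth_rate[b_star, 2]
        )

    def test_sklearn_params_roundtrip(self):
        est = DPMoSt(n_restarts=3, lambda_tau=0.2)
        params = est.get_params()
        assert params["n_restarts"] == 3
        est2 = DPMoSt().set_params(**params)
        assert est2.lambda_tau == 0.2

    def test_single_trajectory_data_mostly_no_split(self):
        # cohort with no subtype structure at all: most biomarkers should be
        # classified as following a single shared trajectory
        cfg = SimulationConfig(
            n_subjects=30, n_biomarkers=3, n_timepoints=5,
            noise_variance=0.2, n_specific=0, seed=2,
        )
        ds, truth = generate_dataset(cfg)
        est = DPMoSt(random_state=1, n_restarts=3, n_outer=100).fit(ds)
        assert (est.split_probability_ < 0.5).mean() >= 2 / 3


class TestTransfer:

    def test_self_transfer_consistency(self, frozen):
        ds, truth, est, _ = frozen
        train = ds.subset_subjects(range(30))
        staged = est.stage(train)
        # re-estimated shifts agree with the training shifts
        r = np.corrcoef(staged["tau"], est.params_.tau)[0, 1]
        assert r > 0.95

    def test_biomarker_subset_supported(self, frozen):
        ds, truth, est, test_idx = frozen
        sub = ds.subset_subjects(test_idx).subset_biomarkers(
            ds.biomarker_names[:2]
        )
        staged = est.stage(sub)
        assert staged["subtype_probability"].between(0, 1).all()
        assert len(staged) == len(test_idx)

    def test_no_overlap_rejected(self, frozen):
        ds, truth, est, test_idx = frozen
        sub = ds.subset_subjects(test_idx)
        renamed = LongitudinalDataset(
            sub.subject_ids, sub.times, sub.values, [f"x{i}" for i in range(5)]
        )
        with pytest.raises(ValueError, match="overlap"):
            est.stage(renamed)

    def test_late_stage_subjects_get_larger_tau(self, frozen):
        ds, truth, est, test_idx = frozen
        held = ds.subset_subjects(test_idx)
        recentred = LongitudinalDataset(
            held.subject_ids,
            [t - t[0] for t in held.times],
            held.values,
            held.biomarker_names,
        )
        staged = est.stage(recentred)
        offsets = truth.time_offset[test_idx]
        order = np.argsort(offsets)
        tau = staged["tau"].to_numpy()
        # earliest third vs latest third of held-out subjects
        assert tau[order[-3:]].mean() > tau[order[:3]].mean()

    def test_requires_fit(self):
        with pytest.raises(RuntimeError):
            DPMoSt().stage(None)
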
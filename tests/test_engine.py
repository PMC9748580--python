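"""The coordinate-ascent MFVB fitter: streamlined path against the dense
reference, conjugate limits, and the conjugate-fragment update arithmetic."""

import numpy as np
import pytest

import mglmmvb as mv
from mglmmvb import (
    FitControls,
    PriorConfig,
    build_design,
    compute_elbo,
    fit,
    fit_naive,
    initialize_state,
)
from mglmmvb.engine import (
    _row_weights,
    update_auxiliaries,
    update_beta_u_streamlined,
    update_predictor_moments,
    update_random_effects_covariance,
    update_residual_variances,
)
from tests.conftest import make_mixed_design


def assemble_full_covariance(state, design):
    """Dense (p + mq) covariance from the stored blocks."""
    p, q, m = design.p, design.q, design.m
    full = np.zeros((p + m * q, p + m * q))
    full[:p, :p] = state.Sigma_beta
    for i in range(m):
        c0 = p + i * q
        full[c0 : c0 + q, c0 : c0 + q] = state.Sigma_u[i]
        full[:p, c0 : c0 + q] = state.cross_cov[i]
        full[c0 : c0 + q, :p] = state.cross_cov[i].T
    return full


def states_close(a, b, rtol=1e-8, atol=1e-10):
    for name in ("mu_beta", "Sigma_beta", "mu_u", "Sigma_u", "cross_cov",
                 "M_qinv", "mu_inv_sig2", "mu_inv_a"):
        np.testing.assert_allclose(
            getattr(a, name), getattr(b, name), rtol=rtol, atol=atol, err_msg=name
        )
    if a.B_R is not None:
        np.testing.assert_allclose(a.B_R, b.B_R, rtol=rtol, atol=atol, err_msg="B_R")


class TestInitialization:
    def test_stated_defaults(self, mixed_design_small):
        design, _, _ = mixed_design_small
        state = initialize_state(design, PriorConfig())
        np.testing.assert_array_equal(state.M_qinv, np.eye(design.q))
        np.testing.assert_array_equal(state.mu_beta, np.zeros(design.p))
        np.testing.assert_array_equal(state.Sigma_beta, np.eye(design.p))
        assert np.all(state.mu_inv_sig2 == 1.0) and np.all(state.mu_inv_a == 1.0)
        state.check_invariants()


class TestStreamlinedNaiveEquivalence:
    @pytest.mark.parametrize("seed,scenario,m", [(0, 2, 6), (1, 2, 12), (2, 1, 10), (3, 2, 20)])
    def test_per_cycle_state_equality(self, seed, scenario, m):
        # every q-parameter matches the dense reference after EVERY cycle
        design = make_mixed_design(m=m, seed=seed, scenario=scenario)
        for n_cycles in (1, 2, 3, 5, 8):
            ctl = FitControls(max_iter=n_cycles)
            rs = fit(design, controls=ctl)
            rn = fit_naive(design, controls=ctl)
            states_close(rs.state, rn.state)
            np.testing.assert_allclose(rs.elbo_trace, rn.elbo_trace, rtol=1e-8)
            rs.state.check_invariants()

    def test_stored_blocks_match_dense_inverse(self, mixed_design_small):
        # the stored covariance blocks equal the corresponding blocks of the
        # inverse of the joint precision the cycle solved
        design, _, _ = mixed_design_small
        priors = PriorConfig()
        res = fit(design, controls=FitControls(max_iter=3))
        state = res.state
        # rebuild the precision the update inverted: rerun the prior cycles
        res2 = fit(design, controls=FitControls(max_iter=2))
        moments_before = update_predictor_moments(res2.state, design)
        einv = _row_weights(res2.state, design)
        w = einv * moments_before.e_b2
        C = design.full_C()
        p, q, m = design.p, design.q, design.m
        D = np.zeros((p + m * q, p + m * q))
        D[:p, :p] = np.eye(p) / priors.sigma2_beta
        for i in range(m):
            c0 = p + i * q
            D[c0 : c0 + q, c0 : c0 + q] = res2.state.M_qinv
        precision = C.T @ (w[:, None] * C) + D
        inv = np.linalg.inv(precision)
        np.testing.assert_allclose(inv[:p, :p], state.Sigma_beta, atol=1e-10)
        for i in range(m):
            c0 = p + i * q
            np.testing.assert_allclose(
                inv[c0 : c0 + q, c0 : c0 + q], state.Sigma_u[i], atol=1e-10
            )
            np.testing.assert_allclose(
                inv[:p, c0 : c0 + q], state.cross_cov[i], atol=1e-10
            )
        # and the log-determinant bookkeeping agrees with the dense value
        sign, logdet = np.linalg.slogdet(precision)
        assert sign > 0 and -logdet == pytest.approx(state.logdet_Sigma_nu, rel=1e-9)


class TestConjugateLimits:
    def test_ridge_limit_single_subject(self):
        # random-effect precision frozen at ~0: the fitted values match the
        # ridge solution with penalty only on beta (the beta/u split itself is
        # unidentified here because X_i and Z_i share columns)
        design = make_mixed_design(m=1, seed=4, scenario=1)
        priors = PriorConfig()
        big = 1e12 * np.eye(design.q)
        res = fit(
            design,
            priors=priors,
            controls=FitControls(tolerance=1e-13, max_iter=200),
            frozen_variance_components={"Sigma_R": big, "sigma2_eps": [1.0, 1.0, 1.0]},
        )
        C = design.full_C()
        D = np.zeros((C.shape[1], C.shape[1]))
        D[: design.p, : design.p] = np.eye(design.p) / priors.sigma2_beta
        D[design.p :, design.p :] = np.eye(design.q) / 1e12
        sol = np.linalg.solve(C.T @ C + D, C.T @ design.y)
        got = np.concatenate([res.state.mu_beta, res.state.mu_u.ravel()])
        np.testing.assert_allclose(C @ got, C @ sol, rtol=1e-6, atol=1e-8)

    def test_henderson_mixed_model_equations(self):
        # variance components frozen at truth: converged mean solves the
        # Henderson mixed-model equations
        truth = mv.scenario_truth(1)
        dataset, _ = mv.simulate_dataset(truth, m=10, seed=4)
        design = build_design(dataset)
        sig2 = [truth.sigma2_eps[r] for r in range(3)]
        priors = PriorConfig()
        res = fit(
            design,
            priors=priors,
            controls=FitControls(tolerance=1e-12, max_iter=50),
            frozen_variance_components={"Sigma_R": truth.Sigma_R, "sigma2_eps": sig2},
        )
        assert res.converged
        einv = _row_weights(res.state, design)
        C = design.full_C()
        p, q, m = design.p, design.q, design.m
        D = np.zeros((p + m * q, p + m * q))
        D[:p, :p] = np.eye(p) / priors.sigma2_beta
        Minv = np.linalg.inv(truth.Sigma_R)
        for i in range(m):
            c0 = p + i * q
            D[c0 : c0 + q, c0 : c0 + q] = Minv
        sol = np.linalg.solve(C.T @ (einv[:, None] * C) + D, C.T @ (einv * design.y))
        got = np.concatenate([res.state.mu_beta, res.state.mu_u.ravel()])
        np.testing.assert_allclose(got, sol, rtol=1e-6, atol=1e-10)


class TestUpdateArithmetic:
    def test_beta_precision_identity_with_unit_curvature(self, gaussian_design_small):
        # with E[b''] = 1 and unit residual weights,
        # Sigma_q(beta)^{-1} = X'X + sigma_beta^{-2} I - S by construction
        design, _, _ = gaussian_design_small
        priors = PriorConfig()
        state = initialize_state(design, priors)
        moments = update_predictor_moments(state, design)
        np.testing.assert_array_equal(moments.e_b2, np.ones(design.n_rows))
        new = update_beta_u_streamlined(state, design, moments, priors)
        # recompute S from the same inputs
        w = np.ones(design.n_rows)
        S = np.zeros((design.p, design.p))
        for i in range(design.m):
            Xi, Zi = design.X_i(i), design.Z_i(i)
            G = Xi.T @ Zi
            H = np.linalg.inv(Zi.T @ Zi + state.M_qinv)
            S += G @ H @ G.T
        expected_precision = design.X.T @ design.X + np.eye(design.p) / priors.sigma2_beta - S
        np.testing.assert_allclose(
            np.linalg.inv(new.Sigma_beta), expected_precision, rtol=1e-8
        )

    def test_residual_variance_printed_formula(self, one_marker_table, one_marker_spec):
        # sum n_ir = 10, expected SSQ+trace = 4, mu_q(1/a_eps) = 1
        # -> B = 3, mu_q(1/sigma2) = 5.5/3
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject": np.repeat([1, 2], 5),
                "marker": "bilirubin",
                "time": np.tile(np.linspace(0, 1, 5), 2),
                "response": np.zeros(10),
            }
        )
        ds = mv.read_long_table(table, one_marker_spec)
        design = build_design(ds)
        state = initialize_state(design, PriorConfig())
        from mglmmvb.families import PredictorMoments

        moments = PredictorMoments(mu=np.zeros(10), var=np.full(10, 0.4))
        new = update_residual_variances(state, design, moments, PriorConfig())
        assert new.B_sig2[0] == pytest.approx(3.0)
        assert new.mu_inv_sig2[0] == pytest.approx(5.5 / 3.0)

    def test_residual_variance_perfect_fit_limit(self, one_marker_table, one_marker_spec):
        ds = mv.read_long_table(one_marker_table, one_marker_spec)
        design = build_design(ds)
        state = initialize_state(design, PriorConfig())
        from mglmmvb.families import PredictorMoments

        moments = PredictorMoments(mu=design.y.copy(), var=np.zeros(design.n_rows))
        new = update_residual_variances(state, design, moments, PriorConfig())
        assert new.B_sig2[0] == pytest.approx(state.mu_inv_a_eps[0])

    def test_trace_term_equals_rowwise_quadratic_forms(self):
        # E||y_r - C_r nu||^2 accumulated row-wise equals the matrix form
        design = make_mixed_design(m=3, seed=6, scenario=1)
        res = fit(design, controls=FitControls(max_iter=4))
        moments = update_predictor_moments(res.state, design)
        full = assemble_full_covariance(res.state, design)
        C = design.full_C()
        for r in range(design.R):
            rows = design.marker_idx == r
            brute = np.einsum("nd,de,ne->n", C[rows], full, C[rows])
            np.testing.assert_allclose(moments.var[rows], brute, rtol=1e-8, atol=1e-12)

    def test_auxiliary_update_printed_formula(self):
        priors = PriorConfig(nu=2.0, a_k=1e4)
        state = initialize_state(make_mixed_design(m=2, seed=0), priors)
        state.M_qinv = 0.5 * np.eye(6)
        new = update_auxiliaries(state, priors, q=6)
        np.testing.assert_allclose(new.B_a, 1.0 + 1e-8)
        np.testing.assert_allclose(new.mu_inv_a, 4.0 / (1.0 + 1e-8))

    def test_auxiliary_update_infinite_scale_limit(self):
        priors = PriorConfig(nu=2.0, a_k=1e300)
        state = initialize_state(make_mixed_design(m=2, seed=0), priors)
        state.M_qinv = 0.7 * np.eye(6)
        new = update_auxiliaries(state, priors, q=6)
        np.testing.assert_allclose(new.B_a, 2.0 * 0.7)

    def test_random_effects_covariance_single_subject_identity(self):
        design = make_mixed_design(m=1, seed=0)
        priors = PriorConfig(nu=2.0)
        state = initialize_state(design, priors)  # mu_u = 0, Sigma_u = I, mu_inv_a = 1
        new = update_random_effects_covariance(state, priors, m=1)
        q = design.q
        np.testing.assert_allclose(new.B_R, 5.0 * np.eye(q))
        np.testing.assert_allclose(new.M_qinv, (q + 2) / 5.0 * np.eye(q))

    def test_random_effects_covariance_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        design = make_mixed_design(m=3, seed=1)
        priors = PriorConfig(nu=2.0)
        state = initialize_state(design, priors)
        q = design.q
        state.mu_u = rng.normal(size=(3, q))
        mats = rng.normal(size=(3, q, q))
        state.Sigma_u = mats @ np.swapaxes(mats, 1, 2) + np.eye(q)
        state.mu_inv_a = rng.uniform(0.5, 2.0, size=q)
        new = update_random_effects_covariance(state, priors, m=3)
        B = 2.0 * priors.nu * np.diag(state.mu_inv_a)
        for i in range(3):
            B = B + np.outer(state.mu_u[i], state.mu_u[i]) + state.Sigma_u[i]
        np.testing.assert_allclose(new.B_R, B, rtol=1e-12)
        np.testing.assert_allclose(
            new.M_qinv, (priors.nu + q + 3 - 1) * np.linalg.inv(B), rtol=1e-10
        )

    def test_covariance_update_linear_in_subject_blocks(self):
        design = make_mixed_design(m=2, seed=2)
        priors = PriorConfig()
        state = initialize_state(design, priors)
        state.mu_inv_a = np.zeros(design.q)  # isolate the data part
        b1 = update_random_effects_covariance(state, priors, m=2).B_R
        state.Sigma_u = 3.0 * state.Sigma_u
        b2 = update_random_effects_covariance(state, priors, m=2).B_R
        np.testing.assert_allclose(b2, 3.0 * b1, rtol=1e-12)


class TestPredictorMoments:
    def test_degenerate_blocks_population_only(self, gaussian_design_small):
        design, _, _ = gaussian_design_small
        state = initialize_state(design, PriorConfig())
        state.mu_u[:] = 0.0
        state.Sigma_u[:] = 0.0
        state.cross_cov[:] = 0.0
        moments = update_predictor_moments(state, design)
        np.testing.assert_allclose(moments.mu, design.X @ state.mu_beta)
        np.testing.assert_allclose(
            moments.var, np.einsum("np,pq,nq->n", design.X, state.Sigma_beta, design.X)
        )

    def test_all_zero_covariances_give_zero_variance(self, gaussian_design_small):
        design, _, _ = gaussian_design_small
        state = initialize_state(design, PriorConfig())
        state.Sigma_beta[:] = 0.0
        state.Sigma_u[:] = 0.0
        moments = update_predictor_moments(state, design)
        np.testing.assert_array_equal(moments.var, np.zeros(design.n_rows))

    def test_matches_dense_covariance_assembly(self):
        design = make_mixed_design(m=3, seed=9, scenario=2)
        res = fit(design, controls=FitControls(max_iter=5))
        moments = update_predictor_moments(res.state, design)
        full = assemble_full_covariance(res.state, design)
        C = design.full_C()
        mu_full = np.concatenate([res.state.mu_beta, res.state.mu_u.ravel()])
        np.testing.assert_allclose(moments.mu, C @ mu_full, rtol=1e-10)
        np.testing.assert_allclose(
            moments.var, np.einsum("nd,de,ne->n", C, full, C), rtol=1e-8, atol=1e-12
        )


class TestFitDriver:
    def test_single_cycle_contract(self, gaussian_design_small):
        design, _, _ = gaussian_design_small
        res = fit(design, controls=FitControls(max_iter=1))
        assert res.iterations == 1 and not res.converged and len(res.elbo_trace) == 1

    def test_elbo_monotone_all_gaussian(self, gaussian_design_small):
        design, _, _ = gaussian_design_small
        res = fit(design, controls=FitControls(max_iter=100))
        tr = np.asarray(res.elbo_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_converged_run_meets_stopping_rule(self, gaussian_design_small):
        design, _, _ = gaussian_design_small
        res = fit(design)
        assert res.converged
        tr = res.elbo_trace
        assert abs(tr[-1] - tr[-2]) / (1 + abs(tr[-1])) < 1e-7

    def test_fit_is_deterministic(self):
        design = make_mixed_design(m=5, seed=13)
        r1 = fit(design, controls=FitControls(max_iter=20))
        r2 = fit(design, controls=FitControls(max_iter=20))
        np.testing.assert_array_equal(r1.state.mu_beta, r2.state.mu_beta)
        np.testing.assert_array_equal(r1.elbo_trace, r2.elbo_trace)

    def test_mixed_family_trace_finite(self, mixed_design_small):
        design, _, _ = mixed_design_small
        res = fit(design, controls=FitControls(max_iter=60))
        assert np.all(np.isfinite(res.elbo_trace))
        res.state.check_invariants()

    def test_naive_guard(self, mixed_design_small):
        design, _, _ = mixed_design_small
        with pytest.raises(ValueError, match="guard"):
            fit_naive(design, guard=10)

    def test_parameter_recovery_across_replicates(self):
        # each fixed-effect posterior mean within 3 posterior SDs of its
        # generating value in >= 95% of seeded replicates
        truth = mv.scenario_truth(1)
        beta_true = truth.beta_stacked()
        hits = 0
        total = 0
        for seed in range(20):
            dataset, _ = mv.simulate_dataset(truth, m=1000, seed=100 + seed)
            res = fit(build_design(dataset))
            z = np.abs(res.beta_mean() - beta_true) / res.beta_sd()
            hits += int(np.all(z < 3.0))
            total += 1
        assert hits / total >= 0.95

    def test_subject_missing_marker_entirely(self, two_marker_dataset):
        ds, specs = two_marker_dataset
        table = ds.table[~((ds.table.subject == 1) & (ds.table.marker == "ascites"))]
        design = build_design(mv.read_long_table(table, specs))
        res = fit(design, controls=FitControls(max_iter=40))
        assert np.all(np.isfinite(res.state.mu_u))
        res.state.check_invariants()
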
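"""Model log-posteriors, the NUTS backend, and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from ddrm import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    convergence_report,
    fit_brm,
    fit_ddrm,
    fit_joint,
    generate_dataset,
    hdi,
    point_estimates,
)
from ddrm.inference import _BRMModel, _DDRMModel, _JointModel, prepare_rs1, prepare_rs2
from ddrm.simulation import sample_rs1_table


def _finite_difference_check(model, rng, n_coords=25, h=1e-6, tol=1e-5):
    q = rng.uniform(-0.8, 0.8, model.dim)
    _, grad = model.logp_and_grad(q)
    coords = rng.choice(model.dim, size=min(n_coords, model.dim), replace=False)
    for k in coords:
        qp, qm = q.copy(), q.copy()
        qp[k] += h
        qm[k] -= h
        fd = (model.logp_and_grad(qp)[0] - model.logp_and_grad(qm)[0]) / (2 * h)
        assert grad[k] == pytest.approx(fd, rel=tol, abs=tol)


class TestModelGradients:
    """Analytic gradients agree with central finite differences."""

    @pytest.mark.parametrize("preset", ["simulation", "empirical"])
    def test_ddrm(self, small_dataset, preset):
        pi, ii, y, persons, items = prepare_rs2(small_dataset.responses)
        model = _DDRMModel(pi, ii, np.log(y), len(persons), len(items), PriorSpec(preset))
        _finite_difference_check(model, np.random.default_rng(1))

    def test_ddrm_fixed_alpha(self, small_dataset):
        pi, ii, y, persons, items = prepare_rs2(small_dataset.responses)
        model = _DDRMModel(
            pi, ii, np.log(y), len(persons), len(items),
            PriorSpec("simulation", fix_alpha=0.5),
        )
        _finite_difference_check(model, np.random.default_rng(2))

    def test_brm(self, small_rs1_table):
        pi, ii, x, persons, items = prepare_rs1(small_rs1_table)
        model = _BRMModel(pi, ii, x, len(persons), len(items), PriorSpec("simulation"))
        _finite_difference_check(model, np.random.default_rng(3))

    def test_joint_including_correlation_coordinates(self, small_dataset, small_rs1_table):
        pi2, ii2, y, persons, items2 = prepare_rs2(small_dataset.responses)
        pi1, ii1, x, _, items1 = prepare_rs1(small_rs1_table)
        model = _JointModel(
            (pi1, ii1, x, len(items1)), (pi2, ii2, y, len(items2)),
            len(persons), PriorSpec.empirical(),
        )
        rng = np.random.default_rng(4)
        _finite_difference_check(model, rng, n_coords=40)
        # explicitly cover the three correlation coordinates
        q = rng.uniform(-0.8, 0.8, model.dim)
        _, grad = model.logp_and_grad(q)
        for k in range(model.s_corr.start, model.s_corr.stop):
            qp, qm = q.copy(), q.copy()
            qp[k] += 1e-6
            qm[k] -= 1e-6
            fd = (model.logp_and_grad(qp)[0] - model.logp_and_grad(qm)[0]) / 2e-6
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestPriorOnly:
    def test_person_prior_is_standard_normal(self):
        ds = generate_dataset(40, 5, seed=2)
        config = MCMCConfig(n_chains=2, n_warmup=200, n_sampling=400, seed=8)
        fit = fit_ddrm(ds.responses, PriorSpec.simulation(), config, prior_only=True)
        theta = fit.stacked("theta").ravel()
        assert abs(theta.mean()) < 0.1
        assert abs(theta.std() - 1.0) < 0.1

    def test_joint_prior_correlations_valid_and_centred(self):
        ds = generate_dataset(30, 4, seed=3)
        rs1 = sample_rs1_table(ds.design, seed=4)
        config = MCMCConfig(n_chains=2, n_warmup=200, n_sampling=400, seed=9)
        fit = fit_joint(rs1, ds.responses, PriorSpec.empirical(), config, prior_only=True)
        omega = fit.stacked("Omega")
        np.testing.assert_allclose(
            omega[:, [0, 1, 2], [0, 1, 2]], 1.0, atol=1e-10
        )
        assert np.all(np.linalg.eigvalsh(omega).min(axis=1) > 0)
        # LKJ(1) marginals are centred at zero
        assert abs(omega[:, 0, 1].mean()) < 0.12
        assert abs(omega[:, 0, 2].mean()) < 0.12

    def test_group_level_person_moments_not_free_parameters(self, small_ddrm_fit):
        assert "mu_theta" not in small_ddrm_fit.posterior
        assert "sigma_theta" not in small_ddrm_fit.posterior


class TestFitDDRM:
    def test_recovers_person_location(self, small_dataset, small_ddrm_fit):
        med = point_estimates(small_ddrm_fit)
        r = np.corrcoef(med["theta"], small_dataset.design.theta)[0, 1]
        assert r > 0.9

    def test_scaling_parameter_near_truth(self, small_ddrm_fit):
        med = point_estimates(small_ddrm_fit)
        assert 0.3 < med["alpha_lambda"] < 0.8

    def test_seeded_runs_identical(self):
        ds = generate_dataset(12, 4, seed=6)
        config = MCMCConfig(n_chains=2, n_warmup=60, n_sampling=60, seed=17)
        f1 = fit_ddrm(ds.responses, config=config)
        f2 = fit_ddrm(ds.responses, config=config)
        np.testing.assert_array_equal(f1.posterior["theta"], f2.posterior["theta"])
        np.testing.assert_array_equal(f1.posterior["tau"], f2.posterior["tau"])

    def test_non_interior_data_rejected(self, small_dataset):
        bad = small_dataset.responses.copy()
        bad.loc[0, "yl"] = 0.0
        with pytest.raises(ValueError, match="rescale_rs2"):
            fit_ddrm(bad)


class TestFitBRM:
    def test_null_data_centres_contrast_at_zero(self):
        rng = np.random.default_rng(10)
        n_persons, n_items = 30, 6
        rows = [
            {"person": i, "item": j, "x": rng.beta(1.0, 1.0)}
            for i in range(n_persons)
            for j in range(n_items)
        ]
        import pandas as pd

        config = MCMCConfig(n_chains=2, n_warmup=200, n_sampling=200, seed=5)
        fit = fit_brm(
            pd.DataFrame(rows), PriorSpec.simulation(fix_alpha=0.5), config
        )
        med = point_estimates(fit)
        contrast = med["theta"].mean() - med["delta"].mean()
        assert abs(contrast) < 0.3


class TestFitJoint:
    def test_recovers_unit_person_correlation(self):
        """When theta_B = theta_D in the generating process, the posterior
        correlation between them concentrates near one."""
        import pandas as pd

        rng = np.random.default_rng(12)
        I, J = 60, 6
        theta = rng.standard_normal(I)
        eta = rng.standard_normal(I)
        delta = np.linspace(-1.5, 1.5, J)
        tau = np.full(J, 1.0)
        lin = 0.5 * (theta[:, None] - delta[None, :])
        x = rng.beta(np.exp(lin + tau), np.exp(-lin + tau))
        g = rng.standard_gamma(
            np.stack(
                [
                    np.exp(lin + tau),
                    np.exp(0.5 * eta[:, None] + np.zeros(J) + tau),
                    np.exp(-lin + tau),
                ],
                axis=-1,
            )
        )
        y = g / g.sum(axis=-1, keepdims=True)
        ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
        rs1 = pd.DataFrame({"person": ii.ravel(), "item": jj.ravel(), "x": x.ravel()})
        rs2 = pd.DataFrame(
            {
                "person": ii.ravel(),
                "item": jj.ravel(),
                "yl": y[..., 0].ravel(),
                "yu": (y[..., 0] + y[..., 1]).ravel(),
            }
        )
        config = MCMCConfig(n_chains=2, n_warmup=250, n_sampling=250, seed=13)
        fit = fit_joint(rs1, rs2, PriorSpec.empirical(), config)
        omega_bd = np.median(fit.stacked("Omega")[:, 0, 1])
        assert omega_bd > 0.85

    def test_person_mismatch_rejected(self, small_dataset, small_rs1_table):
        truncated = small_rs1_table[small_rs1_table["person"] < 10]
        with pytest.raises(ValueError, match="same persons"):
            fit_joint(truncated, small_dataset.responses)


class TestPosteriorSummaries:
    def test_point_estimates_are_medians(self, small_ddrm_fit):
        med = point_estimates(small_ddrm_fit)
        manual = np.median(small_ddrm_fit.stacked("theta"), axis=0)
        np.testing.assert_allclose(med["theta"], manual)

    def test_median_of_symmetric_draws(self):
        draws = PosteriorDraws(
            posterior={"x": np.array([[[-2.0], [0.0], [2.0], [1.0], [-1.0]]])},
            sample_stats={"diverging": np.zeros((1, 5), dtype=bool)},
            log_likelihood={},
            model="test", config=MCMCConfig(), priors=PriorSpec(),
        )
        assert point_estimates(draws)["x"][0] == 0.0

    def test_hdi_standard_normal(self):
        x = np.random.default_rng(0).standard_normal(200_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_hdi_narrower_than_equal_tails_for_skew(self):
        x = np.random.default_rng(1).gamma(2.0, size=100_000)
        lo, hi = hdi(x, 0.9)
        eq_lo, eq_hi = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (eq_hi - eq_lo)

    def test_hdi_full_mass_spans_range(self):
        x = np.array([3.0, -1.0, 2.0, 0.5])
        assert hdi(x, 1.0) == (-1.0, 3.0)


class TestConvergenceReport:
    @staticmethod
    def _draws_from(chains, diverging=None):
        chains = np.asarray(chains, dtype=float)
        n_chains, n_draws = chains.shape
        return PosteriorDraws(
            posterior={"x": chains[..., None]},
            sample_stats={
                "diverging": diverging
                if diverging is not None
                else np.zeros((n_chains, n_draws), dtype=bool)
            },
            log_likelihood={},
            model="test", config=MCMCConfig(), priors=PriorSpec(),
        )

    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(2)
        report = convergence_report(self._draws_from(rng.standard_normal((4, 1000))))
        assert 0.99 <= report.max_rhat <= 1.01
        assert report.passed

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 1000))
        chains[0] += 5.0
        report = convergence_report(self._draws_from(chains))
        assert report.max_rhat > 1.05
        assert not report.passed

    def test_any_divergence_fails_in_simulation_context(self):
        rng = np.random.default_rng(4)
        div = np.zeros((4, 1000), dtype=bool)
        div[1, 10] = True
        report = convergence_report(
            self._draws_from(rng.standard_normal((4, 1000)), diverging=div),
            context="simulation",
        )
        assert not report.passed
        report_emp = convergence_report(
            self._draws_from(rng.standard_normal((4, 1000)), diverging=div),
            context="empirical",
        )
        assert report_emp.passed

    def test_single_chain_flagged(self):
        report = convergence_report(
            self._draws_from(np.random.default_rng(5).standard_normal((1, 500)))
        )
        assert not report.rhat_available
        assert not report.passed
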
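"""ADSM, dependence correlations, recovery metrics, PPC, and LOO."""

import numpy as np
import pandas as pd
import pytest

from ddrm import (
    adsm,
    generate_dataset,
    latent_dependence,
    loo_report,
    manifest_dependence,
    ppc_inclusion_density,
    ppc_marginal,
    recovery_metrics,
)


class TestAdsm:
    @pytest.mark.parametrize(
        "yl, yu, expected",
        [(0.2, 0.4, 0.2), (0.9, 0.98, 0.44), (0.499, 0.501, 0.0)],
    )
    def test_values(self, yl, yu, expected):
        assert adsm(yl, yu).y_adsm == pytest.approx(expected, abs=1e-12)

    def test_midpoint_limit(self):
        for eps in (1e-2, 1e-4, 1e-6):
            assert adsm(0.5, 0.5 + eps).y_adsm == pytest.approx(eps / 2)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            yl = rng.uniform(0.01, 0.5)
            yu = rng.uniform(yl + 0.01, 0.99)
            mirrored = (1 - yu, 1 - yl)
            assert adsm(yl, yu).y_adsm == pytest.approx(adsm(*mirrored).y_adsm)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            adsm(0.7, 0.3)

    def test_range_bound(self):
        vals = adsm(
            np.array([0.01, 0.49, 0.95]), np.array([0.02, 0.51, 0.99])
        )
        assert np.all((vals >= 0) & (vals < 0.5))


class TestManifestDependence:
    def test_strongly_negative_under_design(self):
        ds = generate_dataset(250, 20, seed=44)
        assert manifest_dependence(ds) < -0.5

    def test_reflection_leaves_correlation_unchanged(self):
        ds = generate_dataset(100, 10, seed=45)
        r1 = manifest_dependence(ds)
        mirrored = ds.responses.copy()
        mirrored["yl"], mirrored["yu"] = 1 - ds.responses["yu"], 1 - ds.responses["yl"]
        assert manifest_dependence(mirrored) == pytest.approx(r1, abs=1e-12)

    def test_constant_widths_flagged(self):
        df = pd.DataFrame(
            {
                "person": np.repeat(np.arange(5), 2),
                "item": np.tile(np.arange(2), 5),
                "yl": np.full(10, 0.3),
                "yu": np.full(10, 0.5),
            }
        )
        with pytest.raises(ValueError, match="constant"):
            manifest_dependence(df)

    def test_needs_three_persons(self):
        df = pd.DataFrame(
            {"person": [0, 1], "item": [0, 0], "yl": [0.1, 0.2], "yu": [0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="persons"):
            manifest_dependence(df)


class TestLatentDependence:
    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(1)
        r = latent_dependence(rng.standard_normal(50_000), rng.standard_normal(50_000))
        assert abs(r) < 0.02

    def test_perfect_dependence(self):
        theta = np.random.default_rng(2).standard_normal(500)
        assert latent_dependence(theta, np.abs(theta)) == pytest.approx(1.0)


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        truth = {"theta": np.array([0.0, 1.0, -1.0, 2.0])}
        ivs = {"theta": np.array([[v - 0.1, v + 0.1] for v in truth["theta"]])}
        report = recovery_metrics([truth], [truth], [ivs])
        row = report.summary.iloc[0]
        assert row["correlation"] == pytest.approx(1.0)
        assert row["bias"] == pytest.approx(0.0)
        assert row["rmse"] == pytest.approx(0.0)
        assert row["coverage"] == pytest.approx(100.0)

    def test_constant_shift(self):
        truth = {"theta": np.array([0.0, 1.0, -1.0])}
        est = {"theta": truth["theta"] + 1.0}
        report = recovery_metrics([est], [truth])
        row = report.summary.iloc[0]
        assert row["bias"] == pytest.approx(1.0)
        assert row["rmse"] == pytest.approx(1.0)
        assert row["correlation"] == pytest.approx(1.0)

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(3)
        truth = {"g": rng.standard_normal(200)}
        est = {"g": truth["g"] + rng.normal(0.3, 0.5, 200)}
        report = recovery_metrics([est], [truth])
        row = report.table.iloc[0]
        err = est["g"] - truth["g"]
        assert row["rmse"] ** 2 == pytest.approx(row["bias"] ** 2 + err.var(), rel=1e-9)
        assert row["rmse"] >= abs(row["bias"])

    def test_agreement_with_naive_recomputation(self):
        rng = np.random.default_rng(4)
        truth = {"theta": rng.standard_normal(50), "tau": rng.uniform(0, 2, 8)}
        est = {k: v + rng.normal(0, 0.2, v.shape) for k, v in truth.items()}
        report = recovery_metrics([est], [truth])
        for group in ("theta", "tau"):
            row = report.table[report.table["group"] == group].iloc[0]
            e, t = est[group], truth[group]
            assert row["bias"] == pytest.approx(np.mean(e - t))
            assert row["rmse"] == pytest.approx(np.sqrt(np.mean((e - t) ** 2)))
            assert row["correlation"] == pytest.approx(np.corrcoef(e, t)[0, 1])


class TestPpcInclusionDensity:
    def test_documented_example(self):
        intervals = np.array([[0.50, 0.54], [0.32, 0.55], [0.53, 0.87]])
        grid, counts = ppc_inclusion_density(intervals, grid_size=101)
        assert counts[np.argmin(np.abs(grid - 0.53))] == 3

    def test_no_intervals_gives_zeros(self):
        _, counts = ppc_inclusion_density(np.empty((0, 2)))
        assert np.all(counts == 0)

    def test_full_interval_counts_once_everywhere(self):
        _, counts = ppc_inclusion_density(np.array([[0.0, 1.0]]))
        assert np.all(counts == 1)


class TestPpcMarginal:
    def test_replicate_count_and_calibration(self, small_dataset, small_ddrm_fit):
        res = ppc_marginal(
            small_ddrm_fit, small_dataset.responses,
            aspect="width", n_replicates=40, seed=0,
        )
        assert res["replicated"].shape == (40, 512)
        lo = res["replicated"].min(axis=0)
        hi = res["replicated"].max(axis=0)
        inside = (res["empirical"] >= lo) & (res["empirical"] <= hi)
        # data were simulated from the fitted model: the empirical density
        # should sit inside the replicate envelope almost everywhere
        assert inside.mean() >= 0.9

    def test_location_and_width_consistent_with_bounds(self, small_dataset):
        df = small_dataset.responses
        loc = (df["yl"] + df["yu"]) / 2
        width = df["yu"] - df["yl"]
        np.testing.assert_allclose(loc + width / 2, df["yu"])
        np.testing.assert_allclose(loc - width / 2, df["yl"])

    def test_aspect_model_mismatch_rejected(self, small_dataset, small_ddrm_fit):
        with pytest.raises(ValueError, match="rs1"):
            ppc_marginal(small_ddrm_fit, small_dataset.responses, aspect="rs1")


class TestLooReport:
    def test_effective_parameters_bounded(self, small_dataset, small_ddrm_fit):
        report = loo_report(small_ddrm_fit)
        n_params = sum(
            np.prod(v.shape[2:], dtype=int) for v in small_ddrm_fit.posterior.values()
        )
        assert report.p_loo > 0
        assert report.p_loo < n_params
        assert report.p_loo < report.n_obs
        # short chains inflate Pareto-k estimates; nearly all observations
        # should still be unflagged under correct specification
        assert report.n_flagged <= 0.05 * report.n_obs

    def test_requires_pointwise_loglik(self, small_dataset):
        from ddrm import MCMCConfig, fit_ddrm

        fit = fit_ddrm(
            small_dataset.responses.head(60),
            config=MCMCConfig(n_chains=2, n_warmup=50, n_sampling=50, seed=1),
            store_loglik=False,
        )
        with pytest.raises(ValueError, match="log-likelihood"):
            loo_report(fit)
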
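import numpy as np
import pytest
from scipy.optimize import minimize

import dissonet as dn
from dissonet import EffectSpec, EstimationSettings, ModelSpec

from conftest import enumerate_two_layer_states, random_attrs, random_two_layer


def make_result(spec, theta, se, t_ratios):
    p = len(spec)
    return dn.EstimationResult(
        spec=spec,
        theta=np.asarray(theta, float),
        se=np.asarray(se, float),
        t_ratios=np.asarray(t_ratios, float),
        covariance=np.eye(p),
        observed=np.zeros(p),
        sim_mean=np.zeros(p),
        sim_sd=np.ones(p),
        converged=True,
        n_retries=0,
        seed=0,
    )


class TestFit:
    def test_arc_only_recovers_logit_density(self, rng):
        n = 16
        g = random_two_layer(rng, n, p_f=0.25, p_d=0.25)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"),))
        r = dn.fit(g, None, spec, EstimationSettings(seed=1, phase3_samples=600))
        d = g.F.sum() / (n * (n - 1))
        target = np.log(d / (1 - d))
        assert r.converged
        assert abs(r.theta[0] - target) < 2 * r.se[0]

    def test_matches_enumeration_mle(self):
        """Robbins-Monro vs. the exact MLE over all 4096 states at n=3."""
        spec = ModelSpec(
            effects=(
                EffectSpec("arc", "F"),
                EffectSpec("arc", "D"),
                EffectSpec("reciprocity", "F"),
                EffectSpec("exchange", "cross"),
            )
        )
        F = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 0]], np.uint8)
        D = np.array([[0, 0, 1], [0, 0, 0], [1, 1, 0]], np.uint8)
        g = dn.TwoLayerDigraph(F=F, D=D)
        z_obs = dn.statistics(g, None, spec)
        Z = np.array(
            [dn.statistics(s, None, spec) for s in enumerate_two_layer_states(3)]
        )

        def nll(th):
            w = Z @ th
            m = w.max()
            return -(z_obs @ th) + m + np.log(np.exp(w - m).sum())

        mle = minimize(nll, np.zeros(len(spec)), method="BFGS").x
        r = dn.fit(g, None, spec, EstimationSettings(seed=5, phase3_samples=1500))
        assert r.converged
        assert np.all(np.abs(r.theta - mle) <= 2 * r.se)

    def test_reproducible_for_fixed_seed(self, rng):
        g = random_two_layer(rng, 10, p_f=0.2, p_d=0.15)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("arc", "D")))
        s = EstimationSettings(seed=11, phase1_samples=40,
                               subphase_iterations=(50, 100), phase3_samples=200)
        r1 = dn.fit(g, None, spec, s)
        r2 = dn.fit(g, None, spec, s)
        np.testing.assert_array_equal(r1.theta, r2.theta)
        np.testing.assert_array_equal(r1.se, r2.se)

    def test_significance_flag_is_two_se_rule(self):
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("arc", "D")))
        r = make_result(spec, theta=[1.0, 0.5], se=[0.5, 0.5], t_ratios=[0.0, 0.0])
        assert r.significant.tolist() == [True, False]
        stars = r.to_frame()["significant"].tolist()
        assert stars == ["*", ""]

    def test_constant_attribute_is_degenerate(self, rng):
        g = random_two_layer(rng, 8)
        attrs = dn.ActorTable(
            pwb=[50] * 8, smf=rng.integers(0, 10, 8), ses=rng.integers(0, 2, 8),
            gender=["boy"] * 8,
        )
        spec = ModelSpec(
            effects=(EffectSpec("arc", "F"), EffectSpec("sender", "F", "pwb"))
        )
        with pytest.raises(ValueError, match="constant"):
            dn.fit(g, attrs, spec)

    def test_failed_convergence_is_flagged_not_silent(self, rng):
        g = random_two_layer(rng, 10, p_f=0.35, p_d=0.1)
        # strong observed reciprocity that a frozen phase 2 cannot reach
        g.F[:] = np.maximum(g.F, g.F.T)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("reciprocity", "F")))
        s = EstimationSettings(
            seed=3, phase1_samples=20, subphase_iterations=(1,), initial_gain=1e-12,
            phase3_samples=150, max_retries=0,
        )
        r = dn.fit(g, None, spec, s)
        assert not r.converged
        assert np.isfinite(r.theta).all() and np.isfinite(r.t_ratios).all()

    def test_se_estimates_stabilise_with_phase3_size(self, rng):
        """The Monte-Carlo scatter of the SE estimate shrinks with the
        phase-3 sample size (the SE itself estimates a fixed quantity)."""
        g = random_two_layer(rng, 12, p_f=0.25, p_d=0.2)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"),))
        ses = {}
        for n3 in (100, 900):
            vals = [
                dn.fit(
                    g, None, spec,
                    EstimationSettings(seed=40 + k, phase1_samples=30,
                                       subphase_iterations=(30, 60), phase3_samples=n3),
                ).se[0]
                for k in range(4)
            ]
            ses[n3] = np.std(vals)
        assert ses[900] < ses[100]


class TestConvergenceCheck:
    def test_all_zero_ratios_pass(self):
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("arc", "D")))
        r = make_result(spec, [0, 0], [1, 1], [0.0, 0.0])
        passed, ratios = dn.convergence_check(r)
        assert passed and set(ratios) == set(spec.labels)

    def test_single_bad_ratio_fails_and_names_effect(self, caplog):
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("arc", "D")))
        r = make_result(spec, [0, 0], [1, 1], [0.02, 0.15])
        with caplog.at_level("WARNING"):
            passed, ratios = dn.convergence_check(r)
        assert not passed
        assert ratios["arc[D]"] == 0.15
        assert "arc[D]" in caplog.text

    def test_converged_arc_only_fit_passes(self, rng):
        g = random_two_layer(rng, 12, p_f=0.3, p_d=0.2)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"),))
        r = dn.fit(g, None, spec, EstimationSettings(seed=2, phase3_samples=500))
        passed, _ = dn.convergence_check(r)
        assert passed == r.converged == True  # noqa: E712


class TestGof:
    @pytest.fixture()
    def fitted(self, rng):
        g = random_two_layer(rng, 12, p_f=0.25, p_d=0.15)
        spec = ModelSpec(effects=(EffectSpec("arc", "F"), EffectSpec("arc", "D")))
        r = dn.fit(g, None, spec, EstimationSettings(seed=21, phase3_samples=400))
        return g, r

    def test_fitted_statistics_have_small_t(self, fitted):
        g, r = fitted
        report = dn.gof(g, None, r, n_samples=400, seed=77)
        assert report.max_abs_t_fitted < 2.0

    def test_auxiliary_statistics_reported_separately(self, fitted):
        g, r = fitted
        aux = ModelSpec(effects=(EffectSpec("reciprocity", "F"),
                                 EffectSpec("exchange", "cross")))
        report = dn.gof(g, None, r, auxiliary_spec=aux, n_samples=300, seed=78)
        t = report.table
        assert t["fitted"].sum() == 2 and (~t["fitted"]).sum() == 2
        assert np.isfinite(t["observed"]).all()

    def test_miscalibrated_theta_shows_large_t(self, fitted):
        g, r = fitted
        import dataclasses

        wrong = dataclasses.replace(r, theta=r.theta + np.array([3.0, 0.0]))
        report = dn.gof(g, None, wrong, n_samples=300, seed=79)
        t_arc_f = report.table.loc[report.table["statistic"] == "arc[F]", "t"].iloc[0]
        assert abs(t_arc_f) > 2.0

    def test_moment_match_at_converged_estimate(self, fitted):
        """Method-of-moments fixed point: simulated means within 0.1 SD."""
        g, r = fitted
        assert r.converged
        assert np.all(np.abs(r.sim_mean - r.observed) <= 0.1 * r.sim_sd)


class TestResultSerialisation:
    def test_csv_round_trip_preserves_estimates(self, tmp_path):
        spec = dn.cohort_model_spec(("pwb",))
        p = len(spec)
        rng = np.random.default_rng(0)
        r = make_result(spec, rng.normal(size=p), np.abs(rng.normal(size=p)) + 0.1,
                        rng.normal(scale=0.01, size=p))
        path = tmp_path / "estimates.csv"
        r.to_csv(path)
        r2 = dn.EstimationResult.from_csv(path)
        assert r2.spec == r.spec
        np.testing.assert_allclose(r2.theta, r.theta)
        np.testing.assert_allclose(r2.se, r.se)
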
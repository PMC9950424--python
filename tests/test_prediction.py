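import numpy as np
import pytest

from adprog.dynamics import CHANNELS
from adprog.model import ModelConfig, ParamPoint, PosteriorDraws
from adprog.observation import inverse_sigmoid_link
from adprog.prediction import (
    ConversionPrediction,
    Forecast,
    estimate_initial_state,
    forecast_subject,
    time_to_conversion,
    velocity_summary,
)
from adprog.synthetic import GeneratorConfig, generate_cohort


def truth_draws(cfg: GeneratorConfig, truth, n_draws=60) -> PosteriorDraws:
    """Degenerate posterior at the generator's true parameters."""
    mc = ModelConfig(chains=1, warmup=10, draws=10, seed=0)
    point = ParamPoint(
        velocity=cfg.velocity,
        sigma=np.array([cfg.noise[c].sigma for c in CHANNELS]),
        ologit=cfg.ordered_logit,
        mu0=cfg.mu0, tau0=cfg.tau0, x0=truth.x0,
    )
    return PosteriorDraws.from_point(point, mc, n_draws=n_draws)


def make_forecast(grid, p_ad):
    p_ad = np.asarray(p_ad, float)
    probs = np.stack([1.0 - p_ad, np.zeros_like(p_ad), p_ad], axis=-1)[None]
    return Forecast(
        subject_id="X", grid=np.asarray(grid, float),
        trajectories=np.zeros((1, grid.size, 5)),
        probs=probs, mean_probs=probs[0], x0_samples=np.zeros((1, 5)),
    )


class TestTimeToConversion:
    grid = np.linspace(0.0, 10.0, 201)

    def test_linear_curve_interpolated_crossings(self):
        """P(AD)(t) = 0.05 t crosses 30% at 6y, 50% at 10y, never reaches 70%."""
        cp = time_to_conversion(make_forecast(self.grid, 0.05 * self.grid))
        assert cp.t30 == pytest.approx(6.0, abs=1e-9)
        assert cp.t50 == pytest.approx(10.0, abs=1e-9)
        assert np.isnan(cp.t70) and cp.beyond_horizon["t70"]

    def test_immediate_crossing_is_time_zero(self):
        cp = time_to_conversion(make_forecast(self.grid, np.full(201, 0.8)))
        assert cp.t30 == cp.t50 == cp.t70 == 0.0

    def test_flat_low_curve_beyond_horizon(self):
        cp = time_to_conversion(make_forecast(self.grid, np.full(201, 0.1)))
        assert all(cp.beyond_horizon.values())
        assert np.isnan(cp.t50)

    @pytest.mark.parametrize("seed", range(4))
    def test_threshold_ordering_on_arbitrary_curves(self, seed):
        rng = np.random.default_rng(seed)
        curve = np.clip(np.cumsum(rng.normal(0.01, 0.05, 201)), 0, 1)
        cp = time_to_conversion(make_forecast(self.grid, curve))
        finite = [t for t in (cp.t30, cp.t50, cp.t70) if np.isfinite(t)]
        assert finite == sorted(finite)

    def test_unordered_times_rejected_by_container(self):
        with pytest.raises(ValueError, match="ordered"):
            ConversionPrediction("x", t30=5.0, t50=3.0, t70=8.0, horizon=10.0)


class TestInitialStateEstimation:
    def setup_cohort(self, noise_scale=0.02, seed=9, visits=4):
        cfg = GeneratorConfig(n_subjects=20, n_sites=2, seed=seed,
                              regular_visits=visits, regular_followup=2.0,
                              noise_scale=noise_scale)
        return cfg, *generate_cohort(cfg)

    def test_low_noise_anchors_to_inverse_linked_observations(self):
        cfg, cohort, truth = self.setup_cohort(noise_scale=0.02)
        draws = truth_draws(cfg, truth)
        for s in (0, 3):
            sid = cohort.subject_ids[s]
            x0s, _ = estimate_initial_state(cohort.subject(sid), draws, seed=1)
            est = x0s.mean(axis=0)
            subj = cohort.subject(sid)
            first = subj.observations[subj.observations["time_years"] == 0.0]
            for _, row in first.iterrows():
                if row["censored"]:
                    continue
                c = CHANNELS.index(row["channel"])
                anchor = inverse_sigmoid_link(row["value"], cfg.links[row["channel"]])
                assert est[c] == pytest.approx(anchor, abs=0.12)

    def test_more_observations_shrink_posterior(self):
        cfg1, cohort1, truth1 = self.setup_cohort(noise_scale=1.0, visits=1)
        cfg4, cohort4, truth4 = self.setup_cohort(noise_scale=1.0, visits=5)
        np.testing.assert_array_equal(truth1.x0, truth4.x0)  # same covariate stream
        draws1 = truth_draws(cfg1, truth1)
        draws4 = truth_draws(cfg4, truth4)
        sds1, sds4 = [], []
        for sid in cohort1.subject_ids[:6]:
            x1, _ = estimate_initial_state(cohort1.subject(sid), draws1, n_steps=500, seed=2)
            x4, _ = estimate_initial_state(cohort4.subject(sid), draws4, n_steps=500, seed=2)
            sds1.append(x1.std(axis=0).mean())
            sds4.append(x4.std(axis=0).mean())
        assert np.mean(sds4) <= np.mean(sds1) * 1.05

    def test_recovery_within_two_posterior_sds(self):
        cfg, cohort, truth = self.setup_cohort(noise_scale=1.0, seed=31)
        draws = truth_draws(cfg, truth)
        hits = total = 0
        for s, sid in enumerate(cohort.subject_ids):
            x0s, _ = estimate_initial_state(cohort.subject(sid), draws, seed=s)
            mean, sd = x0s.mean(axis=0), x0s.std(axis=0)
            hits += int(np.sum(np.abs(mean - truth.x0[s]) <= 2.0 * sd))
            total += 5
        assert hits / total >= 0.85

    def test_no_window_data_names_subject(self):
        cfg, cohort, truth = self.setup_cohort()
        subj = cohort.subject(cohort.subject_ids[0])
        subj.observations = subj.observations.iloc[0:0]
        with pytest.raises(ValueError, match=subj.subject_id):
            estimate_initial_state(subj, truth_draws(cfg, truth))


class TestForecast:
    def test_null_dynamics_give_flat_probability_curves(self):
        cfg = GeneratorConfig(n_subjects=5, n_sites=1, seed=3,
                              regular_visits=3, regular_followup=2.0,
                              velocity=__import__("adprog.dynamics", fromlist=["VelocityParams"]).VelocityParams.zeros())
        cohort, truth = generate_cohort(cfg)
        draws = truth_draws(cfg, truth, n_draws=20)
        fc = forecast_subject(cohort.subject(cohort.subject_ids[0]), draws, seed=0)
        np.testing.assert_allclose(fc.mean_probs, np.tile(fc.mean_probs[0], (fc.grid.size, 1)), atol=1e-9)

    def test_backward_and_forward_span_populated(self):
        cfg = GeneratorConfig(n_subjects=5, n_sites=1, seed=4, regular_visits=3, regular_followup=2.0)
        cohort, truth = generate_cohort(cfg)
        draws = truth_draws(cfg, truth, n_draws=20)
        fc = forecast_subject(cohort.subject(cohort.subject_ids[0]), draws, t_min=-10.0, t_max=20.0, seed=0)
        assert fc.grid[0] == pytest.approx(-10.0) and fc.grid[-1] == pytest.approx(20.0)
        assert np.isfinite(fc.trajectories).all()
        np.testing.assert_allclose(fc.mean_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_grid_refinement_stable_t50(self):
        cfg = GeneratorConfig(n_subjects=12, n_sites=2, seed=6, regular_visits=4, regular_followup=2.0)
        cohort, truth = generate_cohort(cfg)
        draws = truth_draws(cfg, truth, n_draws=30)
        for sid in cohort.subject_ids[:4]:
            coarse = forecast_subject(cohort.subject(sid), draws, step=1 / 12, seed=0)
            fine = forecast_subject(cohort.subject(sid), draws, step=1 / 24, seed=0)
            t_c = time_to_conversion(coarse).t50
            t_f = time_to_conversion(fine).t50
            if np.isfinite(t_c) and np.isfinite(t_f):
                assert abs(t_c - t_f) < 1 / 12


class TestVelocitySummary:
    def test_enumeration_oracle_on_fitted_cohort(self, fitted_small):
        cohort, _, res = fitted_small
        draws = res.draws
        region = {"tau": (-1.0, 1.0)}
        summary = velocity_summary(draws, cohort, region, n_draws=20)
        assert not summary.empty
        # independent loop-based oracle for the pooled mean
        sub = draws.thin_to(20)
        K = sub.n_chains * sub.n_draws
        cov = cohort.covariates
        age_std = (cov["age"].to_numpy(float) - 75.0) / 10.0
        apoe = cov["apoe4"].to_numpy(int)
        samples = []
        for k in range(K):
            vp = sub.velocity_params(k)
            x0k = sub.stacked("x0")[k]
            for s in range(cohort.n_subjects):
                if -1.0 <= x0k[s, 0] <= 1.0:
                    A = vp.V + age_std[s] * vp.W_age + apoe[s] * vp.W_apoe
                    samples.append(A @ x0k[s] + vp.v0)
        samples = np.array(samples)
        tab = summary.table.set_index("component")
        for c_idx, cname in enumerate(CHANNELS):
            assert tab.loc[cname, "mean"] == pytest.approx(samples[:, c_idx].mean(), rel=1e-9)
            assert tab.loc[cname, "hdi_low"] <= tab.loc[cname, "mean"] <= tab.loc[cname, "hdi_high"]

    def test_empty_region_flagged(self, fitted_small):
        cohort, _, res = fitted_small
        summary = velocity_summary(res.draws, cohort, {"tau": (500.0, 600.0)}, n_draws=10)
        assert summary.empty and summary.n_samples == 0

    def test_stratified_by_apoe(self, fitted_small):
        cohort, _, res = fitted_small
        summary = velocity_summary(res.draws, cohort, {}, strata="apoe4", n_draws=10)
        assert set(summary.table["stratum"]) == {"apoe4=0", "apoe4=1"}
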
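"""MSD computation, translation-state classification and CDF mixture fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ertrack.motion import (
    NON_TRANSLATING,
    TRANSLATING,
    UNCLASSIFIED,
    CdfMixtureFit,
    ClassificationConfig,
    DisplacementSample,
    TrajectoryMsd,
    classify_trajectories,
    classify_translation,
    ensemble_msd,
    evaluate_mixture_cdf,
    fit_cdf_mixture,
    fit_dapp,
    msd_lag1,
    pooled_displacements,
    translating_fraction,
)
from ertrack.synthetic import (
    SimulationConfig,
    sample_displacements_cdf,
    simulate_brownian,
    simulate_mixture,
)

from conftest import make_trajectory


class TestMsdLag1:
    def test_stationary_is_zero(self, stationary_track):
        m = msd_lag1(stationary_track)
        assert m.msd_lag1 == 0.0
        assert m.n_displacements == 11
        assert m.label == TRANSLATING  # 0 < 0.055

    def test_uniform_step_gives_square(self):
        xy = np.column_stack([0.1 * np.arange(12), np.zeros(12)])
        m = msd_lag1(make_trajectory(xy))
        assert m.msd_lag1 == pytest.approx(0.01)

    def test_short_track_unclassified(self):
        xy = np.column_stack([0.1 * np.arange(5), np.zeros(5)])
        m = msd_lag1(make_trajectory(xy))
        assert m.label == UNCLASSIFIED

    def test_gap_pairs_skipped(self, caplog):
        xy = np.column_stack([0.1 * np.arange(11), np.zeros(11)])
        tr = make_trajectory(xy, frames=[0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 11])
        with caplog.at_level("WARNING"):
            m = msd_lag1(tr)
        assert m.n_displacements == 9
        assert m.msd_lag1 == pytest.approx(0.01)
        assert "gap" in caplog.text

    def test_population_mean_matches_4d_dt(self):
        """Simulated D=0.0025 µm²/s, σ=0: mean per-track MSD ≈ 0.01 µm²."""
        cfg = SimulationConfig(diffusion_coefficients=[0.0025], fractions=[1.0],
                               n_particles=500, n_steps=15, seed=12)
        ts, _ = simulate_brownian(cfg)
        msds = [msd_lag1(t).msd_lag1 for t in ts]
        assert np.mean(msds) == pytest.approx(0.01, rel=0.05)

    @given(dx=st.floats(-5, 5), dy=st.floats(-5, 5),
           theta=st.floats(0, 2 * np.pi))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, dx, dy, theta):
        """msd_lag1 is unchanged by global translation and rotation."""
        rng = np.random.default_rng(0)
        xy = rng.normal(5, 0.1, size=(12, 2))
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = xy @ rot.T + [dx, dy]
        a = msd_lag1(make_trajectory(xy)).msd_lag1
        b = msd_lag1(make_trajectory(xy2)).msd_lag1
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


class TestClassification:
    cfg = ClassificationConfig()

    @pytest.mark.parametrize("msd,expect", [
        (0.011, TRANSLATING),       # control-like confined regime
        (0.097, NON_TRANSLATING),   # puromycin-like mobile regime
        (0.055, NON_TRANSLATING),   # boundary: strict '<'
    ])
    def test_threshold(self, msd, expect):
        m = TrajectoryMsd(track_id="0", msd_lag1=msd, n_displacements=11, label="")
        assert classify_translation(m, self.cfg) == expect

    def test_unclassified_propagates(self):
        m = TrajectoryMsd(track_id="0", msd_lag1=0.01, n_displacements=3,
                          label=UNCLASSIFIED)
        assert classify_translation(m, self.cfg) == UNCLASSIFIED

    def test_monotone_in_msd(self):
        """Raising msd_lag1 never flips non_translating back to translating."""
        labels = [classify_translation(
            TrajectoryMsd("0", m, 11, ""), self.cfg) for m in np.linspace(0, 0.2, 101)]
        flips = [(a, b) for a, b in zip(labels, labels[1:])
                 if a == NON_TRANSLATING and b == TRANSLATING]
        assert not flips


class TestTranslatingFraction:
    def test_all_translating(self):
        msds = [TrajectoryMsd(str(i), 0.01, 11, TRANSLATING) for i in range(10)]
        assert translating_fraction(msds) == 1.0

    def test_unclassified_excluded(self):
        msds = [TrajectoryMsd("0", 0.01, 11, TRANSLATING),
                TrajectoryMsd("1", 0.2, 11, NON_TRANSLATING),
                TrajectoryMsd("2", 0.0, 2, UNCLASSIFIED)]
        assert translating_fraction(msds) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no classified"):
            translating_fraction([])
        with pytest.raises(ValueError, match="no classified"):
            translating_fraction([TrajectoryMsd("0", 0.0, 2, UNCLASSIFIED)])

    def test_reorder_invariant(self, rng):
        msds = [TrajectoryMsd(str(i), 0.01 if i % 3 else 0.2, 11,
                              TRANSLATING if i % 3 else NON_TRANSLATING)
                for i in range(30)]
        shuffled = list(msds)
        rng.shuffle(shuffled)
        assert translating_fraction(shuffled) == translating_fraction(msds)

    def test_mixture_recovery_30pct(self):
        """Ground-truth 30% confined mixture recovered within binomial CI."""
        n = 600
        ts, gt = simulate_mixture(0.3, free_d=0.1, confined_d=0.5,
                                  confinement_radius=0.1, n_particles=n, seed=21)
        frac = translating_fraction(classify_trajectories(ts.trajectories))
        ci = 1.96 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) <= ci


class TestEnsembleMsd:
    def test_stationary_all_zero(self, stationary_track):
        ens = ensemble_msd([stationary_track], max_lag=4)
        np.testing.assert_array_equal(ens.msd_values, 0.0)

    def test_matches_brute_force_pair_average(self, rng):
        """Direct average over all displacement pairs at each lag."""
        trajs = [make_trajectory(rng.normal(5, 1, size=(rng.integers(5, 12), 2)),
                                 track_id=str(i)) for i in range(8)]
        ens = ensemble_msd(trajs, max_lag=4)
        for k, lag in enumerate(ens.lag_times):
            kf = int(round(lag))
            sds = []
            for tr in trajs:
                xy = tr.xy
                for i in range(len(xy) - kf):
                    sds.append(((xy[i + kf] - xy[i]) ** 2).sum())
            assert ens.msd_values[k] == pytest.approx(np.mean(sds), rel=1e-12)

    def test_simulated_slope(self):
        cfg = SimulationConfig(diffusion_coefficients=[0.05], fractions=[1.0],
                               n_particles=300, n_steps=30, seed=13)
        ts, _ = simulate_brownian(cfg)
        ens = ensemble_msd(ts.trajectories, max_lag=4)
        np.testing.assert_allclose(ens.msd_values, 4 * 0.05 * ens.lag_times, rtol=0.05)

    def test_long_lags_omitted(self):
        xy = np.zeros((6, 2))
        ens = ensemble_msd([make_trajectory(xy)], max_lag=20)
        assert ens.lag_times.max() <= 5


class TestFitDapp:
    def test_exact_line_recovers_parameters(self):
        tau = np.arange(1.0, 9.0)
        from ertrack.motion import EnsembleMsdFit

        ens = EnsembleMsdFit(lag_times=tau, msd_values=4 * 0.05 * tau + 4 * 0.02**2,
                             n_per_lag=np.full(8, 100))
        ens = fit_dapp(ens)
        assert ens.d_app == pytest.approx(0.05)
        assert ens.sigma == pytest.approx(0.02)
        assert not ens.clamped

    def test_constant_msd_gives_zero_d(self):
        from ertrack.motion import EnsembleMsdFit

        tau = np.arange(1.0, 5.0)
        ens = fit_dapp(EnsembleMsdFit(lag_times=tau, msd_values=np.full(4, 4 * 0.03**2),
                                      n_per_lag=np.full(4, 10)))
        assert ens.d_app == pytest.approx(0.0, abs=1e-12)
        assert ens.sigma == pytest.approx(0.03)

    def test_negative_slope_clamped_and_flagged(self):
        from ertrack.motion import EnsembleMsdFit

        tau = np.arange(1.0, 5.0)
        ens = fit_dapp(EnsembleMsdFit(lag_times=tau, msd_values=0.1 - 0.01 * tau,
                                      n_per_lag=np.full(4, 10)))
        assert ens.d_app == 0.0
        assert ens.clamped

    def test_too_few_lags_raises(self):
        from ertrack.motion import EnsembleMsdFit

        ens = EnsembleMsdFit(lag_times=np.array([1.0, 2.0]),
                             msd_values=np.array([0.1, 0.2]), n_per_lag=np.array([5, 5]))
        with pytest.raises(ValueError, match="lag points"):
            fit_dapp(ens)


class TestCdfMixture:
    def test_pure_brownian_dominant_component(self):
        """Three-component fit of one-species data: dominant A ≥ 0.95, D within 10%."""
        r = sample_displacements_cdf([1.0], [0.05], 1.0, n=4000, seed=31)
        fit = fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=3, seed=1)
        i = int(np.argmax(fit.fractions))
        assert fit.fractions[i] >= 0.95
        assert fit.diffusion_coefficients[i] == pytest.approx(0.05, rel=0.10)

    def test_model_cdf_zero_at_origin_and_monotone(self):
        fit = CdfMixtureFit(fractions=np.array([0.3, 0.7]),
                            diffusion_coefficients=np.array([0.5, 0.01]),
                            lag_t=1.0, rss=0.0, n_components_used=2)
        r = np.linspace(0, 3, 500)
        cdf = evaluate_mixture_cdf(fit, r)
        assert cdf[0] == 0.0
        assert np.all(np.diff(cdf) >= 0)

    def test_three_population_recovery(self):
        """A=(0.3,0.4,0.3), D=(0.5,0.05,0.005), n=5000: fractions ±0.05, D within 2×."""
        a_true = [0.3, 0.4, 0.3]
        d_true = [0.5, 0.05, 0.005]
        r = sample_displacements_cdf(a_true, d_true, 1.0, n=5000, seed=32)
        fit = fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=3, seed=2)
        assert fit.n_components_used == 3
        np.testing.assert_allclose(fit.fractions, a_true, atol=0.05)
        for d_hat, d in zip(fit.diffusion_coefficients, d_true):
            assert d / 2 <= d_hat <= d * 2

    def test_fractions_sum_to_one(self):
        r = sample_displacements_cdf([0.5, 0.5], [0.3, 0.01], 1.0, n=1000, seed=33)
        fit = fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=2, seed=3)
        assert fit.fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fit.diffusion_coefficients) <= 0)  # descending D

    def test_close_components_merged_with_flag(self):
        r = sample_displacements_cdf([1.0], [0.05], 1.0, n=2000, seed=34)
        fit = fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=2, seed=4)
        if fit.merged:  # merge happens when the two D land within 2x
            assert fit.n_components_used < 2
            assert fit.fractions.sum() == pytest.approx(1.0)

    def test_model_selection_picks_one_for_single_species(self):
        r = sample_displacements_cdf([1.0], [0.05], 1.0, n=3000, seed=35)
        fit = fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=None, seed=5)
        assert fit.fractions.max() >= 0.95

    def test_small_sample_warns(self, caplog):
        r = sample_displacements_cdf([1.0], [0.05], 1.0, n=50, seed=36)
        with caplog.at_level("WARNING"):
            fit_cdf_mixture(DisplacementSample(r=r, lag_t=1.0), n_components=1, seed=6)
        assert "100" in caplog.text

    def test_pooled_displacements(self):
        xy = np.column_stack([0.1 * np.arange(5), np.zeros(5)])
        s = pooled_displacements([make_trajectory(xy)], lag_frames=1)
        np.testing.assert_allclose(s.r, 0.1)
        assert s.lag_t == 1.0
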
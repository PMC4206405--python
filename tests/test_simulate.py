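"""Forward simulation, regime shifts, the lake fixture and experiments."""
import numpy as np
import pytest

from mwmar import InputError, MARParams, MaskSpec, fit_mar, stability_lambda
from mwmar.model import predict_one_step
from mwmar.simulate import (
    RegimeConfig,
    lake_washington_fixture,
    lake_washington_params,
    simulate_mar,
    simulate_regime_shift,
    transition_bias_experiment,
    window_size_experiment,
)


class TestSimulateMar:
    def test_noise_free_equals_iterated_prediction(self):
        params = MARParams(a=[0.3, -0.1], b=[[0.7, 0.1], [0.0, 0.5]],
                           sigma2=[0.0, 0.0])
        panel = simulate_mar(params, T=20, x0=[1.0, 2.0], seed=0)
        x = np.array([1.0, 2.0])
        for t in range(1, 20):
            x = predict_one_step(params, x)
            assert np.allclose(panel.values[t], x, atol=1e-12)

    def test_seed_determinism_and_independence(self, stable_params_2):
        p1 = simulate_mar(stable_params_2, T=50, seed=9)
        p2 = simulate_mar(stable_params_2, T=50, seed=9)
        p3 = simulate_mar(stable_params_2, T=50, seed=10)
        assert np.array_equal(p1.values, p2.values)
        assert not np.array_equal(p1.values, p3.values)

    def test_scalar_closed_form_moments(self):
        params = MARParams(a=[0.0], b=[[0.5]], sigma2=[1.0])
        panel = simulate_mar(params, T=50000, seed=31)
        x = panel.values.ravel()
        assert abs(x.mean()) < 0.02 * np.sqrt(1 / (1 - 0.25))  # mean 0
        assert x.var(ddof=1) == pytest.approx(1 / (1 - 0.25), rel=0.02)

    def test_invalid_inputs(self, stable_params_2):
        with pytest.raises(InputError):
            simulate_mar(stable_params_2, T=1)
        with pytest.raises(InputError):
            simulate_mar(stable_params_2, T=10, x0=[1.0])


class TestRegimeShift:
    def test_no_breakpoints_identical_to_plain_simulation(self, stable_params_2):
        cfg = RegimeConfig(regimes=[stable_params_2], breakpoints=[], T=60, seed=4)
        panel, _, truth = simulate_regime_shift(cfg)
        plain = simulate_mar(stable_params_2, T=60, seed=4)
        assert np.array_equal(panel.values, plain.values)
        assert np.all(truth.regime_index == 0)

    def test_noise_free_switch_changes_dynamics_at_breakpoint(self):
        r1 = MARParams(a=[0.0], b=[[0.8]], sigma2=[0.0])
        r2 = MARParams(a=[0.0], b=[[0.3]], sigma2=[0.0])
        cfg = RegimeConfig(regimes=[r1, r2], breakpoints=[10], T=20,
                           x0=np.array([1.0]), seed=0)
        panel, _, truth = simulate_regime_shift(cfg)
        x = panel.values.ravel()
        pre_ratio = x[5] / x[4]
        post_ratio = x[15] / x[14]
        assert pre_ratio == pytest.approx(0.8, abs=1e-10)
        assert post_ratio == pytest.approx(0.3, abs=1e-10)

    def test_truth_round_trips_to_zero_error(self):
        regimes, bps = lake_washington_params()
        cfg = RegimeConfig(regimes=regimes, breakpoints=bps, T=396, seed=1,
                           covariates=None)
        # strip covariates for this check
        stripped = [MARParams(r.a, r.b, None, r.sigma2) for r in regimes]
        cfg = RegimeConfig(regimes=stripped, breakpoints=bps, T=396, seed=1)
        _, _, truth = simulate_regime_shift(cfg)
        for t in (0, 119, 120, 179, 180, 395):
            expected = stripped[truth.regime_index[t]]
            assert np.array_equal(truth.params_at(t).b, expected.b)

    def test_invalid_breakpoints_rejected(self, stable_params_2):
        with pytest.raises(InputError):
            RegimeConfig(regimes=[stable_params_2, stable_params_2],
                         breakpoints=[0], T=50)
        with pytest.raises(InputError):
            RegimeConfig(regimes=[stable_params_2], breakpoints=[10], T=50)


class TestLakeFixture:
    def test_dimensions_and_names(self):
        panel, covars, mask, truth = lake_washington_fixture(seed=0)
        assert panel.frame.shape == (396, 4)
        assert covars.frame.shape == (396, 3)
        assert panel.taxon_names == ["DG", "NDC", "Daphnia", "Oscillatoria"]
        assert mask.b_mask.sum() == 15
        assert mask.c_mask.sum() == 10

    def test_covariates_standardized_over_full_series(self):
        _, covars, _, _ = lake_washington_fixture(seed=3)
        covars.check_standardized()

    def test_zero_inflation_pattern(self):
        panel, _, _, truth = lake_washington_fixture(seed=0)
        dmin = panel.frame["Daphnia"].min()
        omin = panel.frame["Oscillatoria"].min()
        daph_zero_early = (panel.frame["Daphnia"].iloc[:120] == dmin).mean()
        daph_zero_late = (panel.frame["Daphnia"].iloc[180:] == dmin).mean()
        osc_zero_early = (panel.frame["Oscillatoria"].iloc[:120] == omin).mean()
        osc_zero_late = (panel.frame["Oscillatoria"].iloc[180:] == omin).mean()
        assert daph_zero_early > 5 * max(daph_zero_late, 0.01)
        assert osc_zero_late > 5 * max(osc_zero_early, 0.01)

    def test_transition_phase_least_stable_in_truth(self):
        regimes, _ = lake_washington_params()
        lams = [stability_lambda(r.b) for r in regimes]
        assert lams[1] == max(lams)
        assert lams[2] == min(lams)

    def test_seed_changes_panel(self):
        p0, _, _, _ = lake_washington_fixture(seed=0)
        p1, _, _, _ = lake_washington_fixture(seed=1)
        assert not np.array_equal(p0.values, p1.values)

    def test_cyanobacterium_grazer_effect_fades_after_regime_shift(self):
        """Osc->Daphnia: significantly negative early, non-significant late."""
        from mwmar.bootstrap import bootstrap_intervals, is_significant
        panel, covars, mask, _ = lake_washington_fixture(seed=0)
        i, j = 2, 3  # response Daphnia, predictor Oscillatoria
        early_sig_neg, late_nonsig = [], []
        for end in range(84, 396, 12):
            yw = panel.window(end - 84, end + 1)
            uw = covars.window(end - 84, end + 1)
            fit = fit_mar(yw, uw, mask)
            iv = bootstrap_intervals(fit, yw, uw, mask, n_boot=200, seed=end)
            sig = is_significant(iv.b_lo[i, j], iv.b_hi[i, j])
            if end < 120:           # windows wholly in the eutrophic phase
                early_sig_neg.append(sig and iv.b_hi[i, j] < 0)
            elif end >= 264:        # windows wholly in the clear-water phase
                late_nonsig.append(not sig)
        assert np.mean(early_sig_neg) >= 2 / 3
        assert np.mean(late_nonsig) >= 0.8

    def test_stability_trajectory_peaks_during_transition(self):
        from mwmar.window import moving_window_fit
        panel, covars, mask, _ = lake_washington_fixture(seed=0)
        traj = moving_window_fit(panel, covars, mask, 84)
        lam = traj.lambda_series()
        argmax_pos = 84 + int(np.argmax(lam.to_numpy()))
        # peak lies in windows overlapping the transition phase (120..180)
        assert 120 < argmax_pos < 180 + 84
        # clear-water windows are the most stable stretch
        late = lam.to_numpy()[264 - 84:]
        assert late.mean() < lam.to_numpy()[:120 - 84].mean()


class TestWindowSizeExperiment:
    def test_noise_free_single_rep_zero_rmse(self):
        params = MARParams(a=[0.2, 0.0], b=[[0.6, 0.1], [0.2, 0.5]],
                           sigma2=[0.0, 0.0])
        # start off the fixed point so lag columns are not constant
        rng_x0 = np.array([2.0, -1.0])

        import mwmar.simulate as sim

        tab = sim.window_size_experiment(params, sizes=[10, 20], n_reps=1,
                                         T=60, seed=0)
        # degenerate noise-free runs may fail to fit once the transient dies;
        # any fitted coefficient must be exact
        fitted = tab.table.dropna()
        if len(fitted):
            assert (fitted.rmse < 1e-6).all()

    def test_rmse_decreases_with_window_size(self):
        params = MARParams(a=[0.2, 0.0], b=[[0.6, 0.1], [0.2, 0.5]],
                           sigma2=[0.2, 0.2])
        tab = window_size_experiment(params, sizes=[24, 48, 96], n_reps=30,
                                     T=200, seed=6)
        offdiag = ["b:taxon0<-taxon1", "b:taxon1<-taxon0"]
        r = [tab.mean_rmse(s, offdiag) for s in (24, 48, 96)]
        assert r[0] > r[1] > r[2]

    def test_rmse_at_least_abs_bias(self):
        params = MARParams(a=[0.1], b=[[0.7]], sigma2=[0.3])
        tab = window_size_experiment(params, sizes=[30], n_reps=20, T=100, seed=2)
        assert (tab.table.rmse >= tab.table.bias.abs() - 1e-12).all()


@pytest.fixture(scope="module")
def transition_profile():
    r1 = MARParams(a=[0.1, 0.0], b=[[0.8, 0.0], [0.1, 0.5]],
                   sigma2=[0.05, 0.05])
    r2 = MARParams(a=[0.1, 0.0], b=[[0.3, 0.0], [0.1, 0.5]],
                   sigma2=[0.05, 0.05])
    cfg = RegimeConfig(regimes=[r1, r2], breakpoints=[150], T=320, seed=0)
    prof = transition_bias_experiment(cfg, w=84, n_reps=10, seed=1)
    return prof[prof.coefficient == "b:taxon0<-taxon0"]


class TestTransitionBiasExperiment:
    @pytest.fixture
    def profile(self, transition_profile):
        return transition_profile

    def test_within_regime_windows_nearly_unbiased(self, profile):
        # wholly pre/post windows: aggregate bias stays at the O(1/W)
        # autoregressive small-sample scale, well below the regime gap
        pre = profile[profile.offset <= -10]
        post = profile[profile.offset >= 94]
        assert abs(pre.mean_error.mean()) < 0.08
        assert abs(post.mean_error.mean()) < 0.08

    def test_straddling_windows_move_between_regimes(self, profile):
        mid = profile[(profile.offset > 0) & (profile.offset < 84)]
        assert ((mid.mean_estimate < 0.90) & (mid.mean_estimate > 0.15)).all()
        # traverse is decreasing in trend from old to new value
        assert mid.mean_estimate.iloc[0] > mid.mean_estimate.iloc[-1]

    def test_estimates_blend_regimes_when_window_exceeds_phase(self):
        r1 = MARParams(a=[0.0], b=[[0.8]], sigma2=[0.1])
        r2 = MARParams(a=[0.0], b=[[0.2]], sigma2=[0.1])
        cfg = RegimeConfig(regimes=[r1, r2], breakpoints=[40], T=80, seed=3)
        prof = transition_bias_experiment(cfg, w=70, n_reps=15, seed=5)
        # every window straddles; estimates sit between the regime values
        est = prof.mean_estimate
        assert est.between(0.2, 0.8).mean() > 0.9
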
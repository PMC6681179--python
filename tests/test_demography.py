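"""Scenario catalogue, epoch schedules, expected-SFS engines, likelihood, fitting."""

import numpy as np
import pytest

from divergekit import demography as dm
from divergekit.spectra import JointSFS


def model(name, **params):
    return dm.DemographicModel.from_name(name, params)


class TestCatalogue:
    def test_thirty_four_scenarios(self):
        names = dm.model_catalogue()
        assert len(names) == 34
        assert len(set(names)) == 34
        assert "SI2M2P" not in names and "SI2M2Pex" not in names
        for name in names:
            cat, flags = dm.parse_model_name(name)
            assert dm.model_name(cat, flags) == name

    @pytest.mark.parametrize(
        "name,k",
        [("SI", 4), ("IM", 6), ("SC", 7), ("PSC", 7), ("PSCex", 10),
         ("PSC2M2Pex", 12), ("SC2N", 9), ("IM2Nex", 11)],
    )
    def test_free_parameter_counts(self, name, k):
        cat, flags = dm.parse_model_name(name)
        assert len(dm.param_names(cat, flags)) == k


class TestEpochSchedules:
    def test_si_single_isolated_epoch(self):
        sched = dm.build_epochs(model("SI", nu1=1, nu2=2, t_iso=0.5))
        assert len(sched.epochs) == 1
        e = sched.epochs[0]
        assert (e.m12, e.m21) == (0.0, 0.0)
        assert e.duration == 0.5

    def test_psc_contact_pattern(self):
        sched = dm.build_epochs(
            model("PSC", nu1=1, nu2=1, M12=2, M21=3, t_iso=0.4, t_sc=0.2))
        assert len(sched.epochs) == 4
        mig = [(e.m12, e.m21) for e in sched.epochs]
        assert mig == [(0, 0), (2, 3), (0, 0), (2, 3)]  # ends in contact
        assert [e.duration for e in sched.epochs] == [0.2, 0.1, 0.2, 0.1]

    def test_sc_with_zero_contact_degenerates_to_si(self):
        sc = dm.build_epochs(model("SC", nu1=1, nu2=2, M12=5, M21=5, t_iso=0.5, t_sc=0.0))
        si = dm.build_epochs(model("SI", nu1=1, nu2=2, t_iso=0.5))
        assert sc.epochs == si.epochs

    def test_growth_epoch_appended(self):
        sched = dm.build_epochs(
            model("SCex", nu1=2, nu2=3, M12=1, M21=1, t_iso=0.5, t_sc=0.2,
                  nu_a1=0.5, nu_a2=0.7, t_scg=0.1))
        assert len(sched.epochs) == 3
        grow = sched.epochs[-1]
        assert grow.is_exponential
        assert (grow.nu1_start, grow.nu1_end) == (0.5, 2)
        assert grow.m12 == 1  # SC ends in contact, growth keeps gene flow

    def test_missing_time_is_an_error(self):
        with pytest.raises(dm.ModelError):
            dm.build_epochs(model("SC", nu1=1, nu2=1, M12=1, M21=1, t_iso=0.5))


class TestMisid:
    def test_identity_at_o_one(self):
        M = np.arange(25.0).reshape(5, 5)
        assert np.array_equal(dm.apply_misid(M, 1.0), M)

    def test_half_is_reverse_symmetric_fixed_point(self):
        M = np.arange(25.0).reshape(5, 5)
        out = dm.apply_misid(M, 0.5000001)
        assert np.allclose(out, out[::-1, ::-1], atol=1e-5)

    def test_single_mass_hand_computation(self):
        M = np.zeros((5, 5))
        M[1, 0] = 1.0
        out = dm.apply_misid(M, 0.97)
        assert out[1, 0] == pytest.approx(0.97)
        assert out[3, 4] == pytest.approx(0.03)
        assert out.sum() == pytest.approx(1.0)

    def test_out_of_range_o_rejected(self):
        with pytest.raises(dm.ModelError):
            dm.apply_misid(np.ones((3, 3)), 0.4)


class TestExactEngine:
    def test_single_population_watterson(self):
        # constant-size single population: E[xi_i] proportional to 1/i
        e = dm.expected_sfs(model("SI", nu1=1, nu2=1, t_iso=1e-9), 10, 0)
        xi = e[1:10, 0]
        expected = 1.0 / np.arange(1, 10)
        ratio = xi / xi[0]
        assert np.abs(ratio - expected / expected[0]).max() < 5e-3

    def test_symmetric_im_transpose_invariance(self):
        m = model("IM", nu1=1.3, nu2=1.3, M12=2.5, M21=2.5, t_sc=0.8)
        e = dm.expected_sfs(m, 4, 4)
        assert np.abs(e - e.T).max() < 1e-8

    def test_2n_identity_mixture(self):
        base = model("SC", nu1=1.5, nu2=0.8, M12=2, M21=1, t_iso=0.5, t_sc=0.2)
        with_flag = model("SC2N", nu1=1.5, nu2=0.8, M12=2, M21=1, t_iso=0.5,
                          t_sc=0.2, nr=0.5, bf=1.0)
        assert np.allclose(dm.expected_sfs(base, 4, 4), dm.expected_sfs(with_flag, 4, 4),
                           rtol=1e-10)

    def test_marginal_matches_single_population(self):
        # no migration, equal split sizes, ancestral size 1: the pop-1
        # marginal of the joint SFS equals the one-population expectation
        m2 = model("SI", nu1=1.0, nu2=1.0, t_iso=0.6)
        joint = dm.expected_sfs(m2, 4, 4)
        single = dm.expected_sfs(model("SI", nu1=1.0, nu2=1.0, t_iso=0.6), 4, 0)
        marg = joint.sum(axis=1)
        assert np.allclose(marg[1:4], single[1:4, 0], rtol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_vs_monte_carlo(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = model(
            "SC",
            nu1=rng.uniform(0.3, 3), nu2=rng.uniform(0.3, 3),
            M12=rng.uniform(0, 5), M21=rng.uniform(0, 5),
            t_iso=rng.uniform(0.05, 1.5), t_sc=rng.uniform(0.05, 0.8),
        )
        exact = dm.expected_sfs(m, 4, 4)
        sched = dm.build_epochs(m)
        mc, se = dm._expected_sfs_mc(sched, 4, 4, n_replicates=1500, seed=seed + 1,
                                     return_se=True)
        free = ~JointSFS(np.zeros((5, 5)), 4, 4).mask
        z = (exact - mc)[free] / np.maximum(se[free], 1e-12)
        assert np.abs(z).max() < 3.0

    def test_large_samples_need_monte_carlo(self):
        with pytest.raises(dm.ModelError):
            dm.expected_sfs(model("SI", nu1=1, nu2=1, t_iso=0.5), 10, 10)


class TestCompositeLoglik:
    def _obs_exp(self):
        m = model("IM", nu1=1, nu2=1.5, M12=1, M21=2, t_sc=0.7)
        exp = dm.expected_sfs(m, 4, 4)
        return exp

    def test_poisson_mode_value(self):
        from scipy.stats import poisson

        exp = self._obs_exp()
        alpha = 50.0
        counts = np.round(alpha * exp)
        obs = JointSFS(counts, 4, 4)
        # profiled alpha-hat reproduces the Poisson log-pmf sum at its mode
        ll = dm.composite_loglik(obs, exp)
        free = ~obs.mask
        ahat = counts[free].sum() / exp[free].sum()
        direct = poisson.logpmf(counts[free], ahat * exp[free]).sum()
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_empty_observation_convention(self):
        obs = JointSFS(np.zeros((5, 5)), 4, 4)
        assert dm.composite_loglik(obs, self._obs_exp()) == 0.0

    def test_scale_profiling_invariance(self):
        exp = self._obs_exp()
        rng = np.random.default_rng(3)
        counts = rng.poisson(40 * exp).astype(float)
        obs1 = JointSFS(counts, 4, 4)
        obs2 = JointSFS(2 * counts, 4, 4)
        # doubling the expectation changes nothing (alpha-hat absorbs it)
        assert dm.composite_loglik(obs1, exp) == pytest.approx(
            dm.composite_loglik(obs1, 2 * exp))
        # model comparison is unaffected by doubling the data either
        exp_b = dm.expected_sfs(model("IM", nu1=1, nu2=1.5, M12=1, M21=2, t_sc=0.3), 4, 4)
        d1 = dm.composite_loglik(obs1, exp) - dm.composite_loglik(obs1, exp_b)
        d2 = dm.composite_loglik(obs2, exp) - dm.composite_loglik(obs2, exp_b)
        assert np.sign(d1) == np.sign(d2)

    def test_zero_expectation_with_data_is_minus_inf(self):
        exp = np.zeros((5, 5))
        exp[1, 1] = 1.0
        counts = np.zeros((5, 5))
        counts[2, 2] = 3
        obs = JointSFS(counts, 4, 4)
        with pytest.warns(UserWarning):
            assert dm.composite_loglik(obs, exp) == -np.inf


class TestFitMachinery:
    def _toy_observation(self, seed=0):
        m = model("IM", nu1=1.2, nu2=0.7, M12=2, M21=1, t_sc=0.5)
        exp = dm.expected_sfs(m, 4, 4)
        rng = np.random.default_rng(seed)
        return JointSFS(rng.poisson(2000 * exp / exp.sum()).astype(float), 4, 4)

    def test_seed_determinism(self):
        obs = self._toy_observation()
        kw = dict(n_starts=2, seed=9, fixed={"O": 1.0},
                  optimizer_options={"maxfev": 120})
        f1 = dm.fit_model(obs, "IM", **kw)
        f2 = dm.fit_model(obs, "IM", **kw)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params

    def test_refit_from_optimum_is_a_fixed_point(self):
        obs = self._toy_observation()
        fit = dm.fit_model(obs, "IM", n_starts=3, seed=2, fixed={"O": 1.0},
                           optimizer_options={"maxfev": 600})
        refit = dm.fit_model(
            obs, "IM", n_starts=0, seed=3, fixed={"O": 1.0},
            init_params={k: v for k, v in fit.params.items() if k != "O"},
            optimizer_options={"maxfev": 600})
        assert refit.loglik >= fit.loglik - 1e-6

    def test_true_model_beats_misspecified_neighbour_on_average(self):
        # composite lnL at the generating parameters exceeds a size-inflated
        # neighbour's on average over replicates
        m_true = model("IM", nu1=1.2, nu2=0.7, M12=2, M21=1, t_sc=0.5)
        m_bad = model("IM", nu1=3.6, nu2=2.1, M12=2, M21=1, t_sc=0.5)
        e_true = dm.expected_sfs(m_true, 4, 4)
        e_bad = dm.expected_sfs(m_bad, 4, 4)
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(10):
            obs = JointSFS(rng.poisson(1000 * e_true / e_true.sum()).astype(float), 4, 4)
            diffs.append(dm.composite_loglik(obs, e_true) - dm.composite_loglik(obs, e_bad))
        assert np.mean(diffs) > 0


class TestAicAndUnits:
    def test_aic_formula(self):
        f = dm.FitResult(model=model("SI", nu1=1, nu2=1, t_iso=1), params={},
                         loglik=0.0, k=0, aic=0.0)
        assert dm.aic(f) == 0.0

    def test_rank_models_orders_by_aic(self):
        fits = [
            dm.FitResult(model=model("SI", nu1=1, nu2=1, t_iso=1), params={},
                         loglik=-100.0, k=3, aic=206.0),
            dm.FitResult(model=model("IM", nu1=1, nu2=1, M12=1, M21=1, t_sc=1),
                         params={}, loglik=-90.0, k=5, aic=190.0),
        ]
        table = dm.rank_models(fits)
        assert list(table["model"]) == ["IM", "SI"]
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["delta_aic"].iloc[1] == pytest.approx(16.0)

    @pytest.mark.parametrize(
        "sd_over_est,band", [(0.1, ""), (0.35, "*"), (0.9, "**"), (2.0, "***")])
    def test_star_bands(self, sd_over_est, band):
        assert dm.star_band(sd_over_est * 2.0, 2.0) == band

    def test_unit_conversion(self):
        params = {"nu1": 1.0, "M12": 1.0, "t_iso": 0.0, "O": 0.97}
        out = dm.to_demographic_units(params, Nref=2_156_641, generation_time_years=1.0)
        assert out["N1"] == pytest.approx(2_156_641)
        assert out["Tiso_years"] == 0.0
        assert out["O"] == 0.97
        out2 = dm.to_demographic_units({"M12": 1.0}, Nref=1e6)
        assert out2["m12"] == pytest.approx(5e-7)

    def test_min_scaled_time(self):
        # ~50,000 years at Nref=2.1e6, 1-year generations
        t = dm.min_scaled_time(50_000, 2.1e6)
        assert t == pytest.approx(50_000 / (2 * 2.1e6))


class TestBootstrapUncertainty:
    def test_zero_variance_replicates_give_zero_sd(self):
        obs_exp = dm.expected_sfs(model("SI", nu1=1.2, nu2=0.8, t_iso=0.4), 4, 4)
        obs = JointSFS(np.round(500 * obs_exp / obs_exp.sum()), 4, 4)
        fit = dm.fit_model(obs, "SI", n_starts=2, seed=4, fixed={"O": 1.0},
                           optimizer_options={"maxfev": 400})
        reps = [obs.copy() for _ in range(4)]
        out = dm.bootstrap_uncertainty("SI", reps, fit, seed=1,
                                       optimizer_options={"maxfev": 150})
        assert all(sd <= 0.02 * abs(fit.params[n]) + 1e-6
                   for n, sd in out.bootstrap_sd.items())
        assert not out.flagged
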
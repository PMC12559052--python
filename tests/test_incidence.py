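"""Poisson GLMM: Laplace correctness, oracle equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from haekit.incidence import (FitError, IncidenceFit, estimate_incidence,
                              fit_poisson_glmm, individual_incidence,
                              laplace_loglik, position_median_minutes,
                              player_median_minutes)
from haekit.linking import count_haes_per_player_match, filter_wear_compliance
from haekit.reporting import truth_hae_records
from haekit.synthetic import simulate_dataset
from haekit.config import ThresholdGrid
from _oracles import agh_poisson_marginal_loglik, tiny_crossed_poisson
from conftest import single_position_sim, small_sim


def counts_frame(sim, seed=None, grid=None):
    grid = grid or ThresholdGrid()
    data = simulate_dataset(sim)
    pm = filter_wear_compliance(data.involvements, data.wear_periods,
                                data.cohort.player_matches)
    return count_haes_per_player_match(truth_hae_records(data.haes), pm, grid), data


class TestLaplace:
    def test_matches_quadrature_on_tiny_instance(self):
        y, pi, fi = tiny_crossed_poisson(rate=10.0, reps=5, seed=42)
        eta = np.full(y.size, np.log(10.0))
        ll, _ = laplace_loglik(y, eta, pi, fi, 3, 2, 0.5, 0.3)
        oracle = agh_poisson_marginal_loglik(y, eta, pi, fi, 3, 2, 0.5, 0.3)
        assert abs(ll - oracle) / abs(oracle) < 1e-4

    def test_collapses_to_plain_poisson_as_sigmas_vanish(self):
        y, pi, fi = tiny_crossed_poisson(rate=4.0, reps=3, seed=1)
        eta = np.full(y.size, np.log(4.0))
        ll, _ = laplace_loglik(y, eta, pi, fi, 3, 2, 0.0, 0.0)
        from scipy.special import gammaln
        plain = float((y * eta - np.exp(eta) - gammaln(y + 1)).sum())
        assert ll == pytest.approx(plain, rel=1e-8)


class TestFit:
    def test_sigma_zero_equals_glm_oracle(self):
        counts, _ = counts_frame(single_position_sim(seed=3, rate_per_min=0.1))
        fit = fit_poisson_glmm(counts, "n_pla_gt_10", fix_sigmas=(0.0, 0.0))
        X = np.column_stack([np.ones(len(counts)),
                             np.log(counts["playing_time"])])
        glm = sm.GLM(counts["n_pla_gt_10"], X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.beta.to_numpy(), glm.params, atol=1e-5)

    def test_single_position_rate_recovery(self):
        # lambda = 2 per 80 min at >10 g: rate 0.025/min
        counts, _ = counts_frame(single_position_sim(seed=4, rate_per_min=0.025,
                                                     n_teams=6, n_rounds=14))
        # generator magnitudes: only a fraction of HAEs exceed 10 g
        from haekit.synthetic import MagnitudeModel, _tail
        mm = MagnitudeModel()
        frac = 0.5 * (_tail(10.0, mm.carrier_logmean, mm.pla_logsd)
                      + _tail(10.0, mm.tackler_logmean, mm.pla_logsd))
        fit = fit_poisson_glmm(counts, "n_pla_gt_10")
        est = estimate_incidence(fit, 80.0, "prop")
        expected = 2.0 * frac
        assert est.ci_low < expected < est.ci_high
        assert est.mean == pytest.approx(expected, rel=0.25)

    def test_exposure_coefficient_near_one(self):
        counts, _ = counts_frame(small_sim(seed=5, n_rounds=16))
        fit = fit_poisson_glmm(counts, "n_pla_gt_10")
        se = np.sqrt(np.diag(fit.vcov_beta))[list(fit.beta.index).index("log_minutes")]
        assert fit.beta["log_minutes"] == pytest.approx(1.0, abs=3 * se + 0.05)

    def test_relabelling_and_row_permutation_equivariance(self):
        counts, _ = counts_frame(small_sim(seed=6))
        fit1 = fit_poisson_glmm(counts, "n_pla_gt_25")
        shuffled = counts.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["player_id"] = "x" + shuffled["player_id"]
        shuffled["fixture_id"] = "x" + shuffled["fixture_id"]
        fit2 = fit_poisson_glmm(shuffled, "n_pla_gt_25")
        # identical optima up to the outer optimiser's stopping tolerance
        assert np.allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-3)
        assert fit1.sigma_player == pytest.approx(fit2.sigma_player, abs=1e-3)

    def test_estimates_monotone_in_threshold(self):
        counts, _ = counts_frame(small_sim(seed=7, n_rounds=10))
        means = []
        for t in (10, 25, 40):
            fit = fit_poisson_glmm(counts, f"n_pla_gt_{t}")
            means.append(estimate_incidence(fit, 80.0, "prop").mean)
        assert means[0] >= means[1] >= means[2]

    def test_all_zero_counts_degenerate(self):
        counts, _ = counts_frame(small_sim(seed=8))
        counts["n_zero"] = 0
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_poisson_glmm(counts, "n_zero")
        est = estimate_incidence(fit, 80.0, "prop")
        assert est.mean == 0.0 and est.ci_high == 0.0

    def test_needs_two_players_and_fixtures(self):
        df = pd.DataFrame({"player_id": ["P1"] * 4, "fixture_id": ["F1"] * 4,
                           "position": "prop", "playing_time": 40.0,
                           "n": [1, 2, 0, 1]})
        with pytest.raises(FitError):
            fit_poisson_glmm(df, "n")


class TestEstimates:
    @staticmethod
    def _toy_fit(modes):
        players = list(modes)
        return IncidenceFit(
            threshold=("pla", 25.0),
            beta=pd.Series({"(Intercept)": np.log(2.0) - np.log(80.0),
                            "log_minutes": 1.0}),
            vcov_beta=np.zeros((2, 2)),
            sigma_player=0.3, sigma_fixture=0.1,
            player_modes=pd.Series(modes),
            player_cond_sd=pd.Series(0.0, index=players),
            fixture_modes=pd.Series(dtype=float),
            player_position=pd.Series("prop", index=players),
            loglik=0.0, grad_norm=0.0, converged=True, offset_time=False,
            positions=["prop"])

    def test_proportional_scaling_when_time_coefficient_one(self):
        fit = self._toy_fit({"P1": 0.0})
        assert estimate_incidence(fit, 80.0, "prop").mean == pytest.approx(2.0)
        assert estimate_incidence(fit, 40.0, "prop").mean == pytest.approx(1.0)

    def test_full_match_position_denominators_agree(self):
        counts, _ = counts_frame(small_sim(seed=9))
        fit = fit_poisson_glmm(counts, "n_pla_gt_10")
        a = estimate_incidence(fit, 80.0, "wing", denominator="full_match_80")
        b = estimate_incidence(fit, 80.0, "wing", denominator="median_playing_time")
        assert a.mean == b.mean and a.ci_low == b.ci_low

    def test_zero_mode_player_equals_position_estimate(self):
        fit = self._toy_fit({"P1": 0.0})
        ind = individual_incidence(fit, "P1", 80.0)
        grp = estimate_incidence(fit, 80.0, "prop")
        assert ind.mean == pytest.approx(grp.mean)

    def test_threefold_intercept_ratio(self):
        fit = self._toy_fit({"P1": 0.0, "P2": np.log(3.0)})
        a = individual_incidence(fit, "P1", 80.0)
        b = individual_incidence(fit, "P2", 80.0)
        assert b.mean / a.mean == pytest.approx(3.0)

    def test_unknown_position_or_player(self):
        fit = self._toy_fit({"P1": 0.0})
        with pytest.raises(KeyError):
            estimate_incidence(fit, 80.0, "scrum-half")
        with pytest.raises(KeyError):
            individual_incidence(fit, "P9", 80.0)

    def test_elevated_player_flagged_above_population(self):
        # one simulated player with a +1.6 log-rate intercept stands clear
        # of the population-mean interval
        sim = single_position_sim(seed=10, rate_per_min=0.05, n_teams=6,
                                  n_rounds=14, player_sd=0.0)
        data = simulate_dataset(sim)
        haes = truth_hae_records(data.haes)
        target = data.cohort.players["player_id"].iloc[0]
        pm_t = data.cohort.player_matches.query("player_id == @target")
        rng = np.random.default_rng(0)
        extra = []
        for _, r in pm_t.iterrows():
            base = 0.05 * r["playing_time"]
            n_extra = rng.poisson(base * (np.exp(1.6) - 1.0))
            for j in range(n_extra):
                extra.append({"hae_id": f"X{len(extra)}", "player_id": target,
                              "fixture_id": r["fixture_id"], "timestamp": 0.0,
                              "pla_g": 15.0, "paa_rads2": 1200.0,
                              "rvci_rads": 8.2, "noise_class": 0,
                              "applied_cutoff_hz": 200.0})
        haes = pd.concat([haes, pd.DataFrame(extra)], ignore_index=True)
        pm = filter_wear_compliance(data.involvements, data.wear_periods,
                                    data.cohort.player_matches)
        counts = count_haes_per_player_match(haes, pm, ThresholdGrid())
        fit = fit_poisson_glmm(counts, "n_pla_gt_10")
        grp = estimate_incidence(fit, 80.0, "prop")
        ind = individual_incidence(fit, target, 80.0)
        assert fit.player_modes.loc[target] == fit.player_modes.max()
        assert ind.ci_low > grp.ci_high


def test_median_minute_helpers():
    pm = pd.DataFrame({"player_id": ["a", "a", "b"], "position": ["prop"] * 3,
                       "playing_time": [30.0, 50.0, 80.0]})
    assert position_median_minutes(pm)["prop"] == 50.0
    assert player_median_minutes(pm)["a"] == 40.0
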
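"""Ordinal mixed model: banding, oracle equivalence, recovery, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from haekit.config import AnalysisConfig, ThresholdGrid
from haekit.linking import NO_HAE
from haekit.probability import (band_probabilities, build_ordinal_outcome,
                                exceedance_probabilities, fit_clmm,
                                individual_probabilities, simulate_ordinal_outcomes)

CUTS = np.array([-0.5, 0.8, 2.0])


def inv_with_maxima(max_plas, roles=None, in_wear=True):
    n = len(max_plas)
    roles = roles or ["tackler"] * n
    return pd.DataFrame({
        "involvement_id": [f"I{i}" for i in range(n)],
        "tackle_event_id": [f"E{i}" for i in range(n)],
        "player_id": "P1", "fixture_id": "F1",
        "timestamp": np.arange(n, dtype=float),
        "role": roles, "tackle_sequence": "one-on-one",
        "in_wear": in_wear,
        "max_pla": max_plas,
        "max_paa": [np.nan if np.isnan(v) else v * 80 for v in max_plas],
        "max_rvci": [np.nan if np.isnan(v) else v * 0.55 for v in max_plas],
    })


class TestBanding:
    def test_band_assignment(self, grid):
        inv = inv_with_maxima([27.0, np.nan, 9.0, 25.0, 80.0])
        out = build_ordinal_outcome(inv, grid, "pla")
        assert list(out["category"]) == [3, 0, 1, 2, 6]
        assert out["category_label"].iloc[0] == "(25, 40]"
        assert out["category_label"].iloc[1] == NO_HAE
        assert out["category_label"].iloc[2] == "<= 10 (recorded)"
        assert out["category_label"].iloc[3] == "(10, 25]"  # upper-inclusive
        assert out["category_label"].iloc[4] == "> 70"

    def test_negative_maxima_rejected(self, grid):
        with pytest.raises(ValueError):
            build_ordinal_outcome(inv_with_maxima([-1.0]), grid, "pla")

    def test_out_of_wear_dropped(self, grid):
        inv = inv_with_maxima([27.0, 12.0])
        inv.loc[1, "in_wear"] = False
        out = build_ordinal_outcome(inv, grid, "pla")
        assert len(out) == 1


class TestFit:
    def test_sigma_zero_equals_ordered_model_oracle(self):
        out = simulate_ordinal_outcomes(20, 8, 10, CUTS, 0.5, (0, 0, 0), seed=7)
        fit = fit_clmm(out, fix_sigmas=(0.0, 0.0, 0.0))
        x = (out["role"] == "ball-carrier").astype(float).to_numpy()
        res = OrderedModel(out["category"].to_numpy(), x[:, None],
                           distr="logit").fit(method="bfgs", disp=False)
        assert fit.beta_role == pytest.approx(res.params[0], abs=1e-4)
        sm_cuts = OrderedModel(out["category"].to_numpy(), x[:, None],
                               distr="logit").transform_threshold_params(
                                   res.params[1:])[1:-1]
        assert np.allclose(fit.cutpoints, sm_cuts, atol=1e-4)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)

    def test_role_effect_recovery_zero_sds(self):
        betas = []
        for seed in range(6):
            out = simulate_ordinal_outcomes(15, 8, 8, CUTS, 0.5, (0, 0, 0),
                                            seed=seed)
            betas.append(fit_clmm(out, fix_sigmas=(0.0, 0.0, 0.0)).beta_role)
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean() - 0.5) < 3 * mc_se + 0.02

    def test_monotone_relabelling_leaves_fit_unchanged(self):
        out = simulate_ordinal_outcomes(10, 6, 8, CUTS, 0.4, (0, 0, 0), seed=3)
        relabelled = out.copy()
        relabelled["category"] = relabelled["category"] * 10  # order-preserving
        relabelled.attrs = dict(out.attrs)
        fit1 = fit_clmm(out, fix_sigmas=(0.0, 0.0, 0.0))
        fit2 = fit_clmm(relabelled, fix_sigmas=(0.0, 0.0, 0.0))
        assert fit2.beta_role == pytest.approx(fit1.beta_role, abs=1e-6)

    def test_empty_category_merged_with_warning(self):
        out = simulate_ordinal_outcomes(10, 6, 8, CUTS, 0.4, (0, 0, 0), seed=3)
        out = out[out["category"] != 2].reset_index(drop=True)
        out.attrs["labels"] = ["cat0", "cat1", "cat2", "cat3"]
        out.attrs["thresholds"] = (1.0, 2.0)
        with pytest.warns(UserWarning, match="merged"):
            fit = fit_clmm(out, fix_sigmas=(0.0, 0.0, 0.0))
        assert "cat2" in fit.merged_categories


@pytest.fixture(scope="module")
def fitted_model():
    cuts = np.array([0.3, 2.7, 4.5, 5.6])
    out = simulate_ordinal_outcomes(30, 8, 10, cuts, 0.35, (0.1, 0.35, 0.0),
                                    seed=11)
    return fit_clmm(out)


class TestExceedance:
    def test_complement_identity_at_lowest_boundary(self, fitted_model):
        exc = exceedance_probabilities(fitted_model, (0.0,), n_boot=400,
                                       re_draws=400, seed=5)
        bands = band_probabilities(fitted_model, n_boot=400, re_draws=400, seed=5)
        for role in ("ball-carrier", "tackler"):
            p_any = exc[exc["role"] == role]["probability"].iloc[0]
            p_none = bands[(bands["role"] == role)
                           & (bands["category_label"] == "cat0")]["probability"].iloc[0]
            assert p_any == pytest.approx(1.0 - p_none, abs=1e-9)

    def test_band_probabilities_sum_to_one(self, fitted_model):
        bands = band_probabilities(fitted_model, n_boot=300, re_draws=300, seed=2)
        sums = bands.groupby("role")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_exceedance_monotone_in_threshold(self, fitted_model):
        thr = (0.0, 1.0, 2.0, 3.0)
        exc = exceedance_probabilities(fitted_model, thr, n_boot=300,
                                       re_draws=300, seed=3)
        for role, g in exc.groupby("role"):
            p = g.sort_values("threshold")["probability"].to_numpy()
            assert (np.diff(p) <= 1e-12).all()

    def test_zero_role_effect_roles_agree(self):
        out = simulate_ordinal_outcomes(25, 8, 10, CUTS, 0.0, (0, 0, 0), seed=9)
        fit = fit_clmm(out, fix_sigmas=(0.0, 0.0, 0.0))
        exc = exceedance_probabilities(fit, (1.0,), n_boot=400, re_draws=1,
                                       seed=4)
        car = exc[exc["role"] == "ball-carrier"].iloc[0]
        tck = exc[exc["role"] == "tackler"].iloc[0]
        assert car["ci_low"] <= tck["probability"] <= car["ci_high"]

    def test_bootstrap_converges_with_draws(self, fitted_model):
        a = exceedance_probabilities(fitted_model, (1.0,), n_boot=2000,
                                     re_draws=300, seed=6)
        b = exceedance_probabilities(fitted_model, (1.0,), n_boot=4000,
                                     re_draws=300, seed=6)
        diff = np.abs(a["probability"].to_numpy() - b["probability"].to_numpy())
        assert (diff < 0.001).all()  # < 0.1 percentage point

    def test_small_n_boot_warns(self, fitted_model):
        with pytest.warns(UserWarning, match="n_boot"):
            exceedance_probabilities(fitted_model, (1.0,), n_boot=50,
                                     re_draws=10, seed=1)

    def test_unobserved_top_threshold_reported_as_zero(self, fitted_model):
        exc = exceedance_probabilities(fitted_model, (1e9,), n_boot=200,
                                       re_draws=10, seed=1)
        assert (exc["probability"] == 0.0).all()
        assert (~exc["boundary_observed"]).all()


class TestIndividual:
    @staticmethod
    def _player(player, n_carrier, n_tackler, exceed_carrier, exceed_tackler):
        rows = []
        for i in range(n_carrier):
            v = 30.0 if i < exceed_carrier else 12.0
            rows.append((player, "ball-carrier", v))
        for i in range(n_tackler):
            v = 30.0 if i < exceed_tackler else 12.0
            rows.append((player, "tackler", v))
        return rows

    def _frame(self, rows):
        df = pd.DataFrame(rows, columns=["player_id", "role", "max_pla"])
        df["involvement_id"] = [f"I{i}" for i in range(len(df))]
        df["tackle_event_id"] = df["involvement_id"]
        df["fixture_id"] = "F1"
        df["timestamp"] = 0.0
        df["in_wear"] = True
        df["max_paa"] = df["max_pla"] * 80
        df["max_rvci"] = df["max_pla"] * 0.55
        return df

    def test_direct_proportions(self, grid):
        df = self._frame(self._player("P1", 20, 23, 4, 8))
        out = individual_probabilities(df, grid)
        p_car = out.query("role == 'ball-carrier' and metric == 'pla' "
                          "and threshold == 25.0")["proportion"].iloc[0]
        p_tck = out.query("role == 'tackler' and metric == 'pla' "
                          "and threshold == 25.0")["proportion"].iloc[0]
        assert p_car == pytest.approx(0.20)
        assert p_tck == pytest.approx(8 / 23)

    def test_strict_involvement_rule_boundary(self, grid):
        rows = self._player("P_ok", 16, 16, 1, 1) + self._player("P_out", 16, 15, 1, 1)
        out = individual_probabilities(self._frame(rows), grid)
        assert set(out["player_id"]) == {"P_ok"}

    def test_out_of_wear_involvements_not_measured(self, grid):
        df = self._frame(self._player("P1", 20, 20, 4, 4))
        df.loc[df.index[:10], "in_wear"] = False  # drops carrier count to 10
        out = individual_probabilities(df, grid)
        assert out.empty
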
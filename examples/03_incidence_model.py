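"""Fit the Poisson mixed model of HAE incidence.

Simulates a season, applies the wear-compliance rule, counts HAEs above
25 g per player-match, and fits the Poisson GLMM with position and log
playing time as fixed effects and crossed player/fixture random
intercepts.  Prints per-position incidence under the two exposure
denominators and the most elevated individual player.
"""

import warnings

from haekit import (SimulationConfig, ThresholdGrid, simulate_dataset,
                    filter_wear_compliance, count_haes_per_player_match,
                    fit_poisson_glmm, estimate_incidence, individual_incidence,
                    position_median_minutes, player_median_minutes)
from haekit.reporting import truth_hae_records

warnings.filterwarnings("ignore")

sim = SimulationConfig(n_teams=6, n_rounds=12, participation_prob=0.6, seed=3)
data = simulate_dataset(sim)
grid = ThresholdGrid()

pm = filter_wear_compliance(data.involvements, data.wear_periods,
                            data.cohort.player_matches)
print(f"wear-compliant player-matches: {int(pm['included_for_incidence'].sum())}"
      f" of {len(pm)}")
counts = count_haes_per_player_match(truth_hae_records(data.haes), pm, grid)

fit = fit_poisson_glmm(counts, "n_pla_gt_25", threshold=("pla", 25.0))
print(f"random-intercept sds: player {fit.sigma_player:.2f}, "
      f"fixture {fit.sigma_fixture:.2f}")
print()
print("incidence of HAEs > 25 g (mean, 95% CI):")
medians = position_median_minutes(data.cohort.player_matches)
truth = data.truth.position_incidence.query("metric=='pla' and threshold==25.0")
for position in sorted(counts["position"].unique()):
    est = estimate_incidence(fit, float(medians[position]), position)
    tr = truth.loc[truth["position"] == position, "per_median"].iloc[0]
    print(f"  {position:14s} {est.mean:5.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})"
          f" per median playing time ({est.minutes:.0f} min); truth {tr:.2f}")
print()
ply_median = player_median_minutes(data.cohort.player_matches)
top = fit.player_modes.idxmax()
ind = individual_incidence(fit, top, float(ply_median[top]))
print(f"most elevated player {top} ({fit.player_position[top]}): "
      f"{ind.mean:.2f} ({ind.ci_low:.2f}-{ind.ci_high:.2f}) per median playing time")
print("The per-position truths typically fall inside the 95% intervals")
print("(roughly one in twenty lands just outside); the elevated player")
print("reflects their fitted random intercept.")
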
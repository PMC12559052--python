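"""Pipeline orchestration, result tables and the CI-overlap rule.

``run_pipeline`` chains simulate -> process -> link -> incidence ->
probability on synthetic (or supplied) data and writes the result
tables: per-position incidence under both exposure denominators
(full-match equivalent and position-median playing time), per-player
incidence at the headline threshold, role exceedance probabilities per
metric and threshold with bootstrap intervals, ordinal band
probabilities, per-player exceedance proportions, and carrier-tackler
comparison flags under the interval-overlap rule (two estimates are
deemed significantly different only when their confidence limits do not
overlap; a shared endpoint counts as overlap).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config
from .incidence import (fit_poisson_glmm, estimate_incidence, individual_incidence,
                        position_median_minutes, player_median_minutes)
from .kinematics import hae_records_frame, process_traces
from .linking import (count_haes_per_player_match, filter_wear_compliance,
                      link_haes_to_involvements, mark_wear,
                      max_magnitude_per_involvement, remove_sequential_tackles)
from .probability import (band_probabilities, build_ordinal_outcome,
                          exceedance_probabilities, fit_clmm,
                          individual_probabilities)
from .synthetic import SimulationConfig, SimulatedDataset, simulate_dataset

__all__ = ["ComparisonFlag", "compare_ci", "run_pipeline", "PipelineResult",
           "truth_hae_records"]


@dataclass(frozen=True)
class ComparisonFlag:
    """Interval-overlap comparison between two estimates."""

    estimate_a: str
    estimate_b: str
    overlap: bool
    significant: bool


def compare_ci(a, b, label_a: str = "a", label_b: str = "b") -> ComparisonFlag:
    """Overlap rule on closed intervals: ``max(lows) <= min(highs)``.

    ``a`` and ``b`` are (low, high) pairs or objects with ``ci_low`` /
    ``ci_high``.  Estimates sharing an endpoint overlap (not significant).
    """
    lo_a, hi_a = _interval(a)
    lo_b, hi_b = _interval(b)
    overlap = max(lo_a, lo_b) <= min(hi_a, hi_b)
    return ComparisonFlag(label_a, label_b, overlap, not overlap)


def _interval(x):
    if hasattr(x, "ci_low") and hasattr(x, "ci_high"):
        lo, hi = float(x.ci_low), float(x.ci_high)
    else:
        lo, hi = float(x[0]), float(x[1])
    if np.isnan(lo) or np.isnan(hi):
        raise ValueError("estimate has no confidence interval")
    return lo, hi


def truth_hae_records(haes: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth magnitude table in processed-record layout.

    Used on the fast (trace-free) path, where the drawn CoG peaks of the
    triggered events stand in for the signal-processing output.
    """
    sub = haes[haes["triggered"]] if "triggered" in haes.columns else haes
    return pd.DataFrame({
        "hae_id": sub["hae_id"],
        "player_id": sub["player_id"],
        "fixture_id": sub["fixture_id"],
        "timestamp": sub["timestamp"],
        "pla_g": sub["pla_true"],
        "paa_rads2": sub["paa_true"],
        "rvci_rads": sub["rvci_true"],
        "noise_class": sub["noise_class"],
        "applied_cutoff_hz": np.nan,
    }).reset_index(drop=True)


@dataclass
class PipelineResult:
    data: SimulatedDataset
    hae_records: pd.DataFrame
    player_matches: pd.DataFrame         # with compliance flags
    player_match_counts: pd.DataFrame    # included rows with per-threshold counts
    involvements: pd.DataFrame           # linked, with maxima
    incidence_group: pd.DataFrame
    incidence_individual: pd.DataFrame
    probability_group: pd.DataFrame
    probability_bands: pd.DataFrame
    probability_individual: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict


def run_pipeline(
    cfg: Config,
    sim: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    with_traces: bool = False,
    metrics: tuple[str, ...] = ("pla", "paa", "rvci"),
    n_boot: int | None = None,
) -> PipelineResult:
    """Execute every stage on a synthetic season and write all tables.

    With ``with_traces=True`` raw 6-DOF traces are generated and pushed
    through the full signal-processing chain; otherwise the drawn
    ground-truth peaks of triggered events are used directly (identical
    downstream statistics, far cheaper).  Deterministic given the
    simulation seed and config.
    """
    t_start = time.time()
    sim = sim or SimulationConfig(seed=cfg.analysis.rng_seed)
    n_boot = n_boot if n_boot is not None else cfg.analysis.n_bootstrap
    grid = cfg.thresholds
    timings: dict[str, float] = {}

    t0 = time.time()
    data = simulate_dataset(sim, kin=cfg.kinematics, grid=grid,
                            with_traces=with_traces)
    timings["simulate_s"] = round(time.time() - t0, 3)

    t0 = time.time()
    if with_traces and data.traces is not None:
        records = process_traces(data.traces, cfg.kinematics)
        hae_records = hae_records_frame(records)
    else:
        hae_records = truth_hae_records(data.haes)
    timings["process_s"] = round(time.time() - t0, 3)

    # --- linkage and inclusion rules --------------------------------------
    t0 = time.time()
    pm = filter_wear_compliance(data.involvements, data.wear_periods,
                                data.cohort.player_matches, cfg.analysis)
    involvements = mark_wear(data.involvements, data.wear_periods)
    involvements = remove_sequential_tackles(involvements)
    involvements, hae_records = link_haes_to_involvements(
        hae_records, involvements, window=cfg.analysis.link_window_s)
    involvements = max_magnitude_per_involvement(involvements, hae_records)
    counts = count_haes_per_player_match(hae_records, pm, grid)
    timings["link_s"] = round(time.time() - t0, 3)

    # --- incidence models -------------------------------------------------
    t0 = time.time()
    pos_median = position_median_minutes(data.cohort.player_matches)
    ply_median = player_median_minutes(data.cohort.player_matches)
    full_match = cfg.analysis.full_match_minutes
    inc_rows, ind_rows = [], []
    headline_col = f"n_pla_gt_{cfg.analysis.headline_pla:g}"
    for metric in metrics:
        for threshold in grid.for_metric(metric):
            col = f"n_{metric}_gt_{threshold:g}"
            fit = fit_poisson_glmm(counts, col, threshold=(metric, threshold))
            for position in sorted(counts["position"].unique()):
                for denom, minutes in (("full_match_80", full_match),
                                       ("median_playing_time", float(pos_median[position]))):
                    est = estimate_incidence(fit, minutes, position, denominator=denom)
                    inc_rows.append({"metric": metric, "threshold": threshold,
                                     "position": position, "denominator": denom,
                                     "minutes": minutes, "mean": est.mean,
                                     "ci_low": est.ci_low, "ci_high": est.ci_high})
            if metric == "pla" and threshold == cfg.analysis.headline_pla:
                for player in fit.player_modes.index:
                    if player not in ply_median.index:
                        continue
                    est = individual_incidence(fit, player, float(ply_median[player]))
                    ind_rows.append({"metric": metric, "threshold": threshold,
                                     "player_id": player,
                                     "position": fit.player_position.loc[player],
                                     "median_minutes": est.minutes, "mean": est.mean,
                                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    incidence_group = pd.DataFrame(inc_rows)
    incidence_individual = pd.DataFrame(ind_rows)
    timings["incidence_s"] = round(time.time() - t0, 3)

    # --- probability models -----------------------------------------------
    t0 = time.time()
    prob_rows, band_rows = [], []
    for metric in metrics:
        outcomes = build_ordinal_outcome(involvements, grid, metric)
        fit = fit_clmm(outcomes)
        exc = exceedance_probabilities(
            fit, grid.for_metric(metric), metric=metric, n_boot=n_boot,
            re_draws=cfg.analysis.bootstrap_re_draws, seed=cfg.analysis.rng_seed)
        prob_rows.append(exc)
        bands = band_probabilities(fit, n_boot=n_boot,
                                   re_draws=cfg.analysis.bootstrap_re_draws,
                                   seed=cfg.analysis.rng_seed)
        bands.insert(0, "metric", metric)
        band_rows.append(bands)
    probability_group = pd.concat(prob_rows, ignore_index=True)
    probability_bands = pd.concat(band_rows, ignore_index=True)
    probability_individual = individual_probabilities(involvements, grid, cfg.analysis)
    timings["probability_s"] = round(time.time() - t0, 3)

    # --- carrier vs tackler comparison flags ------------------------------
    comp_rows = []
    for (metric, threshold), g in probability_group.groupby(["metric", "threshold"]):
        car = g[g["role"] == "ball-carrier"].iloc[0]
        tck = g[g["role"] == "tackler"].iloc[0]
        flag = compare_ci((car["ci_low"], car["ci_high"]),
                          (tck["ci_low"], tck["ci_high"]),
                          f"ball-carrier:{metric}>{threshold:g}",
                          f"tackler:{metric}>{threshold:g}")
        comp_rows.append({"metric": metric, "threshold": threshold,
                          "overlap": flag.overlap, "significant": flag.significant})
    comparisons = pd.DataFrame(comp_rows)

    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "config_hash": _config_hash(cfg, sim),
        "n_players": int(len(data.cohort.players)),
        "n_fixtures": int(len(data.cohort.fixtures)),
        "n_player_matches": int(len(data.cohort.player_matches)),
        "n_player_matches_included": int(counts.shape[0]),
        "n_involvements": int(len(data.involvements)),
        "n_haes_recorded": int(len(hae_records)),
        "n_boot": int(n_boot),
        "with_traces": bool(with_traces),
        "timings": timings,
        "total_s": round(time.time() - t_start, 3),
    }

    result = PipelineResult(
        data=data, hae_records=hae_records, player_matches=pm,
        player_match_counts=counts, involvements=involvements,
        incidence_group=incidence_group, incidence_individual=incidence_individual,
        probability_group=probability_group, probability_bands=probability_bands,
        probability_individual=probability_individual,
        comparisons=comparisons, manifest=manifest)

    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _config_hash(cfg: Config, sim: SimulationConfig) -> str:
    payload = json.dumps({"config": _jsonable(asdict(cfg)),
                          "sim": _jsonable(asdict(sim))}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_results(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.hae_records.to_csv(out / "hae_records.csv", index=False)
    pm = result.player_matches.copy()
    pm.to_csv(out / "player_match_compliance.csv", index=False)
    result.player_match_counts.to_csv(out / "player_match_counts.csv", index=False)
    inv = result.involvements.copy()
    inv["linked_hae_ids"] = inv["linked_hae_ids"].map(";".join)
    inv.to_csv(out / "involvements_linked.csv", index=False)
    result.incidence_group.to_csv(out / "incidence_group.csv", index=False)
    result.incidence_individual.to_csv(out / "incidence_individual.csv", index=False)
    result.probability_group.to_csv(out / "probability_group.csv", index=False)
    result.probability_bands.to_csv(out / "probability_bands.csv", index=False)
    result.probability_individual.to_csv(out / "probability_individual.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
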
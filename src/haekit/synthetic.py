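"""Synthetic cohorts, match events, and raw 6-DOF sensor traces.

The generator emulates a league-wide instrumented-mouthguard study with
known ground truth, so that every downstream stage — signal processing,
event linkage, the incidence and probability models — can be tested
without any proprietary data.  Its defaults reproduce the study design it
stands in for: 12 teams, one player per position per team (96 players),
~8.3 recorded matches per player (~800 player-matches over a 27-round
season), position-specific median playing times (prop 41 min, hooker 54,
loose forward 52, all other positions 80), heavier tackle loads for
forwards, 34.2% of tackler involvements labelled sequential, and a
lognormal head-CoG peak-linear-acceleration magnitude model calibrated so
that the closed-form per-involvement exceedance probabilities at 10 g and
25 g equal 40.31%/6.29% for ball-carriers and 33.19%/4.26% for tacklers.

Generative model
----------------
* Playing time per player-match: a uniform-by-halves draw (lower half of
  [lo, median] with probability 1/2, upper half [median, hi] otherwise)
  whose endpoints are back-solved from the position's quartiles, so the
  theoretical median and IQR equal the configured ones exactly; clipped
  to [1, 80] and rounded to whole minutes.
* Involvements: carries and non-sequential tackles per player-match are
  independent Poisson draws with mean rate * (minutes/median) *
  exp(u_player + v_fixture); sequential "assist" tackles are drawn at a
  rate giving the configured long-run sequential fraction.  Every carry
  opens a tackle event and tackler involvements attach to a random
  opposing carry event, so an observed event groups whichever
  participants were instrumented (possibly a lone carrier or tackler).
* Recorded HAEs: each non-sequential involvement independently yields at
  most one HAE with a role-specific probability; its CoG PLA is
  lognormal by role, with PAA and RVCI as noisy proportional scalings of
  PLA.  Per-player-match HAE counts are therefore exactly Poisson with
  mean rate_per_min * minutes * exp(u + v) (Poisson thinning).
* Raw traces: each HAE becomes a half-sine linear-acceleration pulse at
  the head CoG plus a matched smooth angular-velocity ramp, mapped to the
  sensor frame by inverting the rigid-body CoG transform, embedded in a
  0.25 s carrier with class-dependent Gaussian sensor noise, and clipped
  at the +/-200 g / +/-35 rad/s measurement ranges.  Draws whose sensor
  trace never crosses the 8 g per-axis trigger emit no trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigError, KinematicsConfig, ThresholdGrid
from .kinematics import RawTrace, write_trace_csv

__all__ = [
    "PositionSpec",
    "MagnitudeModel",
    "SimulationConfig",
    "Cohort",
    "GroundTruth",
    "SimulatedDataset",
    "generate_cohort",
    "generate_match_events",
    "generate_hae_magnitudes",
    "generate_hae_traces",
    "expected_summaries",
    "simulate_dataset",
    "write_dataset",
]

MATCH_SECONDS = 80 * 60.0


@dataclass(frozen=True)
class PositionSpec:
    """One playing position: exposure and involvement rates.

    ``median_minutes`` and the quartiles ``q1``/``q3`` describe playing
    time per match; ``carries_per_match`` and ``tackles_per_match`` are
    expected involvement counts at the median playing time (tackles
    excluding sequential assists).  ``rate_per_min`` is the expected
    number of recorded HAEs per minute of play; when None it is derived
    from the involvement rates and the role HAE probabilities.
    """

    name: str
    group: Literal["forward", "back"]
    median_minutes: float
    q1: float
    q3: float
    carries_per_match: float
    tackles_per_match: float
    rate_per_min: float | None = None


@dataclass(frozen=True)
class MagnitudeModel:
    """Role-specific HAE occurrence and magnitude distributions.

    CoG-resultant PLA is lognormal per role; PAA and RVCI are
    deterministic scalings of PLA with multiplicative lognormal noise, so
    every threshold exceedance has a closed form.  ``hae_prob_*`` is the
    probability that a (non-sequential) involvement yields a recorded
    HAE.  The defaults are calibrated so per-involvement exceedance at
    10 g / 25 g equals 40.31%/6.29% (carrier) and 33.19%/4.26% (tackler).
    """

    carrier_logmean: float = 2.52037     # ln g; median ~12.4 g
    tackler_logmean: float = 2.43114     # ln g; median ~11.4 g
    pla_logsd: float = 0.55
    hae_prob_carrier: float = 0.61642
    hae_prob_tackler: float = 0.56026
    paa_scale: float = 80.0              # rad/s^2 per g (25 g <-> 2000 rad/s^2)
    paa_logsd: float = 0.18
    rvci_scale: float = 0.55             # rad/s per g
    rvci_logsd: float = 0.25


def _default_positions() -> tuple[PositionSpec, ...]:
    return (
        PositionSpec("fullback", "back", 80.0, 80.0, 80.0, 7.0, 2.0),
        PositionSpec("wing", "back", 80.0, 80.0, 80.0, 9.0, 2.0),
        PositionSpec("centre", "back", 80.0, 80.0, 80.0, 8.0, 5.0),
        PositionSpec("half", "back", 80.0, 80.0, 80.0, 4.0, 6.0),
        PositionSpec("prop", "forward", 41.0, 32.0, 49.0, 6.0, 10.0),
        PositionSpec("hooker", "forward", 54.0, 33.5, 72.5, 4.0, 12.0),
        PositionSpec("back row", "forward", 80.0, 61.0, 80.0, 7.0, 11.0),
        PositionSpec("loose forward", "forward", 52.0, 27.0, 74.0, 5.0, 10.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_teams: int = 12
    n_rounds: int = 27
    participation_prob: float = 0.307    # ~8.3 recorded matches per player
    position_table: tuple[PositionSpec, ...] = field(default_factory=_default_positions)
    magnitude_model: MagnitudeModel = field(default_factory=MagnitudeModel)
    player_sd: float = 0.45              # sd of player log-rate intercept
    fixture_sd: float = 0.15             # sd of fixture log-rate intercept
    sequential_fraction: float = 0.342   # of tackler involvements
    wear_miss_prob: float = 0.05         # P(involvement outside a wear period)
    noise_class_probs: tuple[float, float, float] = (0.925, 0.055, 0.020)
    noise_sd_a: tuple[float, float, float] = (0.2, 0.5, 1.2)      # g, by class
    noise_sd_w: tuple[float, float, float] = (0.01, 0.03, 0.08)   # rad/s, by class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_teams < 2 or self.n_teams % 2:
            raise ConfigError("n_teams must be an even number >= 2")
        if not 0.0 < self.participation_prob <= 1.0:
            raise ConfigError("participation_prob must lie in (0, 1]")
        if not 0.0 <= self.sequential_fraction < 1.0:
            raise ConfigError("sequential_fraction must lie in [0, 1)")
        if not 0.0 <= self.wear_miss_prob <= 1.0:
            raise ConfigError("wear_miss_prob must lie in [0, 1]")
        if self.player_sd < 0 or self.fixture_sd < 0:
            raise ConfigError("random-intercept sds must be >= 0")
        probs = self.noise_class_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("noise_class_probs must be a 3-simplex")
        for spec in self.position_table:
            if spec.carries_per_match < 0 or spec.tackles_per_match < 0:
                raise ConfigError(f"{spec.name}: involvement rates must be >= 0")
            if not spec.q1 <= spec.median_minutes <= spec.q3:
                raise ConfigError(f"{spec.name}: need q1 <= median <= q3")
            if spec.rate_per_min is not None and spec.rate_per_min < 0:
                raise ConfigError(f"{spec.name}: rate_per_min must be >= 0")

    # -- derived quantities ------------------------------------------------

    def position(self, name: str) -> PositionSpec:
        for spec in self.position_table:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown position {name!r}")

    def hae_probs(self, spec: PositionSpec) -> tuple[float, float]:
        """(p_carrier, p_tackler) for a position.

        With the default ``rate_per_min=None`` these are the magnitude
        model's role probabilities; an explicit per-position rate rescales
        both roles so that the expected HAE count per player-match is
        exactly rate_per_min * minutes * exp(u + v).
        """
        m = self.magnitude_model
        if spec.rate_per_min is None:
            return m.hae_prob_carrier, m.hae_prob_tackler
        base = (spec.carries_per_match * m.hae_prob_carrier
                + spec.tackles_per_match * m.hae_prob_tackler)
        if base <= 0:
            return 0.0, 0.0
        scale = spec.rate_per_min * spec.median_minutes / base
        pc = m.hae_prob_carrier * scale
        pt = m.hae_prob_tackler * scale
        if max(pc, pt) > 1.0:
            raise ConfigError(
                f"{spec.name}: rate_per_min={spec.rate_per_min} implies an HAE "
                f"probability above 1 per involvement")
        return pc, pt

    def derived_rate_per_min(self, spec: PositionSpec) -> float:
        """Expected recorded HAEs per minute of play for a position."""
        pc, pt = self.hae_probs(spec)
        return (spec.carries_per_match * pc + spec.tackles_per_match * pt) / spec.median_minutes


@dataclass
class Cohort:
    """Players, fixtures and player-matches of one simulated season."""

    players: pd.DataFrame        # player_id, team_id, position, group
    fixtures: pd.DataFrame       # fixture_id, home_team, away_team, round
    player_matches: pd.DataFrame  # player_id, fixture_id, position, group, playing_time


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    position_incidence: pd.DataFrame   # position, metric, threshold, per_median, per_full_match
    role_exceedance: pd.DataFrame      # role, metric, threshold, probability
    player_intercepts: dict[str, float]
    fixture_intercepts: dict[str, float]
    haes: pd.DataFrame | None = None   # per-HAE drawn peaks (filled by the generators)


@dataclass
class SimulatedDataset:
    cohort: Cohort
    involvements: pd.DataFrame
    wear_periods: pd.DataFrame
    haes: pd.DataFrame                  # drawn (ground-truth) HAE table
    truth: GroundTruth
    traces: list[RawTrace] | None = None


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _draw_minutes(spec: PositionSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-by-halves playing time: exact configured median and quartiles."""
    lo = 2.0 * spec.q1 - spec.median_minutes
    hi = 2.0 * spec.q3 - spec.median_minutes
    upper = rng.random(size) < 0.5
    out = np.where(
        upper,
        rng.uniform(spec.median_minutes, max(hi, spec.median_minutes), size),
        rng.uniform(min(lo, spec.median_minutes), spec.median_minutes, size),
    )
    return np.clip(np.round(out), 1.0, 80.0)


def generate_cohort(sim: SimulationConfig) -> Cohort:
    """Players, a round-robin-style fixture list, and player-matches.

    Deterministic given ``sim.seed``.  Each team fields one player per
    position; each player appears in a given fixture of their team with
    probability ``participation_prob`` (emulating voluntary device
    uptake), and their playing time is drawn so the theoretical median
    equals the position's configured median.
    """
    rng = np.random.default_rng(sim.seed)
    players = []
    for team in range(sim.n_teams):
        for spec in sim.position_table:
            pid = f"P{len(players):03d}"
            players.append({"player_id": pid, "team_id": f"T{team:02d}",
                            "position": spec.name, "group": spec.group})
    players = pd.DataFrame(players)

    fixtures = []
    for rnd in range(sim.n_rounds):
        order = rng.permutation(sim.n_teams)
        for k in range(sim.n_teams // 2):
            home, away = order[2 * k], order[2 * k + 1]
            fixtures.append({"fixture_id": f"F{len(fixtures):03d}",
                             "home_team": f"T{home:02d}", "away_team": f"T{away:02d}",
                             "round": rnd})
    fixtures = pd.DataFrame(fixtures)

    rows = []
    for _, fx in fixtures.iterrows():
        for team in (fx["home_team"], fx["away_team"]):
            squad = players[players["team_id"] == team]
            mask = rng.random(len(squad)) < sim.participation_prob
            for _, pl in squad[mask].iterrows():
                rows.append({"player_id": pl["player_id"], "fixture_id": fx["fixture_id"],
                             "position": pl["position"], "group": pl["group"],
                             "team_id": team})
    pm = pd.DataFrame(rows, columns=["player_id", "fixture_id", "position", "group", "team_id"])
    minutes = np.empty(len(pm))
    for spec in sim.position_table:
        idx = np.flatnonzero((pm["position"] == spec.name).to_numpy())
        minutes[idx] = _draw_minutes(spec, idx.size, rng)
    pm["playing_time"] = minutes
    return Cohort(players=players, fixtures=fixtures, player_matches=pm)


# ---------------------------------------------------------------------------
# Match events and wear periods
# ---------------------------------------------------------------------------

def _intercepts(ids, sd: float, rng: np.random.Generator) -> dict[str, float]:
    return {i: float(rng.normal(0.0, sd)) if sd > 0 else 0.0 for i in ids}


def generate_match_events(
    cohort: Cohort, sim: SimulationConfig, rng: np.random.Generator | None = None,
    player_intercepts: dict[str, float] | None = None,
    fixture_intercepts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float], dict[str, float]]:
    """Tackle involvements and wear periods for every player-match.

    Returns ``(involvements, wear_periods, player_intercepts,
    fixture_intercepts)``.  Carries and (non-sequential) tackles are drawn
    per player-match as independent Poisson counts with mean
    rate * (minutes / median) * exp(u_player + v_fixture), so every
    involvement count — and every thinned HAE count — is exactly Poisson
    at the configured rate.  Each carry opens a tackle event; tackler
    involvements attach to a uniformly chosen opposing carry event
    (emulating partial instrumentation: an observed tackle event carries
    whichever of its participants wore a device, so events may lack an
    observed carrier or tacklers).  Sequential (assist) involvements are
    drawn at a rate giving the configured long-run fraction of tackler
    involvements; each involvement falls outside every wear period with
    probability ``wear_miss_prob``.
    """
    rng = rng if rng is not None else np.random.default_rng(sim.seed + 1)
    if player_intercepts is None:
        player_intercepts = _intercepts(cohort.players["player_id"], sim.player_sd, rng)
    if fixture_intercepts is None:
        fixture_intercepts = _intercepts(cohort.fixtures["fixture_id"], sim.fixture_sd, rng)

    s = sim.sequential_fraction
    seq_ratio = s / (1.0 - s)
    specs = {sp.name: sp for sp in sim.position_table}

    pm = cohort.player_matches
    inv_rows: list[dict] = []
    ev_counter = 0

    def _poisson_rate(row, per_match: float, v_f: float) -> float:
        spec = specs[row["position"]]
        return (per_match * (row["playing_time"] / spec.median_minutes)
                * np.exp(player_intercepts[row["player_id"]] + v_f))

    for fixture_id, fpm in pm.groupby("fixture_id", sort=True):
        v_f = fixture_intercepts[fixture_id]
        teams = fpm["team_id"].unique()
        by_team = {t: fpm[fpm["team_id"] == t] for t in teams}

        # carries first: every carry opens a tackle event
        events_by_team: dict[str, list[tuple[str, float]]] = {t: [] for t in teams}
        for team in teams:
            for _, r in by_team[team].iterrows():
                spec = specs[r["position"]]
                n_carries = rng.poisson(_poisson_rate(r, spec.carries_per_match, v_f))
                for _ in range(n_carries):
                    ev_id = f"E{ev_counter:05d}"
                    ev_counter += 1
                    ts = rng.uniform(0.0, MATCH_SECONDS)
                    events_by_team[team].append((ev_id, ts))
                    inv_rows.append({"tackle_event_id": ev_id, "player_id": r["player_id"],
                                     "fixture_id": fixture_id, "timestamp": ts,
                                     "role": "ball-carrier",
                                     "tackle_sequence": "one-on-one"})

        # tackler involvements attach to opposing carry events
        for team in teams:
            opp_events = [ev for t in teams if t != team for ev in events_by_team[t]]
            for _, r in by_team[team].iterrows():
                spec = specs[r["position"]]
                n_tackles = rng.poisson(_poisson_rate(r, spec.tackles_per_match, v_f))
                n_seq = (rng.poisson(_poisson_rate(r, spec.tackles_per_match, v_f)
                                     * seq_ratio) if seq_ratio > 0 else 0)
                for kind, count in (("initial", n_tackles), ("sequential", n_seq)):
                    for _ in range(count):
                        if opp_events:
                            ev_id, ts = opp_events[int(rng.integers(len(opp_events)))]
                        else:
                            # no opposing player instrumented: singleton event
                            ev_id = f"E{ev_counter:05d}"
                            ev_counter += 1
                            ts = rng.uniform(0.0, MATCH_SECONDS)
                        inv_rows.append({
                            "tackle_event_id": ev_id, "player_id": r["player_id"],
                            "fixture_id": fixture_id, "timestamp": ts,
                            "role": "tackler",
                            "tackle_sequence": "sequential" if kind == "sequential"
                            else "initial"})

    involvements = pd.DataFrame(
        inv_rows, columns=["tackle_event_id", "player_id", "fixture_id",
                           "timestamp", "role", "tackle_sequence"])
    # initial tacklers: one-on-one when alone on the event, simultaneous
    # when two or more engaged the carrier together
    is_initial = (involvements["role"] == "tackler") & (
        involvements["tackle_sequence"] == "initial")
    n_initial = (involvements[is_initial].groupby("tackle_event_id")["player_id"]
                 .transform("size"))
    involvements.loc[is_initial, "tackle_sequence"] = np.where(
        n_initial >= 2, "simultaneous", "one-on-one")
    involvements.insert(0, "involvement_id",
                        [f"I{i:06d}" for i in range(len(involvements))])

    wear_rows: list[dict] = []
    inv_by_pm = involvements.groupby(["player_id", "fixture_id"], sort=False)
    keyed = {k: g for k, g in inv_by_pm}
    for _, r in pm.iterrows():
        key = (r["player_id"], r["fixture_id"])
        times = np.sort(keyed[key]["timestamp"].to_numpy()) if key in keyed else np.array([])
        missed = times[rng.random(times.size) < sim.wear_miss_prob] if times.size else np.array([])
        gaps = []
        for t in missed:
            others = times[times != t]
            half = 2.0 if others.size == 0 else min(2.0, 0.45 * np.abs(others - t).min())
            gaps.append((max(0.0, t - half), min(MATCH_SECONDS, t + half)))
        edges = [0.0]
        for lo, hi in sorted(gaps):
            edges += [lo, hi]
        edges.append(MATCH_SECONDS)
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi > lo:
                wear_rows.append({"player_id": r["player_id"], "fixture_id": r["fixture_id"],
                                  "start": lo, "end": hi})
    wear_periods = pd.DataFrame(wear_rows, columns=["player_id", "fixture_id", "start", "end"])
    return involvements, wear_periods, player_intercepts, fixture_intercepts


# ---------------------------------------------------------------------------
# HAE magnitudes (ground truth) and raw traces
# ---------------------------------------------------------------------------

def generate_hae_magnitudes(
    involvements: pd.DataFrame, sim: SimulationConfig,
    positions_by_player: dict[str, str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the recorded-HAE indicator and true peak magnitudes.

    Each non-sequential involvement yields at most one HAE (Bernoulli
    with the role- and position-specific probability); sequential assists
    never do.  Magnitudes are the head-CoG ground truth the trace
    generator will realise.
    """
    rng = rng if rng is not None else np.random.default_rng(sim.seed + 2)
    m = sim.magnitude_model
    rows = []
    for _, r in involvements.iterrows():
        if r["tackle_sequence"] == "sequential" and r["role"] == "tackler":
            continue
        spec = sim.position(positions_by_player[r["player_id"]])
        pc, pt = sim.hae_probs(spec)
        carrier = r["role"] == "ball-carrier"
        if rng.random() >= (pc if carrier else pt):
            continue
        mu = m.carrier_logmean if carrier else m.tackler_logmean
        pla = float(np.exp(rng.normal(mu, m.pla_logsd)))
        paa = float(m.paa_scale * pla * np.exp(rng.normal(0.0, m.paa_logsd)))
        rvci = float(m.rvci_scale * pla * np.exp(rng.normal(0.0, m.rvci_logsd)))
        noise_class = int(rng.choice(3, p=sim.noise_class_probs))
        rows.append({
            "hae_id": f"H{len(rows):05d}",
            "involvement_id": r["involvement_id"],
            "player_id": r["player_id"],
            "fixture_id": r["fixture_id"],
            "role": r["role"],
            "timestamp": float(r["timestamp"] + rng.uniform(-1.0, 1.0)),
            "pla_true": pla, "paa_true": paa, "rvci_true": rvci,
            "noise_class": noise_class,
        })
    return pd.DataFrame(rows, columns=[
        "hae_id", "involvement_id", "player_id", "fixture_id", "role",
        "timestamp", "pla_true", "paa_true", "rvci_true", "noise_class"])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def build_pulse_trace(
    pla_g: float, paa: float, rvci: float, noise_class: int,
    sim: SimulationConfig, kin: KinematicsConfig,
    rng: np.random.Generator,
    player_id: str = "", fixture_id: str = "", start_time: float = 0.0,
    trace_id: str = "", carrier_duration_s: float = 0.25,
) -> RawTrace:
    """One raw sensor-frame trace realising the drawn CoG peaks.

    The head-CoG linear pulse is a half-sine along +x of amplitude
    ``pla_g``; the angular-velocity ramp on z is a smoothstep whose total
    change realises the RVCI target (the ramp fits inside the 10 ms RVCI
    window) and whose duration is set from the PAA target.  The sensor
    trace is the exact inversion of the rigid-body CoG transform, so the
    processing chain recovers the drawn PLA.  Pulse durations are drawn
    per noise class (10-20, 15-20, 25 ms) so that the class-routed
    re-filtering keeps the recovered peak within the stated tolerances.
    """
    fs = kin.sample_rate
    dt = 1.0 / fs
    n = int(round(carrier_duration_s * fs))
    t = np.arange(n) * dt
    centre = carrier_duration_s / 2.0

    lin_lo, lin_hi = [(0.010, 0.020), (0.015, 0.020), (0.025, 0.025)][noise_class]
    t_lin = rng.uniform(lin_lo, lin_hi) if lin_hi > lin_lo else lin_hi
    t0 = centre - t_lin / 2.0
    a_h = np.zeros((3, n))
    in_pulse = (t >= t0) & (t <= t0 + t_lin)
    a_h[0, in_pulse] = pla_g * np.sin(np.pi * (t[in_pulse] - t0) / t_lin)

    # angular ramp: total change from the RVCI target; duration from PAA
    weights = np.asarray(kin.rvci_weights)
    d_omega = rvci / np.sqrt(weights[2])
    if paa > 0 and d_omega > 0:
        ramp = float(np.clip(1.5 * d_omega / paa, 4.0 * dt, kin.rvci_duration))
    else:
        ramp = kin.rvci_duration
    r0 = centre - ramp / 2.0
    omega = np.zeros((3, n))
    omega[2] = d_omega * _smoothstep((t - r0) / ramp)
    # ramp back down well after the triggered window has closed
    down = d_omega * _smoothstep((t - (r0 + ramp + 0.06)) / 0.05)
    omega[2] -= down

    # invert the CoG transform: a_m = a_h - alpha x r - omega x (omega x r)
    r = np.asarray(kin.r_mh)
    alpha = np.gradient(omega, dt, axis=-1)
    a_m_si = (a_h * kin.gravity_constant
              - np.cross(alpha.T, r).T
              - np.cross(omega.T, np.cross(omega.T, r)).T)
    a_m = a_m_si / kin.gravity_constant

    a_m = a_m + rng.normal(0.0, sim.noise_sd_a[noise_class], a_m.shape)
    omega = omega + rng.normal(0.0, sim.noise_sd_w[noise_class], omega.shape)
    a_m = np.clip(a_m, -kin.accel_range, kin.accel_range)
    omega = np.clip(omega, -kin.gyro_range, kin.gyro_range)

    return RawTrace(player_id=player_id, fixture_id=fixture_id,
                    start_time=start_time, a=a_m, omega=omega,
                    noise_class=noise_class, trace_id=trace_id)


def generate_hae_traces(
    haes: pd.DataFrame, sim: SimulationConfig, kin: KinematicsConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RawTrace], pd.DataFrame]:
    """Raw sensor traces for every drawn HAE that crosses the trigger.

    Returns ``(traces, haes)`` where the returned table gains two
    columns: ``triggered`` (the constructed sensor trace crosses the 8 g
    per-axis trigger, hence a trace was emitted) and ``clipped`` (some
    sample hit the sensor measurement range).
    """
    rng = rng if rng is not None else np.random.default_rng(sim.seed + 3)
    traces: list[RawTrace] = []
    triggered = np.zeros(len(haes), dtype=bool)
    clipped = np.zeros(len(haes), dtype=bool)
    for i, (_, r) in enumerate(haes.iterrows()):
        raw = build_pulse_trace(
            r["pla_true"], r["paa_true"], r["rvci_true"], int(r["noise_class"]),
            sim, kin, rng,
            player_id=r["player_id"], fixture_id=r["fixture_id"],
            start_time=float(r["timestamp"]) - 0.125, trace_id=r["hae_id"])
        trig = bool((np.abs(raw.a) > kin.trigger_threshold).any())
        triggered[i] = trig
        clipped[i] = bool((np.abs(raw.a) >= kin.accel_range).any()
                          or (np.abs(raw.omega) >= kin.gyro_range).any())
        if trig:
            traces.append(raw)
    out = haes.copy()
    out["triggered"] = triggered
    out["clipped"] = clipped
    return traces, out


# ---------------------------------------------------------------------------
# Closed-form expectations (recovery-test oracle)
# ---------------------------------------------------------------------------

def _tail(threshold: float, logmean: float, logsd: float,
          scale: float = 1.0, extra_logsd: float = 0.0) -> float:
    """P(scale * X * e^eps > threshold) for lognormal X; closed form."""
    if threshold <= 0:
        return 1.0
    sd = float(np.hypot(logsd, extra_logsd))
    return float(norm.sf((np.log(threshold / scale) - logmean) / sd))


def expected_summaries(sim: SimulationConfig, grid: ThresholdGrid) -> GroundTruth:
    """Analytic per-position incidence and per-role exceedance.

    Uses the lognormal tail formulas of the magnitude model; these are
    the recovery targets for the fitted models (evaluated at zero random
    effects, matching the mixed models' population-level estimates).
    """
    m = sim.magnitude_model
    metric_params = {
        "pla": (1.0, 0.0),
        "paa": (m.paa_scale, m.paa_logsd),
        "rvci": (m.rvci_scale, m.rvci_logsd),
    }
    inc_rows, exc_rows = [], []
    for metric, (scale, extra) in metric_params.items():
        for threshold in grid.for_metric(metric):
            s_c = _tail(threshold, m.carrier_logmean, m.pla_logsd, scale, extra)
            s_t = _tail(threshold, m.tackler_logmean, m.pla_logsd, scale, extra)
            for spec in sim.position_table:
                pc, pt = sim.hae_probs(spec)
                per_match = (spec.carries_per_match * pc * s_c
                             + spec.tackles_per_match * pt * s_t)
                rate_min = per_match / spec.median_minutes
                inc_rows.append({"position": spec.name, "group": spec.group,
                                 "metric": metric, "threshold": threshold,
                                 "per_median": rate_min * spec.median_minutes,
                                 "per_full_match": rate_min * 80.0})
            # involvement-weighted role exceedance (uniform role probabilities
            # across positions at the defaults)
            wc = sum(s2.carries_per_match for s2 in sim.position_table)
            wt = sum(s2.tackles_per_match for s2 in sim.position_table)
            pc_bar = sum(s2.carries_per_match * sim.hae_probs(s2)[0]
                         for s2 in sim.position_table) / wc
            pt_bar = sum(s2.tackles_per_match * sim.hae_probs(s2)[1]
                         for s2 in sim.position_table) / wt
            exc_rows.append({"role": "ball-carrier", "metric": metric,
                             "threshold": threshold, "probability": pc_bar * s_c})
            exc_rows.append({"role": "tackler", "metric": metric,
                             "threshold": threshold, "probability": pt_bar * s_t})
    return GroundTruth(
        position_incidence=pd.DataFrame(inc_rows),
        role_exceedance=pd.DataFrame(exc_rows),
        player_intercepts={}, fixture_intercepts={})


# ---------------------------------------------------------------------------
# One-call dataset simulation and writers
# ---------------------------------------------------------------------------

def simulate_dataset(
    sim: SimulationConfig,
    kin: KinematicsConfig | None = None,
    grid: ThresholdGrid | None = None,
    with_traces: bool = False,
) -> SimulatedDataset:
    """Generate a full synthetic dataset (deterministic given ``sim.seed``).

    With ``with_traces=False`` the drawn ground-truth magnitudes stand in
    for processed sensor output (all drawn HAEs above the 8 g trigger are
    treated as recorded); with ``with_traces=True`` raw traces are built
    and the triggered flag reflects the constructed sensor signal.
    """
    kin = kin or KinematicsConfig()
    grid = grid or ThresholdGrid()
    rng = np.random.default_rng(sim.seed)
    cohort = generate_cohort(sim)
    involvements, wear, u, v = generate_match_events(cohort, sim, rng)
    pos_by_player = dict(zip(cohort.players["player_id"], cohort.players["position"]))
    haes = generate_hae_magnitudes(involvements, sim, pos_by_player, rng)
    traces = None
    if with_traces:
        traces, haes = generate_hae_traces(haes, sim, kin, rng)
    else:
        haes = haes.copy()
        haes["triggered"] = haes["pla_true"] > kin.trigger_threshold
        haes["clipped"] = False
    truth = expected_summaries(sim, grid)
    truth.player_intercepts, truth.fixture_intercepts = u, v
    truth.haes = haes
    return SimulatedDataset(cohort=cohort, involvements=involvements,
                            wear_periods=wear, haes=haes, truth=truth,
                            traces=traces)


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the CSV/JSON artefacts of one simulated season."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.cohort.players.to_csv(out / "players.csv", index=False)
    data.cohort.fixtures.to_csv(out / "fixtures.csv", index=False)
    data.cohort.player_matches.to_csv(out / "cohort.csv", index=False)
    data.involvements.to_csv(out / "involvements.csv", index=False)
    data.wear_periods.to_csv(out / "wear_periods.csv", index=False)
    data.haes.to_csv(out / "haes_truth.csv", index=False)
    truth = {
        "position_incidence": data.truth.position_incidence.to_dict(orient="records"),
        "role_exceedance": data.truth.role_exceedance.to_dict(orient="records"),
        "player_intercepts": data.truth.player_intercepts,
        "fixture_intercepts": data.truth.fixture_intercepts,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    if data.traces is not None:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        index = []
        for raw in data.traces:
            write_trace_csv(raw, tdir / f"{raw.trace_id}.csv")
            index.append({"trace_id": raw.trace_id, "player_id": raw.player_id,
                          "fixture_id": raw.fixture_id, "noise_class": raw.noise_class,
                          "start_time": raw.start_time})
        pd.DataFrame(index).to_csv(tdir / "traces_index.csv", index=False)
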
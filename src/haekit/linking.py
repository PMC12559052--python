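"""Inclusion rules and HAE-to-involvement linkage.

Four rules shape the analysis dataset:

* **Wear compliance** — a player-match enters the incidence dataset only
  if strictly more than 90% of that player's tackle involvements fall
  inside an on-the-teeth wear period (proximity-sensor intervals); this
  guards against false negatives from a device not being worn.
* **Sequential-tackle removal** — tackler involvements labelled
  *sequential* are tackle assists with minimal contact and are removed;
  ball-carrier involvements are never removed.
* **Linkage** — each processed HAE is matched to the nearest-in-time
  involvement of the same player in the same fixture within a +/- 5 s
  window (a deterministic stand-in for manual video linkage); ties go to
  the earlier involvement, each HAE links to at most one involvement,
  and unlinked HAEs are retained (flagged) for incidence counting.
* **Per-involvement maxima** — the maximum of each metric over the
  linked HAEs, or the ``no recorded HAEs`` sentinel when none linked.

Incidence counts use all recorded HAEs in wear-compliant player-matches;
the probability models use only involvements inside wear periods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ThresholdGrid

__all__ = [
    "NO_HAE",
    "IntegrityError",
    "mark_wear",
    "filter_wear_compliance",
    "remove_sequential_tackles",
    "link_haes_to_involvements",
    "max_magnitude_per_involvement",
    "count_haes_per_player_match",
]

NO_HAE = "no recorded HAEs"

_METRIC_COLUMNS = {"pla": "pla_g", "paa": "paa_rads2", "rvci": "rvci_rads"}


class IntegrityError(ValueError):
    """Referential or labelling inconsistency in the input tables."""


def mark_wear(involvements: pd.DataFrame, wear_periods: pd.DataFrame) -> pd.DataFrame:
    """Add ``in_wear``: involvement timestamp inside some wear period
    of the same player-match (inclusive endpoints)."""
    out = involvements.copy()
    in_wear = np.zeros(len(out), dtype=bool)
    periods = {k: g[["start", "end"]].to_numpy()
               for k, g in wear_periods.groupby(["player_id", "fixture_id"], sort=False)}
    for i, (pid, fid, ts) in enumerate(
            zip(out["player_id"], out["fixture_id"], out["timestamp"])):
        spans = periods.get((pid, fid))
        if spans is not None:
            in_wear[i] = bool(((spans[:, 0] <= ts) & (ts <= spans[:, 1])).any())
    out["in_wear"] = in_wear
    return out


def filter_wear_compliance(
    involvements: pd.DataFrame,
    wear_periods: pd.DataFrame,
    player_matches: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-player-match wear compliance and the strict inclusion flag.

    ``included_for_incidence`` is True when the in-wear fraction of the
    player's involvements strictly exceeds the compliance threshold
    (default 0.90: exactly 9 of 10 is excluded).  Player-matches with no
    involvements are included vacuously and flagged.
    """
    cfg = cfg or AnalysisConfig()
    marked = mark_wear(involvements, wear_periods)
    known = set(zip(player_matches["player_id"], player_matches["fixture_id"]))
    for pid, fid in zip(marked["player_id"], marked["fixture_id"]):
        if (pid, fid) not in known:
            raise IntegrityError(
                f"involvement references unknown player-match ({pid}, {fid})")
    grouped = marked.groupby(["player_id", "fixture_id"], sort=False)["in_wear"]
    counts = grouped.size()
    in_wear = grouped.sum()

    out = player_matches.copy()
    keys = list(zip(out["player_id"], out["fixture_id"]))
    out["involvement_count"] = [int(counts.get(k, 0)) for k in keys]
    out["involvements_in_wear"] = [int(in_wear.get(k, 0)) for k in keys]
    frac = np.where(out["involvement_count"] > 0,
                    out["involvements_in_wear"] / np.maximum(out["involvement_count"], 1),
                    1.0)
    out["wear_fraction"] = frac
    out["included_for_incidence"] = (
        (out["involvement_count"] == 0)
        | (frac > cfg.wear_compliance_fraction))
    out["vacuous_compliance"] = out["involvement_count"] == 0
    return out


def remove_sequential_tackles(involvements: pd.DataFrame) -> pd.DataFrame:
    """Drop tackler involvements with a sequential tackle sequence.

    Ball-carrier rows are never dropped, whatever their label.  Missing
    labels raise :class:`IntegrityError` listing the offending ids.
    """
    labels = involvements["tackle_sequence"]
    missing = involvements.loc[labels.isna() | (labels == ""), "involvement_id"]
    if len(missing):
        raise IntegrityError(
            f"missing tackle_sequence label for involvement(s): {list(missing)}")
    bad = labels.isin(["one-on-one", "simultaneous", "sequential"])
    if not bad.all():
        raise IntegrityError(
            f"unknown tackle_sequence label(s): "
            f"{sorted(labels[~bad].unique())}")
    drop = (involvements["role"] == "tackler") & (labels == "sequential")
    return involvements[~drop].reset_index(drop=True)


def link_haes_to_involvements(
    haes: pd.DataFrame,
    involvements: pd.DataFrame,
    window: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each HAE to the nearest involvement of the same player-match.

    Returns ``(involvements, haes)`` where involvements gain
    ``linked_hae_ids`` (list) and HAEs gain ``linked_involvement_id``
    (empty string when unlinked) and ``unlinked``.  A HAE links to the
    involvement with the smallest absolute time difference within
    ``+/- window`` seconds; on an exact tie the earlier involvement wins.
    """
    inv = involvements.reset_index(drop=True)
    hae = haes.reset_index(drop=True).copy()
    linked_ids: dict[str, list[str]] = {i: [] for i in inv["involvement_id"]}
    hae_link = np.full(len(hae), "", dtype=object)

    inv_by_pm = {
        k: g.sort_values(["timestamp", "involvement_id"])
        for k, g in inv.groupby(["player_id", "fixture_id"], sort=False)
    }
    for i, (pid, fid, ts) in enumerate(
            zip(hae["player_id"], hae["fixture_id"], hae["timestamp"])):
        g = inv_by_pm.get((pid, fid))
        if g is None:
            continue
        dt = np.abs(g["timestamp"].to_numpy() - ts)
        j = int(np.argmin(dt))  # first minimum = earliest timestamp on ties
        if dt[j] <= window:
            inv_id = g["involvement_id"].iloc[j]
            linked_ids[inv_id].append(hae["hae_id"].iloc[i])
            hae_link[i] = inv_id

    inv = inv.copy()
    inv["linked_hae_ids"] = [linked_ids[i] for i in inv["involvement_id"]]
    hae["linked_involvement_id"] = hae_link
    hae["unlinked"] = hae_link == ""
    return inv, hae


def max_magnitude_per_involvement(
    involvements: pd.DataFrame, haes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-metric maxima over each involvement's linked HAEs.

    Adds ``max_pla``, ``max_paa``, ``max_rvci`` (NaN when no HAEs linked)
    and ``max_label`` carrying the ``no recorded HAEs`` sentinel.
    """
    out = involvements.copy()
    by_hae = haes.set_index("hae_id")
    for metric, col in _METRIC_COLUMNS.items():
        vals = []
        for ids in out["linked_hae_ids"]:
            vals.append(float(by_hae.loc[ids, col].max()) if ids else np.nan)
        out[f"max_{metric}"] = vals
    out["max_label"] = np.where(
        out["linked_hae_ids"].str.len() > 0, "recorded", NO_HAE)
    neg = [m for m in _METRIC_COLUMNS
           if (out[f"max_{m}"].dropna() < 0).any()]
    if neg:
        raise IntegrityError(f"negative per-involvement maxima for metric(s): {neg}")
    return out


def count_haes_per_player_match(
    haes: pd.DataFrame,
    player_matches: pd.DataFrame,
    grid: ThresholdGrid,
) -> pd.DataFrame:
    """Per-threshold HAE counts for the wear-compliant player-matches.

    For every included player-match and every metric threshold, counts
    HAEs whose magnitude strictly exceeds the threshold.  All recorded
    HAEs count (linked or not): the incidence model is count-based.
    Counts are non-increasing across increasing thresholds by
    construction.
    """
    out = player_matches.copy()
    included = out[out["included_for_incidence"]] if "included_for_incidence" in out else out
    by_pm = {k: g for k, g in haes.groupby(["player_id", "fixture_id"], sort=False)}
    for metric, col in _METRIC_COLUMNS.items():
        for threshold in grid.for_metric(metric):
            name = f"n_{metric}_gt_{threshold:g}"
            counts = []
            for pid, fid in zip(out["player_id"], out["fixture_id"]):
                g = by_pm.get((pid, fid))
                counts.append(0 if g is None else int((g[col] > threshold).sum()))
            out[name] = counts
    if "included_for_incidence" in out:
        out = out[out["included_for_incidence"]].reset_index(drop=True)
    return out
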
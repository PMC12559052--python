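"""Signal processing from triggered mouthguard traces to head-CoG metrics.

The chain mirrors the vendor-style post-processing of a 6-DOF instrumented
mouthguard: per-axis linear-acceleration triggering with a 10 ms pre- /
40 ms post-trigger window, four-pole zero-phase Butterworth low-pass
filtering with noise-class-dependent cutoff routing (200 Hz always, then
100 Hz for moderate-noise or 50 Hz for severe-noise events), rigid-body
transformation of linear acceleration from the sensor location to the head
centre of gravity,

    a_h = a_m + alpha x r_mh + omega x (omega x r_mh),

and extraction of three per-event metrics from the resultant curves:

* PLA  - peak resultant linear acceleration at the head CoG (g),
* PAA  - peak resultant angular acceleration (rad/s^2), with angular
  acceleration obtained from the filtered gyro signal by central
  differences,
* RVCI - rotational velocity change index (rad/s): the maximum weighted
  norm of the angular-velocity change over any window of at most 10 ms,
  sqrt(Rx*dwx^2 + Ry*dwy^2 + Rz*dwz^2) with weights (1.00, 1.00, 1.17).

Filtering is realised as a forward-backward pass of a 2-pole Butterworth
(net four poles, -6 dB at the cutoff).  The CoG transform is applied after
filtering; linear channels are stored in g and converted to m/s^2 only
inside the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import ConfigError, KinematicsConfig

__all__ = [
    "RawTrace",
    "KinematicTrace",
    "HAERecord",
    "apply_trigger",
    "lowpass_filter",
    "transform_to_cog",
    "compute_pla",
    "compute_paa",
    "compute_rvci",
    "process_event",
    "process_traces",
    "write_trace_csv",
    "read_trace_csv",
    "read_traces_dir",
    "write_hae_records",
    "read_hae_records",
]


@dataclass
class RawTrace:
    """A continuous 6-DOF recording segment at the sensor location.

    ``a`` is linear acceleration in g, shape (3, N); ``omega`` angular
    velocity in rad/s, shape (3, N); ``start_time`` is the match-clock
    time of the first sample in seconds.
    """

    player_id: str
    fixture_id: str
    start_time: float
    a: np.ndarray
    omega: np.ndarray
    noise_class: int = 0
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.a.shape != self.omega.shape or self.a.ndim != 2 or self.a.shape[0] != 3:
            raise ValueError("a and omega must both have shape (3, N)")


@dataclass
class KinematicTrace:
    """One triggered 50 ms window (160 samples at 3200 Hz).

    The trigger sample sits at the index corresponding to the 10 ms
    pre-trigger span (sample 32 at the defaults).  ``head_padded`` marks
    windows whose pre-trigger span ran off the start of the record and was
    zero-padded.
    """

    hae_id: str
    player_id: str
    fixture_id: str
    trigger_timestamp: float
    t: np.ndarray
    a_m: np.ndarray
    omega: np.ndarray
    noise_class: int = 0
    head_padded: bool = False
    tail_padded: bool = False
    applied_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_m = np.asarray(self.a_m, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.a_m.shape != self.omega.shape or self.a_m.shape[0] != 3:
            raise ValueError("a_m and omega must both have shape (3, N)")
        if self.noise_class not in (0, 1, 2):
            raise ValueError(f"noise_class must be 0, 1 or 2, got {self.noise_class}")


@dataclass(frozen=True)
class HAERecord:
    """Processed head acceleration event."""

    hae_id: str
    player_id: str
    fixture_id: str
    trigger_timestamp: float
    pla: float          # g
    paa: float          # rad/s^2
    rvci: float         # rad/s
    noise_class: int
    applied_cutoff: float  # Hz


# ---------------------------------------------------------------------------
# Triggering and windowing
# ---------------------------------------------------------------------------

def apply_trigger(raw: RawTrace, kin: KinematicsConfig,
                  id_prefix: str | None = None) -> list[KinematicTrace]:
    """Emit triggered windows from a continuous sensor trace.

    A window opens whenever any linear-acceleration axis first exceeds the
    per-axis trigger threshold (8 g); it spans ``pretrigger`` seconds
    before to ``posttrigger`` seconds after the trigger sample.  While a
    window is open no new trigger can fire; triggering re-arms at the
    first sample after the window (the re-arming rule).  Windows whose
    pre-trigger span precedes the record start are zero-padded at the head
    and flagged; likewise at the tail.
    """
    n = raw.a.shape[1]
    pre = kin.trigger_index
    win = kin.window_samples
    post = win - pre
    exceeds = np.abs(raw.a) > kin.trigger_threshold
    hot = np.flatnonzero(exceeds.any(axis=0))
    dt = 1.0 / kin.sample_rate

    windows: list[KinematicTrace] = []
    prefix = id_prefix if id_prefix is not None else (raw.trace_id or "hae")
    rearm = 0  # first index allowed to trigger
    ptr = 0
    while ptr < hot.size:
        k = hot[ptr]
        if k < rearm:
            ptr += 1
            continue
        lo, hi = k - pre, k + post
        a_w = np.zeros((3, win))
        w_w = np.zeros((3, win))
        src_lo, src_hi = max(lo, 0), min(hi, n)
        dst_lo, dst_hi = src_lo - lo, src_lo - lo + (src_hi - src_lo)
        a_w[:, dst_lo:dst_hi] = raw.a[:, src_lo:src_hi]
        w_w[:, dst_lo:dst_hi] = raw.omega[:, src_lo:src_hi]
        t_w = (np.arange(win) - pre) * dt
        windows.append(KinematicTrace(
            hae_id=f"{prefix}_{len(windows):03d}",
            player_id=raw.player_id,
            fixture_id=raw.fixture_id,
            trigger_timestamp=raw.start_time + k * dt,
            t=t_w, a_m=a_w, omega=w_w,
            noise_class=raw.noise_class,
            head_padded=lo < 0, tail_padded=hi > n,
        ))
        rearm = hi
        ptr += 1
    return windows


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _zero_phase_lowpass(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Forward-backward 2-pole Butterworth: 4 effective poles, -6 dB at cutoff."""
    if cutoff >= fs / 2.0:
        raise ConfigError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2.0} Hz")
    b, a = butter(2, cutoff, btype="low", fs=fs)
    n = x.shape[-1]
    # reflective padding spanning at least ~3 time constants of the filter
    padlen = min(n - 1, max(9, int(3.0 * fs / cutoff)))
    return filtfilt(b, a, x, axis=-1, padtype="even", padlen=padlen)


def lowpass_filter(trace: KinematicTrace, kin: KinematicsConfig) -> KinematicTrace:
    """Filter all six channels with the noise-class cutoff routing.

    Every event receives the 200 Hz primary pass; class-1 events are
    filtered again at 100 Hz, class-2 events at 50 Hz.  ``applied_cutoff``
    records the last cutoff used.
    """
    a = _zero_phase_lowpass(trace.a_m, kin.primary_cutoff, kin.sample_rate)
    w = _zero_phase_lowpass(trace.omega, kin.primary_cutoff, kin.sample_rate)
    cutoff = kin.cutoff_for_class(trace.noise_class)
    if trace.noise_class != 0:
        a = _zero_phase_lowpass(a, cutoff, kin.sample_rate)
        w = _zero_phase_lowpass(w, cutoff, kin.sample_rate)
    out = replace(trace)
    out.a_m, out.omega, out.applied_cutoff = a, w, cutoff
    return out


# ---------------------------------------------------------------------------
# CoG transform and metric extraction
# ---------------------------------------------------------------------------

def _angular_acceleration(omega: np.ndarray, fs: float) -> np.ndarray:
    """Central differences (forward/backward at the ends), rad/s^2."""
    return np.gradient(omega, 1.0 / fs, axis=-1)


def transform_to_cog(trace: KinematicTrace, kin: KinematicsConfig) -> np.ndarray:
    """Linear acceleration at the head CoG via the relative-acceleration
    equation, returned in g with shape (3, N).

    a_h = a_m + alpha x r_mh + omega x (omega x r_mh), with a_m converted
    to m/s^2 before the vector terms are added and the result converted
    back to g.
    """
    r = np.asarray(kin.r_mh)
    a_si = trace.a_m * kin.gravity_constant            # (3, N) m/s^2
    omega = trace.omega                                 # (3, N)
    alpha = _angular_acceleration(omega, kin.sample_rate)
    tang = np.cross(alpha.T, r).T                       # alpha x r
    cent = np.cross(omega.T, np.cross(omega.T, r)).T    # omega x (omega x r)
    return (a_si + tang + cent) / kin.gravity_constant


def compute_pla(a_h: np.ndarray) -> float:
    """Peak resultant linear acceleration: max over samples of ||a_h||, g."""
    return float(np.linalg.norm(a_h, axis=0).max(initial=0.0))


def compute_paa(omega: np.ndarray, kin: KinematicsConfig) -> float:
    """Peak resultant angular acceleration from the filtered gyro, rad/s^2."""
    alpha = _angular_acceleration(np.asarray(omega, dtype=float), kin.sample_rate)
    return float(np.linalg.norm(alpha, axis=0).max(initial=0.0))


def compute_rvci(omega: np.ndarray, kin: KinematicsConfig) -> float:
    """Rotational velocity change index, rad/s.

    Since the integral of angular acceleration is the change in angular
    velocity, the metric reduces to the maximum over all sample pairs
    (t1, t2) with 0 < t2 - t1 <= 10 ms of the weighted norm of
    omega(t2) - omega(t1).  The search runs over discrete sample lags of
    1..32 at 3200 Hz.
    """
    omega = np.asarray(omega, dtype=float)
    n = omega.shape[1]
    max_lag = kin.rvci_window_samples
    if max_lag > n - 1:
        raise ConfigError(
            f"RVCI window ({max_lag} samples) exceeds trace length ({n} samples)")
    weights = np.asarray(kin.rvci_weights)[:, None]
    best = 0.0
    for lag in range(1, max_lag + 1):
        d = omega[:, lag:] - omega[:, :-lag]
        vals = np.sqrt((weights * d * d).sum(axis=0))
        m = vals.max(initial=0.0)
        if m > best:
            best = float(m)
    return best


def process_event(trace: KinematicTrace, kin: KinematicsConfig) -> HAERecord:
    """Full per-event chain: filter, CoG transform, metric extraction."""
    filtered = lowpass_filter(trace, kin)
    a_h = transform_to_cog(filtered, kin)
    return HAERecord(
        hae_id=trace.hae_id,
        player_id=trace.player_id,
        fixture_id=trace.fixture_id,
        trigger_timestamp=trace.trigger_timestamp,
        pla=compute_pla(a_h),
        paa=compute_paa(filtered.omega, kin),
        rvci=compute_rvci(filtered.omega, kin),
        noise_class=trace.noise_class,
        applied_cutoff=float(filtered.applied_cutoff),
    )


def process_traces(raws: Iterable[RawTrace], kin: KinematicsConfig) -> list[HAERecord]:
    """Trigger and process a collection of continuous traces."""
    records: list[HAERecord] = []
    for raw in raws:
        for window in apply_trigger(raw, kin):
            records.append(process_event(window, kin))
    return records


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g", "wx_rads", "wy_rads", "wz_rads"]


def write_trace_csv(raw: RawTrace, path: str | Path) -> None:
    t = raw.start_time + np.arange(raw.a.shape[1]) / 3200.0
    df = pd.DataFrame({
        "t_s": t,
        "ax_g": raw.a[0], "ay_g": raw.a[1], "az_g": raw.a[2],
        "wx_rads": raw.omega[0], "wy_rads": raw.omega[1], "wz_rads": raw.omega[2],
    })
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, player_id: str = "", fixture_id: str = "",
                   noise_class: int = 0, trace_id: str = "") -> RawTrace:
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trace columns {missing}")
    return RawTrace(
        player_id=player_id, fixture_id=fixture_id,
        start_time=float(df["t_s"].iloc[0]),
        a=df[["ax_g", "ay_g", "az_g"]].to_numpy().T,
        omega=df[["wx_rads", "wy_rads", "wz_rads"]].to_numpy().T,
        noise_class=noise_class,
        trace_id=trace_id or Path(path).stem,
    )


def read_traces_dir(directory: str | Path) -> list[RawTrace]:
    """Read ``traces/*.csv`` with the accompanying ``traces_index.csv``.

    The index carries per-trace metadata (player, fixture, noise class)
    that the per-sample CSVs do not.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"traces directory not found: {directory}")
    index_path = directory / "traces_index.csv"
    meta: dict[str, dict] = {}
    if index_path.exists():
        idx = pd.read_csv(index_path, dtype={"trace_id": str})
        meta = {row["trace_id"]: row for _, row in idx.iterrows()}
    raws = []
    for path in sorted(directory.glob("*.csv")):
        if path.name == "traces_index.csv":
            continue
        stem = path.stem
        m = meta.get(stem, {})
        raws.append(read_trace_csv(
            path,
            player_id=str(m.get("player_id", "")),
            fixture_id=str(m.get("fixture_id", "")),
            noise_class=int(m.get("noise_class", 0)),
            trace_id=stem,
        ))
    return raws


def hae_records_frame(records: Sequence[HAERecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "hae_id": r.hae_id,
        "player_id": r.player_id,
        "fixture_id": r.fixture_id,
        "timestamp": r.trigger_timestamp,
        "pla_g": r.pla,
        "paa_rads2": r.paa,
        "rvci_rads": r.rvci,
        "noise_class": r.noise_class,
        "applied_cutoff_hz": r.applied_cutoff,
    } for r in records])


def write_hae_records(records: Sequence[HAERecord], path: str | Path) -> None:
    hae_records_frame(records).to_csv(path, index=False)


def read_hae_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hae_id": str, "player_id": str, "fixture_id": str})
    required = {"hae_id", "player_id", "fixture_id", "timestamp",
                "pla_g", "paa_rads2", "rvci_rads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
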
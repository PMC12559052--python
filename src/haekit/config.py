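"""Fixed constants of the processing chain and the analysis threshold grids.

Every number the downstream stages rely on lives here: the sensor and
windowing parameters of the instrumented mouthguard (3200 Hz sampling,
8 g per-axis trigger, 10 ms pre- / 40 ms post-trigger), the Butterworth
cutoff routing by noise class (200/100/50 Hz), the sensor-to-head-CoG
lever arm, the RVCI weighting factors and duration constraint, and the
magnitude-threshold grids at which incidence and exceedance are reported.

All values can be overridden from a single YAML mapping; unknown keys are
rejected so that typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ThresholdGrid",
    "KinematicsConfig",
    "AnalysisConfig",
    "Config",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Malformed configuration file or violated invariant."""


@dataclass(frozen=True)
class ThresholdGrid:
    """Magnitude thresholds at which counts and probabilities are reported.

    PLA thresholds run at 15 g intervals from 10 g to 70 g; the angular
    grids are the approximately proportional PAA (rad/s^2) and RVCI (rad/s)
    thresholds used alongside them.
    """

    pla_thresholds: tuple[float, ...] = (10.0, 25.0, 40.0, 55.0, 70.0)
    paa_thresholds: tuple[float, ...] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0)
    rvci_thresholds: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)

    def __post_init__(self) -> None:
        for name in ("pla_thresholds", "paa_thresholds", "rvci_thresholds"):
            vals = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) == 0:
                raise ConfigError(f"{name}: empty threshold grid")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"{name}: thresholds must be strictly increasing, got {vals}")

    def for_metric(self, metric: str) -> tuple[float, ...]:
        try:
            return {"pla": self.pla_thresholds,
                    "paa": self.paa_thresholds,
                    "rvci": self.rvci_thresholds}[metric]
        except KeyError:
            raise ConfigError(f"unknown metric {metric!r}; expected pla, paa or rvci") from None


@dataclass(frozen=True)
class KinematicsConfig:
    """Sensor, windowing, filtering and metric constants.

    Units: times in seconds, linear channels in g (converted to m/s^2 only
    inside the CoG transform), angular channels in rad/s, cutoffs in Hz,
    ``r_mh`` (sensor-to-head-CoG position vector) in metres.
    """

    sample_rate: float = 3200.0
    pretrigger: float = 0.010
    posttrigger: float = 0.040
    trigger_threshold: float = 8.0          # g, per axis
    accel_range: float = 200.0              # +/- g
    gyro_range: float = 35.0                # +/- rad/s
    primary_cutoff: float = 200.0           # Hz, -6 dB, all events
    moderate_cutoff: float = 100.0          # Hz, second pass for noise class 1
    severe_cutoff: float = 50.0             # Hz, second pass for noise class 2
    r_mh: tuple[float, float, float] = (-0.082, 0.009, -0.065)
    rvci_weights: tuple[float, float, float] = (1.00, 1.00, 1.17)
    rvci_duration: float = 0.010            # s, max window for the velocity change
    gravity_constant: float = 9.80665       # m/s^2 per g

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_mh", tuple(float(v) for v in self.r_mh))
        object.__setattr__(self, "rvci_weights", tuple(float(v) for v in self.rvci_weights))
        if len(self.r_mh) != 3:
            raise ConfigError("r_mh must be a 3-vector")
        if len(self.rvci_weights) != 3:
            raise ConfigError("rvci_weights must be a 3-vector")
        if abs((self.pretrigger + self.posttrigger) - 0.050) > 1e-12:
            raise ConfigError(
                f"pretrigger + posttrigger must equal 0.050 s, got "
                f"{self.pretrigger + self.posttrigger:.6f}")
        if self.rvci_duration <= 0:
            raise ConfigError("rvci_duration must be positive")
        if not (self.primary_cutoff > self.moderate_cutoff > self.severe_cutoff > 0):
            raise ConfigError("cutoffs must be strictly decreasing across noise classes")
        nyquist = self.sample_rate / 2.0
        if self.primary_cutoff >= nyquist:
            raise ConfigError(f"primary_cutoff {self.primary_cutoff} Hz >= Nyquist {nyquist} Hz")

    @property
    def window_samples(self) -> int:
        """Samples per triggered window (160 at the defaults)."""
        return int(round((self.pretrigger + self.posttrigger) * self.sample_rate))

    @property
    def trigger_index(self) -> int:
        """Index of the trigger sample inside a window (32 at the defaults)."""
        return int(round(self.pretrigger * self.sample_rate))

    @property
    def rvci_window_samples(self) -> int:
        """Maximum sample lag for the RVCI pair search (32 at the defaults)."""
        return int(round(self.rvci_duration * self.sample_rate))

    def cutoff_for_class(self, noise_class: int) -> float:
        """Last applied cutoff for a noise class (200, 100 or 50 Hz)."""
        if noise_class == 0:
            return self.primary_cutoff
        if noise_class == 1:
            return self.moderate_cutoff
        if noise_class == 2:
            return self.severe_cutoff
        raise ConfigError(f"noise_class must be 0, 1 or 2, got {noise_class}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Inclusion rules, denominators and inference settings."""

    full_match_minutes: float = 80.0
    wear_compliance_fraction: float = 0.90   # strict >: 'over 90%'
    min_involvements_individual: int = 15    # strict >: 'greater than 15'
    headline_pla: float = 25.0               # g
    link_window_s: float = 5.0               # HAE <-> involvement matching half-window
    n_bootstrap: int = 2000
    bootstrap_re_draws: int = 500            # Monte-Carlo random-effect draws per bootstrap draw
    ci_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.wear_compliance_fraction < 1.0:
            raise ConfigError("wear_compliance_fraction must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.full_match_minutes <= 0:
            raise ConfigError("full_match_minutes must be positive")
        if self.link_window_s <= 0:
            raise ConfigError("link_window_s must be positive")


@dataclass(frozen=True)
class Config:
    """Bundle of the three configuration groups."""

    thresholds: ThresholdGrid = field(default_factory=ThresholdGrid)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


_SECTIONS = {
    "thresholds": ThresholdGrid,
    "kinematics": KinematicsConfig,
    "analysis": AnalysisConfig,
}


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    try:
        return cls(**mapping)
    except TypeError as exc:  # wrong value shape
        raise ConfigError(f"section '{section}': {exc}") from exc


def load_config(path: str | Path | None = None) -> Config:
    """Load a :class:`Config` from a YAML mapping, filling defaults.

    An absent path, empty file or empty mapping yields all defaults.  The
    file may contain any subset of the sections ``thresholds``,
    ``kinematics`` and ``analysis``; unknown sections or keys raise
    :class:`ConfigError` naming the offender, as does any violated
    invariant (e.g. a trigger window that is not 50 ms).
    """
    if path is None:
        return Config()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        return Config()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    built = {}
    for section, cls in _SECTIONS.items():
        mapping = raw.get(section) or {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        built[section] = _build_section(cls, mapping, section)
    return Config(**built)


def save_config(cfg: Config, path: str | Path) -> None:
    """Write a config back to YAML such that ``load_config`` round-trips."""
    payload = {
        "thresholds": _listify(asdict(cfg.thresholds)),
        "kinematics": _listify(asdict(cfg.kinematics)),
        "analysis": _listify(asdict(cfg.analysis)),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _listify(d: dict) -> dict:
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
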
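"""Run configuration: analysis thresholds, scenario, seed and output paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .synthetic import SyntheticScenario

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration field is out of its documented range."""


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the study's defaults.

    Thresholds: transect retention at ``r2_min``/``p_max``, median
    aggregation above ``median_threshold`` transects, exposure quantile
    ``q``, near-zero-lapse removal ``outlier_fraction``, resampling
    ``n_resample``/``iterations``/``alpha`` and the control lapse rate
    ``constant_lrt`` (°C/km).
    """

    seed: int = 0
    r2_min: float = 0.5
    p_max: float = 0.05
    median_threshold: int = 10
    prominence_min: float = 100.0  # m
    q: float = 0.8
    threat_mode: str = "union"
    outlier_fraction: float = 0.01
    n_resample: int = 30
    iterations: int = 1000
    alpha: float = 0.05
    constant_lrt: float = 5.5  # °C/km
    years: float = 40.0
    elev_bin_width: float = 250.0  # m
    lat_bin_width: float = 2.0  # degrees
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)

    def __post_init__(self) -> None:
        self.validate()
        # the pipeline seed governs the scenario too
        self.scenario.seed = self.seed

    def validate(self) -> None:
        checks = [
            ("r2_min", 0 <= self.r2_min <= 1),
            ("p_max", 0 < self.p_max <= 1),
            ("median_threshold", self.median_threshold >= 0),
            ("prominence_min", self.prominence_min >= 0),
            ("q", 0 < self.q < 1),
            ("threat_mode", self.threat_mode in ("union", "intersection")),
            ("outlier_fraction", 0 <= self.outlier_fraction < 0.5),
            ("n_resample", self.n_resample >= 1),
            ("iterations", self.iterations >= 1),
            ("alpha", 0 < self.alpha < 1),
            ("constant_lrt", self.constant_lrt != 0),
            ("years", self.years > 0),
            ("elev_bin_width", self.elev_bin_width > 0),
            ("lat_bin_width", self.lat_bin_width > 0),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ConfigError(f"invalid configuration field(s): {', '.join(bad)}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scenario"] = self.scenario.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scen = d.pop("scenario", None)
        known = {f for f in cls.__dataclass_fields__ if f != "scenario"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        cfg = cls(**d)
        if scen is not None:
            cfg.scenario = SyntheticScenario.from_dict(scen)
            cfg.scenario.seed = cfg.seed
        return cfg
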
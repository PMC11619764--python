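"""Configuration objects for the synthetic cohort and the pipeline.

``SimulationConfig`` houses the generating model: fixed effects for each
summary feature split into a between-person part (on the participant's
global level, X-bar) and a within-person part (on the weekly deviation,
delta-X), covariate effects, the 2x2 random-effect covariance of
(intercept, sqrt-week slope), and the residual scale, all in PHQ-8 points.
Defaults emulate a 131-person, 16-week outpatient cohort with biweekly
PHQ-8 waves and near-complete sensing coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _default_effect_map() -> dict[str, tuple[float, float]]:
    # feature|statistic -> (beta_between, beta_within), PHQ points per unit
    return {
        "wake_time|sd": (1.5, 0.0),
        "step_count_k|mean": (0.0, -0.16),
    }


def _default_covariate_effects() -> dict[str, float]:
    return {
        "age": 0.03,
        "female": 0.5,
        "employed": -0.8,
        "alone": 0.6,
        "treatment": 0.0,
        "sqrt_week": -0.9,
        "treat_sqrt_week": -0.35,
    }


def _default_trait_distributions() -> dict[str, dict[str, float]]:
    """Person-level trait hyper-parameters (see docs/methods.md)."""
    return {
        "age": {"mean": 32.8, "sd": 11.3, "lo": 18.0, "hi": 70.0},
        "female_prob": {"p": 0.733},
        "employed_prob": {"p": 0.855},
        "alone_prob": {"p": 0.168},
        "treatment_prob": {"p": 0.5},
        # sleep timing (hours; sleep_start on the since-previous-midnight axis)
        "wake_mu": {"mean": 7.5, "sd": 1.0, "lo": 5.0, "hi": 11.0},
        "wake_sd": {"log_mean": np.log(0.8), "log_sd": 0.5, "lo": 0.1, "hi": 2.5},
        "sleep_start_mu": {"mean": 23.4, "sd": 1.0, "lo": 20.5, "hi": 26.5},
        "sleep_start_sd": {"log_mean": np.log(0.6), "log_sd": 0.5, "lo": 0.05, "hi": 2.0},
        "interruption_rate": {"shape": 2.0, "scale": 0.5},
        # activity
        "steps_mu": {"log_mean": np.log(7000.0), "log_sd": 0.45, "lo": 1500.0, "hi": 20000.0},
        "steps_cv": {"mean": 0.35, "sd": 0.10, "lo": 0.15, "hi": 0.60},
        "walk_rate_mu": {"mean": 1.5, "sd": 0.25, "lo": 0.8, "hi": 2.5},
        "walk_rate_day_sd": {"value": 0.15},
        # mobility
        "away_clusters_mu": {"mean": 3.0, "sd": 1.0, "lo": 1.0, "hi": 6.0},
        "home_frac_mu": {"mean": 0.65, "sd": 0.12, "lo": 0.38, "hi": 0.95},
        "home_frac_day_sd": {"value": 0.07},
        "away_evenness": {"mean": 1.2, "sd": 0.4, "lo": 0.3, "hi": 3.0},
        "dist_med": {"log_mean": np.log(2000.0), "log_sd": 0.6},
        "dist_day_log_sd": {"value": 0.8},
    }


@dataclass
class SimulationConfig:
    """Full specification of the synthetic cohort generator."""

    n_participants: int = 131
    n_weeks: int = 16
    phq_waves: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
    seed: int = 0
    start_date: str = "2023-01-02"
    phq_hour: float = 18.0
    intercept: float = 9.5
    effect_map: dict[str, tuple[float, float]] = field(default_factory=_default_effect_map)
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    random_effect_cov: list[list[float]] = field(
        default_factory=lambda: [[9.0, -0.4], [-0.4, 0.16]]
    )
    residual_sd: float = 2.5
    day_missing_prob: float = 0.0
    wave_missing_prob: float = 0.0
    #: informative (symptom-linked) day-level missingness, off by default
    informative_missingness: bool = False
    informative_missing_slope: float = 0.0
    #: Beta(a, b) draw of each stream-day's coverage (median ~0.99)
    coverage_beta: tuple[float, float] = (75.0, 0.8)
    trait_distributions: dict[str, dict[str, float]] = field(
        default_factory=_default_trait_distributions
    )

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.n_weeks < 1:
            raise ConfigError("n_weeks must be >= 1")
        waves = tuple(self.phq_waves)
        if any(b <= a for a, b in zip(waves, waves[1:])):
            raise ConfigError("phq_waves must be strictly increasing")
        if waves and (waves[0] < 1 or waves[-1] > self.n_weeks):
            raise ConfigError("phq_waves must lie within 1..n_weeks")
        for name in ("day_missing_prob", "wave_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be > 0")
        cov = np.asarray(self.random_effect_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ConfigError("random_effect_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigError("random_effect_cov must be positive semi-definite")
        a, b = self.coverage_beta
        if a <= 0 or b <= 0:
            raise ConfigError("coverage_beta parameters must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phq_waves"] = list(self.phq_waves)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config field(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "phq_waves" in kwargs:
            kwargs["phq_waves"] = tuple(kwargs["phq_waves"])
        if "effect_map" in kwargs:
            kwargs["effect_map"] = {k: tuple(v) for k, v in kwargs["effect_map"].items()}
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path) -> dict:
    """Read a YAML pipeline configuration file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
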
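"""Pipeline configuration: parameter groups with defaults, YAML round-trip.

Defaults follow the published analysis settings wherever the original study
states one: 15 Hz fourth-order low-pass on position, 30 ms Savitzky-Golay
differentiation, 31 deg/s desaccading threshold with 50 ms padding and a
10 ms minimum-segment rule, 45% maximum excluded fraction per test, and a
0.05 significance level.  Quantities the study leaves open (sampling rate,
noise magnitudes, saccade statistics) are configurable with documented
defaults in :mod:`oculearn.synthetic`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import InvalidArgumentError

__all__ = [
    "FilterParams",
    "SavgolParams",
    "FitParams",
    "StatsParams",
    "AnalysisParams",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass
class FilterParams:
    """Low-pass position filter (Butterworth)."""

    cutoff_hz: float = 15.0
    order: int = 4
    #: forward-backward application; False gives a single causal pass
    zero_phase: bool = True


@dataclass
class SavgolParams:
    """Savitzky-Golay differentiator settings."""

    window_ms: float = 30.0
    polyorder: int = 2


@dataclass
class FitParams:
    """Fixed-frequency sinusoid fit and desaccading parameters."""

    threshold_degps: float = 31.0
    pad_ms: float = 50.0
    min_segment_ms: float = 10.0
    max_excluded_fraction: float = 0.45
    #: which runs the 10 ms segment rule removes: "retained" drops surviving
    #: fragments too short to constrain the fit; "excluded" instead restores
    #: sub-threshold-duration threshold crossings before padding
    min_segment_applies: str = "retained"
    #: what the rejection-rule fraction counts: "all" = everything excluded
    #: for any reason (pads and short segments included); "threshold_only" =
    #: just the samples that crossed the residual threshold
    excluded_fraction_counts: str = "all"
    #: optional override; when None the stimulus frequency is taken from
    #: each trace's metadata
    frequency_hz: float | None = None


@dataclass
class StatsParams:
    alpha: float = 0.05
    #: report Greenhouse-Geisser corrected p alongside the uncorrected one
    sphericity_correction: bool = True


@dataclass
class AnalysisParams:
    """Everything needed to turn a raw position trace into a measurement."""

    filter: FilterParams = field(default_factory=FilterParams)
    savgol: SavgolParams = field(default_factory=SavgolParams)
    fit: FitParams = field(default_factory=FitParams)


@dataclass
class PipelineConfig:
    """Top-level configuration for the simulate/analyze/stats pipeline."""

    seed: int = 0
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    stats: StatsParams = field(default_factory=StatsParams)
    #: simulator section, passed to :func:`oculearn.synthetic.design_from_config`
    #: and :func:`oculearn.synthetic.cohort_from_config`; empty when the
    #: pipeline only analyses existing recordings
    design: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        analysis = d.get("analysis", {}) or {}
        cfg = cls(
            seed=int(d.get("seed", 0)),
            analysis=AnalysisParams(
                filter=_build(FilterParams, analysis.get("filter")),
                savgol=_build(SavgolParams, analysis.get("savgol")),
                fit=_build(FitParams, analysis.get("fit")),
            ),
            stats=_build(StatsParams, d.get("stats")),
            design=dict(d.get("design", {}) or {}),
            cohort=dict(d.get("cohort", {}) or {}),
        )
        return cfg


def _build(cls, section):
    section = dict(section or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise InvalidArgumentError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    return cls(**section)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration, for the run manifest."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
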
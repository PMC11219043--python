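"""Block summaries and VOR/OKR learning curves.

The three tests of a VOR testing block are averaged (over valid tests
only).  VOR learning (dVOR) is the percent change in that block mean after
each 10 min training block, relative to the baseline block measured just
before training.  For pre-training sessions the points at negative times
are referenced to the session's initial (-30 min) block, while the
VOR-increase phase (0..30 min) is referenced to the time-0 block.

OKR learning (dOKR) averages blocks 1-3 for the pre-training baseline and
blocks 58-60 for the post-training measure; intermediate points are
reported for blocks 10, 20, 30, 40 and 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .desaccade import TestMeasurement
from .core import InvalidArgumentError, MissingBaselineError

__all__ = [
    "BlockSummary",
    "LearningPoint",
    "LearningCurve",
    "compute_gain",
    "summarize_block",
    "vor_learning_curve",
    "okr_learning",
    "learning_tables",
]

OKR_BASELINE_BLOCKS = (1, 2, 3)
OKR_POST_BLOCKS = (58, 59, 60)
OKR_INTERMEDIATE_BLOCKS = (10, 20, 30, 40, 50)


@dataclass
class BlockSummary:
    """Mean response amplitude over the valid tests of one block."""

    time_min: float
    mean_amplitude: float | None
    n_valid: int
    metadata: dict = field(default_factory=dict)


@dataclass
class LearningPoint:
    time_min: float
    delta_pct: float
    amplitude: float | None = None
    n_valid: int | None = None


@dataclass
class LearningCurve:
    """Percent change in response amplitude vs pre-training baseline for
    one animal and session."""

    points: list[LearningPoint]
    protocol: str = ""
    animal: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        times = [p.time_min for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("learning-curve times must be strictly increasing")

    def delta_at(self, time_min: float) -> float | None:
        for p in self.points:
            if p.time_min == time_min:
                return p.delta_pct
        return None


def compute_gain(amplitude: float, stimulus_peak: float) -> float:
    """Gain = eye-movement amplitude / stimulus amplitude (dimensionless)."""
    if stimulus_peak <= 0:
        raise InvalidArgumentError("stimulus peak velocity must be positive")
    return amplitude / stimulus_peak


def summarize_block(measurements: list[TestMeasurement]) -> BlockSummary:
    """Average the valid tests of one block.

    All measurements must share the same block identity (``animal`` and
    ``time_min`` metadata, when present).
    """
    if not measurements:
        raise InvalidArgumentError("no measurements given")
    keys = {
        (m.metadata.get("animal"), m.metadata.get("time_min")) for m in measurements
    }
    if len(keys) > 1:
        raise InvalidArgumentError(f"measurements span multiple blocks: {sorted(keys)}")
    time_min = measurements[0].metadata.get("time_min")
    amps = [m.amplitude for m in measurements if m.valid]
    mean = float(np.mean(amps)) if amps else None
    meta = dict(measurements[0].metadata)
    meta.pop("test_index", None)
    return BlockSummary(
        time_min=float(time_min) if time_min is not None else 0.0,
        mean_amplitude=mean,
        n_valid=len(amps),
        metadata=meta,
    )


def _pct(value: float, reference: float) -> float:
    return 100.0 * (value - reference) / reference


def vor_learning_curve(
    blocks: list[BlockSummary], baseline_time: float = 0.0
) -> LearningCurve:
    """Percent change in VOR amplitude relative to the pre-training baseline.

    Points at ``baseline_time`` and later are referenced to the
    ``baseline_time`` block.  When the session includes earlier
    (pre-training) blocks, those points are referenced to the earliest
    block instead, so both phases read as change since their own start.
    Blocks with no valid test yield no point (never an imputed zero).
    """
    blocks = sorted(blocks, key=lambda b: b.time_min)
    by_time = {b.time_min: b for b in blocks}
    base = by_time.get(baseline_time)
    if base is None or base.mean_amplitude is None:
        raise MissingBaselineError(f"no valid baseline block at {baseline_time} min")
    pre_times = [b.time_min for b in blocks if b.time_min < baseline_time]
    pre_ref = None
    if pre_times:
        first = by_time[min(pre_times)]
        if first.mean_amplitude is None:
            raise MissingBaselineError(
                f"no valid pre-training reference block at {first.time_min} min"
            )
        pre_ref = first
    points: list[LearningPoint] = []
    for b in blocks:
        if b.mean_amplitude is None:
            continue
        ref = pre_ref if (pre_ref is not None and b.time_min < baseline_time) else base
        delta = 0.0 if b is ref else _pct(b.mean_amplitude, ref.mean_amplitude)
        points.append(LearningPoint(b.time_min, delta, b.mean_amplitude, b.n_valid))
    meta = blocks[0].metadata
    return LearningCurve(
        points,
        protocol=str(meta.get("protocol", "")),
        animal=str(meta.get("animal", "")),
        condition=str(meta.get("group", "")),
    )


def okr_learning(
    block_amplitudes, metadata: dict | None = None
) -> LearningCurve:
    """OKR learning curve from the 60 per-block amplitudes.

    ``block_amplitudes`` holds one value per 50 s block in order (None/NaN
    for rejected blocks).  Baseline is the mean of blocks 1-3 (time 0);
    the post-training point (time 60) is the mean of blocks 58-60;
    intermediate points use the single block ending at 10, 20, 30, 40 and
    50 min.  Each triad needs at least one valid block.
    """
    amps = np.array(
        [np.nan if a is None else float(a) for a in block_amplitudes], dtype=float
    )
    if amps.size != 60:
        raise InvalidArgumentError(f"expected 60 block amplitudes, got {amps.size}")
    base_vals = amps[[b - 1 for b in OKR_BASELINE_BLOCKS]]
    post_vals = amps[[b - 1 for b in OKR_POST_BLOCKS]]
    if np.isnan(base_vals).all() or np.isnan(post_vals).all():
        raise MissingBaselineError("no valid block in the baseline or post triad")
    baseline = float(np.nanmean(base_vals))
    post = float(np.nanmean(post_vals))
    meta = metadata or {}
    points = [
        LearningPoint(0.0, 0.0, baseline, int(np.sum(~np.isnan(base_vals))))
    ]
    for b in OKR_INTERMEDIATE_BLOCKS:
        a = amps[b - 1]
        if not np.isnan(a):
            points.append(LearningPoint(float(b), _pct(float(a), baseline), float(a), 1))
    points.append(
        LearningPoint(60.0, _pct(post, baseline), post, int(np.sum(~np.isnan(post_vals))))
    )
    return LearningCurve(
        points,
        protocol=str(meta.get("protocol", "okr_adaptation")),
        animal=str(meta.get("animal", "")),
        condition=str(meta.get("group", "")),
    )


def learning_tables(
    measurements: list[TestMeasurement], baseline_time: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-test measurements into tidy block and learning tables.

    Returns ``(blocks, learning)``.  ``blocks`` has one row per animal and
    measurement point (columns: animal, group, protocol, time_min,
    amplitude, gain, n_valid).  ``learning`` has one row per learning
    point (adds delta_pct); VOR-style sessions use
    :func:`vor_learning_curve`, OKR sessions :func:`okr_learning`.
    Animals whose baseline cannot be formed are omitted from ``learning``.
    """
    groups: dict[tuple, list[TestMeasurement]] = {}
    for m in measurements:
        key = (m.metadata.get("animal"), m.metadata.get("time_min"))
        groups.setdefault(key, []).append(m)
    summaries: dict[str, list[BlockSummary]] = {}
    block_rows = []
    for (animal, _), ms in sorted(groups.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        s = summarize_block(ms)
        summaries.setdefault(str(animal), []).append(s)
        peak = s.metadata.get("peak_velocity_degps")
        block_rows.append(
            {
                "animal": animal,
                "group": s.metadata.get("group"),
                "protocol": s.metadata.get("protocol"),
                "time_min": s.time_min,
                "amplitude": s.mean_amplitude,
                "gain": (
                    compute_gain(s.mean_amplitude, peak)
                    if s.mean_amplitude is not None and peak
                    else None
                ),
                "n_valid": s.n_valid,
            }
        )
    blocks_df = pd.DataFrame(block_rows)
    learn_rows = []
    for animal, blocks in summaries.items():
        meta = blocks[0].metadata
        protocol = str(meta.get("protocol", ""))
        try:
            if protocol == "okr_adaptation":
                amps = [None] * 60
                for b in blocks:
                    amps[int(round(b.time_min)) - 1] = b.mean_amplitude
                curve = okr_learning(amps, meta)
            else:
                curve = vor_learning_curve(blocks, baseline_time)
        except MissingBaselineError:
            continue
        peak = meta.get("peak_velocity_degps")
        for p in curve.points:
            learn_rows.append(
                {
                    "animal": animal,
                    "group": curve.condition,
                    "protocol": curve.protocol,
                    "time_min": p.time_min,
                    "amplitude": p.amplitude,
                    "gain": (
                        compute_gain(p.amplitude, peak)
                        if p.amplitude is not None and peak
                        else None
                    ),
                    "delta_pct": p.delta_pct,
                    "n_valid": p.n_valid,
                }
            )
    return blocks_df, pd.DataFrame(learn_rows)
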
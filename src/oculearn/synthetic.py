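"""Synthetic raw eye-position traces and simulated cohorts.

The generator is the inverse of the measurement pipeline: it builds eye
velocity as a scaled, phase-shifted copy of the stimulus sinusoid, adds
half-sine saccade velocity pulses, white velocity noise and slow drift,
integrates to position, and adds independent position sensor noise.  Every
trace records its ground truth in metadata, so each downstream stage can
be validated by parameter recovery.

Experimental designs mirror the VOR/OKR training protocols: VOR testing
blocks of three 45 s tests, 10 min training blocks repeated three times,
pre-training sessions (VOR-decrease or vestibular-only), and 60-block OKR
sessions of 50 s training blocks (each followed by 10 s in darkness).

Defaults the original study does not state, chosen once as realistic for
head-fixed mice on a magnetic eye-tracking rig: 1000 samples/s acquisition,
saccade rate 1/s with peak velocities 100-300 deg/s and durations 20-80 ms,
velocity noise 2 deg/s SD, position sensor noise 0.01 deg SD, 5%
between-animal log-normal gain jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import EyeTrace, InvalidArgumentError

__all__ = [
    "MODALITIES",
    "PROTOCOLS",
    "StimulusSpec",
    "SaccadeEvent",
    "TrueState",
    "Block",
    "ExperimentDesign",
    "GroupSpec",
    "CohortSpec",
    "CohortDataset",
    "make_stimulus_velocity",
    "sample_saccade_train",
    "synthesize_eye_trace",
    "vor_design",
    "pretraining_design",
    "okr_design",
    "design_from_config",
    "cohort_from_config",
    "simulate_cohort",
]

MODALITIES = ("vestibular", "visual", "paired_increase", "paired_decrease", "none")
PROTOCOLS = (
    "vor_increase",
    "vor_decrease",
    "vestibular_only_pretrain",
    "okr_adaptation",
    "composite",
)

DEFAULT_RATE = 1000.0  # samples/s

VOR_TEST_DURATION_S = 45.0
VOR_TESTS_PER_BLOCK = 3
VOR_TRAINING_BLOCK_S = 600.0
VOR_TRAINING_BLOCKS = 3
OKR_BLOCKS = 60
OKR_BLOCK_DURATION_S = 50.0


@dataclass
class StimulusSpec:
    """Sinusoidal stimulus: turntable rotation, drum rotation, or a pairing.

    ``paired_decrease`` means the drum moves with the head (driving learned
    gain decreases); ``paired_increase`` means it moves opposite to the
    head (driving gain increases).
    """

    frequency: float = 1.0
    peak_velocity: float = 10.0
    modality: str = "vestibular"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidArgumentError("stimulus frequency must be positive")
        if self.peak_velocity <= 0:
            raise InvalidArgumentError("stimulus peak velocity must be positive")
        if self.modality not in MODALITIES:
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")


@dataclass
class SaccadeEvent:
    """One saccade/artifact: a half-sine velocity pulse."""

    onset_time: float
    duration: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidArgumentError("saccade duration must be positive")

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration


@dataclass
class TrueState:
    """Ground truth for one synthetic trace.

    gain
        Eye-velocity amplitude divided by stimulus peak velocity.
    phase
        Radians relative to the ideal compensatory response (0 = perfectly
        anti-phase to head velocity for the VOR).
    noise_sd
        White velocity noise SD, deg/s.
    drift_rate
        Constant slow-phase drift, deg/s (linear position drift).
    """

    gain: float = 1.0
    phase: float = 0.0
    noise_sd: float = 0.0
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise InvalidArgumentError("gain must be >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_stimulus_velocity(
    spec: StimulusSpec, duration: float, rate: float = DEFAULT_RATE
) -> np.ndarray:
    """Stimulus velocity profile: ``peak_velocity * sin(2*pi*f*t)``, deg/s."""
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if rate < 100:
        raise InvalidArgumentError("sampling rate must be at least 100 samples/s")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return spec.peak_velocity * np.sin(2.0 * np.pi * spec.frequency * t)


def sample_saccade_train(
    duration: float,
    rate_per_s: float,
    amp_range: tuple[float, float] = (100.0, 300.0),
    dur_range: tuple[float, float] = (0.020, 0.080),
    seed=None,
) -> list[SaccadeEvent]:
    """Draw a homogeneous-Poisson saccade train, thinned to be non-overlapping.

    Onsets are uniform on [0, duration) with a Poisson count of mean
    ``rate_per_s * duration``; events whose pulse would overlap an earlier
    accepted event, or run past the end of the trace, are dropped.
    Amplitudes are uniform over ``amp_range`` with random sign; durations
    uniform over ``dur_range``.
    """
    if rate_per_s < 0:
        raise InvalidArgumentError("saccade rate must be >= 0")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = _as_rng(seed)
    n = rng.poisson(rate_per_s * duration)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, duration, n))
    durs = rng.uniform(dur_range[0], dur_range[1], n)
    amps = rng.uniform(amp_range[0], amp_range[1], n) * rng.choice([-1.0, 1.0], n)
    events: list[SaccadeEvent] = []
    t_free = 0.0
    for onset, dur, amp in zip(onsets, durs, amps):
        if onset < t_free or onset + dur > duration:
            continue
        events.append(SaccadeEvent(float(onset), float(dur), float(amp)))
        t_free = onset + dur
    return events


def _check_saccades(saccades: list[SaccadeEvent], duration: float) -> None:
    prev_end = -np.inf
    for ev in saccades:
        if ev.onset_time < prev_end:
            raise InvalidArgumentError("saccade events overlap or are unsorted")
        if ev.onset_time < 0 or ev.end_time > duration:
            raise InvalidArgumentError("saccade extends outside the trace")
        prev_end = ev.end_time


def synthesize_eye_trace(
    spec: StimulusSpec,
    state: TrueState,
    saccades: list[SaccadeEvent] | None = None,
    duration: float = VOR_TEST_DURATION_S,
    rate: float = DEFAULT_RATE,
    seed=None,
    position_noise_sd: float = 0.01,
    metadata: dict | None = None,
) -> EyeTrace:
    """Generate one raw eye-position trace with known ground truth.

    Eye velocity is ``-gain * peak * sin(2*pi*f*t + phase)`` (anti-phase to
    the stimulus at phase 0, i.e. compensatory), plus half-sine saccade
    pulses, white noise and constant drift.  Position is the cumulative
    trapezoidal integral of velocity plus independent white position noise.
    """
    saccades = saccades or []
    _check_saccades(saccades, duration)
    rng = _as_rng(seed)
    n = int(round(duration * rate))
    if n < 2:
        raise InvalidArgumentError("duration too short at this sampling rate")
    t = np.arange(n) / rate
    w = 2.0 * np.pi * spec.frequency
    velocity = -state.gain * spec.peak_velocity * np.sin(w * t + state.phase)
    for ev in saccades:
        i0 = int(np.ceil(ev.onset_time * rate))
        i1 = int(np.floor(ev.end_time * rate))
        if i1 <= i0:
            continue
        tau = t[i0:i1] - ev.onset_time
        velocity[i0:i1] += ev.peak_velocity * np.sin(np.pi * tau / ev.duration)
    if state.noise_sd > 0:
        velocity = velocity + rng.normal(0.0, state.noise_sd, n)
    if state.drift_rate:
        velocity = velocity + state.drift_rate
    position = cumulative_trapezoid(velocity, dx=1.0 / rate, initial=0.0)
    if position_noise_sd > 0:
        position = position + rng.normal(0.0, position_noise_sd, n)
    meta = {
        "frequency_hz": spec.frequency,
        "peak_velocity_degps": spec.peak_velocity,
        "modality": spec.modality,
        "true_gain": state.gain,
        "true_phase": state.phase,
        "noise_sd_degps": state.noise_sd,
        "drift_rate_degps": state.drift_rate,
        "n_saccades": len(saccades),
    }
    if metadata:
        meta.update(metadata)
    return EyeTrace(position, rate, 0.0, meta)


# ---------------------------------------------------------------------------
# Experimental designs


@dataclass
class Block:
    """One block of a session.

    ``measured`` blocks produce traces that the analysis quantifies: VOR
    testing blocks (``n_tests`` 45 s tests of the vestibular stimulus in
    darkness) and OKR training blocks (one 50 s measured tracking
    response each).  Unmeasured training blocks advance the protocol clock
    only — the simulator applies their learning effect through the gain
    trajectory rather than simulating plasticity.
    """

    kind: str  # "testing" | "training"
    duration_s: float
    stimulus: StimulusSpec
    measured: bool = False
    n_tests: int = 0
    test_duration_s: float = 0.0
    time_min: float | None = None  # label of the measurement point


@dataclass
class ExperimentDesign:
    protocol: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise InvalidArgumentError(f"unknown protocol {self.protocol!r}")
        if not self.blocks:
            raise InvalidArgumentError("design has no blocks")
        if self.protocol != "composite":
            self._validate_protocol()

    def _validate_protocol(self) -> None:
        if self.protocol == "okr_adaptation":
            measured = self.measured_blocks
            if len(measured) != OKR_BLOCKS or any(
                b.duration_s != OKR_BLOCK_DURATION_S for b in measured
            ):
                raise InvalidArgumentError(
                    f"OKR sessions contain {OKR_BLOCKS} training blocks of "
                    f"{OKR_BLOCK_DURATION_S:g} s"
                )
            return
        for b in self.blocks:
            if b.kind == "testing":
                if b.n_tests != VOR_TESTS_PER_BLOCK or b.test_duration_s != VOR_TEST_DURATION_S:
                    raise InvalidArgumentError(
                        "VOR testing blocks contain exactly 3 tests of 45 s"
                    )
            elif b.kind == "training" and b.duration_s != VOR_TRAINING_BLOCK_S:
                raise InvalidArgumentError("VOR training blocks are 600 s")
        n_train = sum(b.kind == "training" for b in self.blocks)
        if n_train % VOR_TRAINING_BLOCKS != 0:
            raise InvalidArgumentError(
                "VOR training phases consist of three 10 min blocks"
            )

    @property
    def measured_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.measured]

    @property
    def measurement_times_min(self) -> list[float]:
        return [b.time_min for b in self.measured_blocks]

    @property
    def n_time_points(self) -> int:
        return len(self.measured_blocks)


def _testing_block(stimulus: StimulusSpec, time_min: float) -> Block:
    return Block(
        kind="testing",
        duration_s=VOR_TESTS_PER_BLOCK * VOR_TEST_DURATION_S,
        stimulus=StimulusSpec(stimulus.frequency, stimulus.peak_velocity, "vestibular"),
        measured=True,
        n_tests=VOR_TESTS_PER_BLOCK,
        test_duration_s=VOR_TEST_DURATION_S,
        time_min=time_min,
    )


def vor_design(
    protocol: str = "vor_increase",
    frequency_hz: float = 1.0,
    peak_velocity_degps: float = 10.0,
) -> ExperimentDesign:
    """Standard VOR learning session: baseline test, then 3 x (10 min
    training + testing block), measurement points at 0/10/20/30 min."""
    if protocol not in ("vor_increase", "vor_decrease"):
        raise InvalidArgumentError("protocol must be vor_increase or vor_decrease")
    pairing = "paired_increase" if protocol == "vor_increase" else "paired_decrease"
    stim = StimulusSpec(frequency_hz, peak_velocity_degps, "vestibular")
    train_stim = StimulusSpec(frequency_hz, peak_velocity_degps, pairing)
    blocks = [_testing_block(stim, 0.0)]
    for k in range(1, VOR_TRAINING_BLOCKS + 1):
        blocks.append(Block("training", VOR_TRAINING_BLOCK_S, train_stim))
        blocks.append(_testing_block(stim, 10.0 * k))
    return ExperimentDesign(protocol, blocks)


def pretraining_design(
    pretrain: str = "vor_decrease",
    frequency_hz: float = 1.0,
    peak_velocity_degps: float = 10.0,
) -> ExperimentDesign:
    """Pre-training session: three 10 min pre-training blocks (VOR-decrease
    pairing or vestibular-only), a testing block before each, then the
    standard VOR-increase phase.  Measurement points at -30/-20/-10 and
    0/10/20/30 min relative to VOR-increase training onset."""
    if pretrain == "vor_decrease":
        pre_modality = "paired_decrease"
        protocol = "composite"
    elif pretrain == "vestibular_only":
        pre_modality = "vestibular"
        protocol = "vestibular_only_pretrain"
    else:
        raise InvalidArgumentError("pretrain must be vor_decrease or vestibular_only")
    stim = StimulusSpec(frequency_hz, peak_velocity_degps, "vestibular")
    pre_stim = StimulusSpec(frequency_hz, peak_velocity_degps, pre_modality)
    inc_stim = StimulusSpec(frequency_hz, peak_velocity_degps, "paired_increase")
    blocks: list[Block] = []
    for k in range(VOR_TRAINING_BLOCKS):
        blocks.append(_testing_block(stim, -30.0 + 10.0 * k))
        blocks.append(Block("training", VOR_TRAINING_BLOCK_S, pre_stim))
    blocks.append(_testing_block(stim, 0.0))
    for k in range(1, VOR_TRAINING_BLOCKS + 1):
        blocks.append(Block("training", VOR_TRAINING_BLOCK_S, inc_stim))
        blocks.append(_testing_block(stim, 10.0 * k))
    return ExperimentDesign(protocol, blocks)


def okr_design(
    frequency_hz: float = 1.0, peak_velocity_degps: float = 10.0
) -> ExperimentDesign:
    """OKR adaptation session: sixty 50 s optokinetic training blocks, each
    followed by 10 s in darkness; every block is itself measured.  Block k
    is labelled with its end time in minutes (1..60)."""
    stim = StimulusSpec(frequency_hz, peak_velocity_degps, "visual")
    blocks = [
        Block(
            kind="training",
            duration_s=OKR_BLOCK_DURATION_S,
            stimulus=stim,
            measured=True,
            n_tests=1,
            test_duration_s=OKR_BLOCK_DURATION_S,
            time_min=float(k + 1),
        )
        for k in range(OKR_BLOCKS)
    ]
    return ExperimentDesign("okr_adaptation", blocks)


def design_from_config(section: dict) -> ExperimentDesign:
    """Build a design from the ``design:`` config section."""
    section = dict(section or {})
    protocol = section.get("protocol", "vor_increase")
    freq = float(section.get("frequency_hz", 1.0))
    peak = float(section.get("peak_velocity_degps", 10.0))
    if protocol in ("vor_increase", "vor_decrease"):
        return vor_design(protocol, freq, peak)
    if protocol == "vor_decrease_pretrain":
        return pretraining_design("vor_decrease", freq, peak)
    if protocol == "vestibular_only_pretrain":
        return pretraining_design("vestibular_only", freq, peak)
    if protocol == "okr_adaptation":
        return okr_design(freq, peak)
    raise InvalidArgumentError(f"unknown design protocol {protocol!r}")


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class GroupSpec:
    """One experimental group: size and its true gain trajectory, one gain
    per measurement time point of the design."""

    n_animals: int
    gain_trajectory: list[float]

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise InvalidArgumentError("n_animals must be >= 1")
        if any(g < 0 for g in self.gain_trajectory):
            raise InvalidArgumentError("gains must be >= 0")


@dataclass
class CohortSpec:
    """A simulated cohort: groups plus the shared noise/saccade process."""

    groups: dict[str, GroupSpec]
    saccade_rate_per_s: float = 1.0
    saccade_amp_range: tuple[float, float] = (100.0, 300.0)
    saccade_dur_range: tuple[float, float] = (0.020, 0.080)
    noise_sd_degps: float = 2.0
    drift_rate_degps: float = 0.0
    position_noise_sd_deg: float = 0.01
    #: SD of the per-animal multiplicative log-normal gain jitter
    jitter_sd: float = 0.05
    rate: float = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise InvalidArgumentError("cohort has no groups")


@dataclass
class CohortDataset:
    """Simulated cohort: one EyeTrace per test plus a tidy metadata table
    (columns: trace, animal, group, protocol, time_min, block_index,
    test_index, frequency_hz, peak_velocity_degps, true_gain)."""

    traces: list[EyeTrace]
    table: pd.DataFrame
    design: ExperimentDesign
    cohort: CohortSpec


def cohort_from_config(section: dict) -> CohortSpec:
    """Build a cohort spec from the ``cohort:`` config section."""
    section = dict(section or {})
    groups = {
        name: GroupSpec(int(g["n_animals"]), [float(x) for x in g["gain_trajectory"]])
        for name, g in dict(section.pop("groups", {})).items()
    }
    for key in ("saccade_amp_range", "saccade_dur_range"):
        if key in section:
            section[key] = tuple(section[key])
    return CohortSpec(groups=groups, **section)


def simulate_cohort(design: ExperimentDesign, cohort: CohortSpec) -> CohortDataset:
    """Simulate every test of every animal in the cohort.

    Each animal draws a single multiplicative log-normal jitter factor
    applied to its group's whole gain trajectory (so programmed percent
    changes are preserved per animal), then one trace per test per
    measurement point with independent saccade trains and noise.  Fully
    deterministic under ``cohort.seed``: per-animal generators are spawned
    from a single seed sequence.
    """
    n_points = design.n_time_points
    for name, g in cohort.groups.items():
        if len(g.gain_trajectory) != n_points:
            raise InvalidArgumentError(
                f"group {name!r} trajectory has {len(g.gain_trajectory)} gains "
                f"but the design has {n_points} measurement points"
            )
    total_animals = sum(g.n_animals for g in cohort.groups.values())
    children = np.random.SeedSequence(cohort.seed).spawn(total_animals)
    traces: list[EyeTrace] = []
    rows: list[dict] = []
    animal_idx = 0
    for group_name, g in cohort.groups.items():
        for a in range(g.n_animals):
            rng = np.random.default_rng(children[animal_idx])
            animal = f"{group_name}-{a + 1:02d}"
            jitter = float(np.exp(rng.normal(0.0, cohort.jitter_sd)))
            for b_idx, block in enumerate(design.measured_blocks):
                true_gain = g.gain_trajectory[b_idx] * jitter
                for t_idx in range(block.n_tests):
                    saccades = sample_saccade_train(
                        block.test_duration_s,
                        cohort.saccade_rate_per_s,
                        cohort.saccade_amp_range,
                        cohort.saccade_dur_range,
                        seed=rng,
                    )
                    state = TrueState(
                        gain=true_gain,
                        phase=0.0,
                        noise_sd=cohort.noise_sd_degps,
                        drift_rate=cohort.drift_rate_degps,
                    )
                    meta = {
                        "animal": animal,
                        "group": group_name,
                        "protocol": design.protocol,
                        "time_min": block.time_min,
                        "block_index": b_idx,
                        "test_index": t_idx,
                    }
                    trace = synthesize_eye_trace(
                        block.stimulus,
                        state,
                        saccades,
                        duration=block.test_duration_s,
                        rate=cohort.rate,
                        seed=rng,
                        position_noise_sd=cohort.position_noise_sd_deg,
                        metadata=meta,
                    )
                    traces.append(trace)
                    rows.append(
                        {
                            "trace": len(traces) - 1,
                            **meta,
                            "frequency_hz": block.stimulus.frequency,
                            "peak_velocity_degps": block.stimulus.peak_velocity,
                            "true_gain": true_gain,
                        }
                    )
            animal_idx += 1
    return CohortDataset(traces, pd.DataFrame(rows), design, cohort)
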
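"""Shared containers and error types for the eye-movement analysis pipeline.

An :class:`EyeTrace` holds one test's uniformly sampled horizontal eye
position (degrees); a :class:`VelocityTrace` holds the derived eye velocity
(deg/s).  Both carry the sampling rate, the start time and a free-form
metadata mapping (animal id, group, stimulus frequency, ...), so every
downstream stage can operate on a single self-describing object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidArgumentError",
    "FormatError",
    "DegenerateFitError",
    "MissingBaselineError",
    "EmptyResultsError",
    "EyeTrace",
    "VelocityTrace",
]


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """An input file does not match the expected on-disk format."""


class DegenerateFitError(RuntimeError):
    """The sinusoid regression basis is rank deficient (too few retained
    samples, or the retained span is shorter than one stimulus cycle)."""


class MissingBaselineError(RuntimeError):
    """No valid baseline measurement exists for a learning-curve request."""


class EmptyResultsError(RuntimeError):
    """The pipeline produced no valid test measurements."""


@dataclass
class EyeTrace:
    """Uniformly sampled eye position for one test segment.

    Parameters
    ----------
    position : ndarray
        Horizontal eye position in degrees, one value per sample.
    rate : float
        Sampling rate in samples/s.
    t0 : float
        Time of the first sample in seconds.
    metadata : dict
        Test identity and stimulus description (keys used by the pipeline:
        ``animal``, ``group``, ``protocol``, ``time_min``, ``test_index``,
        ``frequency_hz``, ``peak_velocity_degps``; synthetic traces also
        record ``true_gain`` and ``true_phase``).
    """

    position: np.ndarray
    rate: float
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 1:
            raise InvalidArgumentError("position must be one-dimensional")
        if not self.rate > 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.position.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class VelocityTrace:
    """Eye velocity derived from an :class:`EyeTrace`.

    ``provenance`` records the conditioning settings used so a measurement
    can be audited (filter cutoff/order, differentiator window/polyorder).
    """

    velocity: np.ndarray
    rate: float
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 1:
            raise InvalidArgumentError("velocity must be one-dimensional")
        if not self.rate > 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.velocity.size

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate
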
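"""Two-pass fixed-frequency sinusoid fitting with saccade/artifact exclusion.

The response amplitude of a VOR or OKR test is measured as follows:

1. Fit the eye-velocity record with a sinusoid at the stimulus frequency
   (ordinary least squares on the basis {sin 2πft, cos 2πft, 1}; the
   frequency itself is fixed, not fitted).
2. Samples whose absolute deviation from this fit exceeds 31 deg/s are
   flagged as saccades or movement artifacts, together with 50 ms of data
   on either side.  Surviving retained segments shorter than 10 ms are
   removed as well — too brief to constrain the fit.
3. If more than 45% of the test's samples were excluded the whole test is
   rejected (no amplitude).  Otherwise the retained samples are fit a
   second time; the amplitude of this second fit is the response
   amplitude, and gain is amplitude divided by the stimulus peak velocity.

All comparisons are strict: a residual of exactly 31 deg/s, or an excluded
fraction of exactly 45%, does not trigger exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisParams, FitParams
from .conditioning import condition
from .core import (
    DegenerateFitError,
    EyeTrace,
    InvalidArgumentError,
    VelocityTrace,
)

__all__ = [
    "SinusoidFit",
    "ExclusionMask",
    "TestMeasurement",
    "fit_sinusoid",
    "build_exclusion_mask",
    "measure_velocity",
    "measure_test",
]


@dataclass
class SinusoidFit:
    """Least-squares fit of v(t) = a·sin(2πft) + b·cos(2πft) + c."""

    frequency: float
    amp_sin: float
    amp_cos: float
    offset: float
    residual_rms: float
    n_used: int

    @property
    def amplitude(self) -> float:
        """Peak velocity of the fitted sinusoid, deg/s."""
        return float(np.hypot(self.amp_sin, self.amp_cos))

    @property
    def phase(self) -> float:
        """Phase in radians, in (-pi, pi]."""
        ph = float(np.arctan2(self.amp_cos, self.amp_sin))
        return np.pi if ph == -np.pi else ph

    def predict(self, t: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * self.frequency
        return self.amp_sin * np.sin(w * t) + self.amp_cos * np.cos(w * t) + self.offset


@dataclass
class ExclusionMask:
    """Per-sample retained/excluded flags for one test."""

    retained: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n(self) -> int:
        return self.retained.size

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def excluded_fraction(self) -> float:
        """Fraction of all samples excluded, for any reason."""
        return 1.0 - self.n_retained / self.n

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Retained runs as half-open ``(start, end)`` sample intervals."""
        return _runs(self.retained)


@dataclass
class TestMeasurement:
    """Amplitude, gain and validity verdict for one test."""

    __test__ = False  # not a pytest class, despite the domain name

    amplitude: float | None
    gain: float | None
    phase: float | None
    excluded_fraction: float
    valid: bool
    reason: str | None = None
    metadata: dict = field(default_factory=dict)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) intervals where ``flags`` is True."""
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _fit_from_basis(
    v: np.ndarray,
    t: np.ndarray,
    sin_t: np.ndarray,
    cos_t: np.ndarray,
    idx: np.ndarray,
    frequency: float,
) -> SinusoidFit:
    """OLS on the precomputed basis {sin, cos, 1}, via 3x3 normal equations."""
    if idx.size < 3:
        raise DegenerateFitError("fewer than 3 retained samples")
    span = t[idx[-1]] - t[idx[0]]
    if span < 1.0 / frequency:
        raise DegenerateFitError("retained samples span less than one stimulus cycle")
    s = sin_t[idx]
    c = cos_t[idx]
    y = v[idx]
    n = float(idx.size)
    ss, sc, cc = s @ s, s @ c, c @ c
    s1, c1 = s.sum(), c.sum()
    G = np.array([[ss, sc, s1], [sc, cc, c1], [s1, c1, n]])
    b = np.array([s @ y, c @ y, y.sum()])
    # rank check on the 3x3 Gram matrix (well scaled: entries are O(n))
    if np.linalg.cond(G) > 1e12:
        raise DegenerateFitError("rank-deficient regression basis")
    coef = np.linalg.solve(G, b)
    resid = y - (coef[0] * s + coef[1] * c + coef[2])
    return SinusoidFit(
        frequency=frequency,
        amp_sin=float(coef[0]),
        amp_cos=float(coef[1]),
        offset=float(coef[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_used=int(idx.size),
    )


def fit_sinusoid(
    velocity: VelocityTrace,
    mask: np.ndarray | None,
    frequency: float,
) -> SinusoidFit:
    """Ordinary least squares of a fixed-frequency sinusoid plus offset.

    Parameters
    ----------
    velocity : VelocityTrace
        Eye velocity, deg/s.
    mask : ndarray of bool or None
        Per-sample retained flags; ``None`` uses every sample.
    frequency : float
        Stimulus frequency in Hz (held fixed).

    Raises
    ------
    DegenerateFitError
        Fewer than 3 retained samples, or the retained samples span less
        than one stimulus cycle.
    """
    if frequency <= 0:
        raise InvalidArgumentError("frequency must be positive")
    v = velocity.velocity
    t = velocity.time
    if mask is None:
        idx = np.arange(v.size)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != v.size:
            raise InvalidArgumentError("mask length does not match trace length")
        idx = np.flatnonzero(mask)
    w = 2.0 * np.pi * frequency
    return _fit_from_basis(v, t, np.sin(w * t), np.cos(w * t), idx, frequency)


def build_exclusion_mask(
    velocity: VelocityTrace,
    fit: SinusoidFit,
    threshold_degps: float = 31.0,
    pad_s: float = 0.050,
    min_segment_s: float = 0.010,
    min_segment_applies: str = "retained",
) -> ExclusionMask:
    """Flag saccades/artifacts by residual thresholding.

    Steps: (1) mark samples with ``|v - fit(t)| > threshold`` (strict);
    (2) dilate each marked sample by ``pad_s`` on both sides, clipping at
    the trace ends; (3) remove retained runs whose duration is strictly
    shorter than ``min_segment_s``.  With
    ``min_segment_applies='excluded'`` step 3 instead restores, before
    padding, threshold-crossing runs shorter than ``min_segment_s``
    (treating them as spurious crossings rather than saccades).
    """
    resid = velocity.velocity - fit.predict(velocity.time)
    return _mask_from_residuals(
        resid, velocity.rate, threshold_degps, pad_s, min_segment_s, min_segment_applies
    )


def _mask_from_residuals(
    resid: np.ndarray,
    rate: float,
    threshold_degps: float,
    pad_s: float,
    min_segment_s: float,
    min_segment_applies: str,
) -> ExclusionMask:
    if threshold_degps < 0 or pad_s < 0 or min_segment_s < 0:
        raise InvalidArgumentError("threshold, pad and min segment must be >= 0")
    if min_segment_applies not in ("retained", "excluded"):
        raise InvalidArgumentError("min_segment_applies must be 'retained' or 'excluded'")
    bad = np.abs(resid) > threshold_degps
    # duration of an n-sample run is n/rate; the rule is a strict inequality
    min_run = min_segment_s * rate - 1e-9
    if min_segment_applies == "excluded":
        for s, e in _runs(bad):
            if (e - s) < min_run:
                bad[s:e] = False
    pad_n = int(round(pad_s * rate))
    if pad_n > 0 and bad.any():
        # dilate by pad_n samples on each side via interval arithmetic
        grown = np.zeros(bad.size, dtype=bool)
        for s, e in _runs(bad):
            grown[max(0, s - pad_n) : min(bad.size, e + pad_n)] = True
        bad = grown
    retained = ~bad
    if min_segment_applies == "retained":
        for s, e in _runs(retained):
            if (e - s) < min_run:
                retained[s:e] = False
    return ExclusionMask(retained, rate)


def measure_velocity(
    velocity: VelocityTrace,
    frequency: float,
    stimulus_peak: float | None = None,
    fit_params: FitParams | None = None,
) -> TestMeasurement:
    """Two-pass measurement on an already-conditioned velocity trace.

    Pass 1 fits every sample; the residuals define the exclusion mask; if
    the excluded fraction exceeds ``max_excluded_fraction`` the test is
    invalid with no amplitude, otherwise pass 2 on the retained samples
    yields the response amplitude.  Exactly two passes are performed.
    """
    p = fit_params or FitParams()
    meta = dict(velocity.metadata)
    if stimulus_peak is None:
        stimulus_peak = meta.get("peak_velocity_degps")
    if frequency <= 0:
        raise InvalidArgumentError("frequency must be positive")
    v = velocity.velocity
    t = velocity.time
    w = 2.0 * np.pi * frequency
    sin_t, cos_t = np.sin(w * t), np.cos(w * t)  # shared by both passes
    try:
        fit1 = _fit_from_basis(v, t, sin_t, cos_t, np.arange(v.size), frequency)
    except DegenerateFitError:
        return TestMeasurement(None, None, None, 0.0, False, "degenerate_fit", meta)
    resid = v - (fit1.amp_sin * sin_t + fit1.amp_cos * cos_t + fit1.offset)
    mask = _mask_from_residuals(
        resid,
        velocity.rate,
        threshold_degps=p.threshold_degps,
        pad_s=p.pad_ms / 1e3,
        min_segment_s=p.min_segment_ms / 1e3,
        min_segment_applies=p.min_segment_applies,
    )
    if p.excluded_fraction_counts == "all":
        frac = mask.excluded_fraction
    elif p.excluded_fraction_counts == "threshold_only":
        frac = float(np.mean(np.abs(resid) > p.threshold_degps))
    else:
        raise InvalidArgumentError(
            "excluded_fraction_counts must be 'all' or 'threshold_only'"
        )
    if frac > p.max_excluded_fraction:
        return TestMeasurement(None, None, None, frac, False, "excluded_fraction", meta)
    try:
        fit2 = _fit_from_basis(
            v, t, sin_t, cos_t, np.flatnonzero(mask.retained), frequency
        )
    except DegenerateFitError:
        return TestMeasurement(None, None, None, frac, False, "degenerate_fit", meta)
    amplitude = fit2.amplitude
    gain = amplitude / stimulus_peak if stimulus_peak else None
    return TestMeasurement(amplitude, gain, fit2.phase, frac, True, None, meta)


def measure_test(
    trace: EyeTrace,
    frequency: float | None = None,
    stimulus_peak: float | None = None,
    params: AnalysisParams | None = None,
) -> TestMeasurement:
    """Measure one test from raw eye position.

    Conditions the trace (low-pass + Savitzky-Golay differentiation) and
    applies the two-pass fit.  ``frequency`` and ``stimulus_peak`` default
    to the trace metadata (``frequency_hz``, ``peak_velocity_degps``).
    """
    params = params or AnalysisParams()
    if frequency is None:
        frequency = params.fit.frequency_hz or trace.metadata.get("frequency_hz")
    if frequency is None:
        raise InvalidArgumentError(
            "stimulus frequency not given and absent from trace metadata"
        )
    velocity = condition(trace, params)
    return measure_velocity(velocity, float(frequency), stimulus_peak, params.fit)
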
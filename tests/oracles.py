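"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive (pure-Python index arithmetic, direct
quadrature) and share no code with the package.
"""

from __future__ import annotations

import numpy as np


def bruteforce_mask(
    resid,
    rate: float,
    threshold: float = 31.0,
    pad_s: float = 0.050,
    min_segment_s: float = 0.010,
    min_segment_applies: str = "retained",
) -> np.ndarray:
    """Reference desaccading mask: per-sample loops and index arithmetic.

    Returns the retained flags.  Duration comparisons are strict, matching
    the rule that a segment of exactly 10 ms is kept.
    """
    resid = list(resid)
    n = len(resid)
    min_run = min_segment_s * rate - 1e-9
    bad = [abs(r) > threshold for r in resid]

    def _flip_short_runs(flags, value, min_len):
        i = 0
        while i < n:
            if flags[i] == value:
                j = i
                while j < n and flags[j] == value:
                    j += 1
                if (j - i) < min_len:
                    for k in range(i, j):
                        flags[k] = not value
                i = j
            else:
                i += 1

    if min_segment_applies == "excluded":
        _flip_short_runs(bad, True, min_run)
    pad_n = int(round(pad_s * rate))
    grown = list(bad)
    if pad_n > 0:
        for i in range(n):
            if bad[i]:
                for j in range(max(0, i - pad_n), min(n, i + pad_n + 1)):
                    grown[j] = True
    retained = [not b for b in grown]
    if min_segment_applies == "retained":
        _flip_short_runs(retained, True, min_run)
    return np.array(retained, dtype=bool)


def quadrature_amplitude(x: np.ndarray, rate: float, frequency: float) -> float:
    """Amplitude of the ``frequency`` component by direct projection over
    whole cycles (independent of any least-squares machinery)."""
    samples_per_cycle = rate / frequency
    n = int(np.floor(x.size / samples_per_cycle) * samples_per_cycle)
    t = np.arange(n) / rate
    w = 2 * np.pi * frequency
    x = x[:n] - np.mean(x[:n])
    a = 2.0 * np.mean(x * np.sin(w * t))
    b = 2.0 * np.mean(x * np.cos(w * t))
    return float(np.hypot(a, b))
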
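"""Fitness measures for the two-stage evolutionary search.

Stage 1 rewards rhythmic B-class output at the worm's bending frequency:

    F1 = prod_{j in {DB, VB}} min(1, TV_j / (4 A f_a T)) * max(0, 1 - |f_j - f_a| / f_a)

with TV_j the total variation of S_j over the window, amplitude
threshold A = 0.5 and target frequency f_a = 0.44 Hz. The normalizer
4*A*f_a*T makes a sinusoid of amplitude A at f_a score exactly 1, which
is where the amplitude term is capped. Stage 2 additionally rewards
matching the worm's mean crawling speed:

    F2 = max(0, 1 - |Vbar - V_a| / V_a),     V_a = 0.22 mm/s,

with Vbar the magnitude of the net center-of-mass displacement divided
by the window duration (pure spinning scores ~0).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import periodogram


@dataclasses.dataclass(frozen=True)
class FitnessConstants:
    amplitude_threshold: float = 0.5   # A
    target_frequency: float = 0.44     # f_a, Hz
    target_velocity: float = 0.22e-3   # V_a, m/s

    def __post_init__(self):
        if min(self.amplitude_threshold, self.target_frequency, self.target_velocity) <= 0:
            raise ValueError("fitness constants must be positive")


def estimate_frequency(signal: np.ndarray, dt: float, spectral_check: bool = False):
    """Dominant frequency from mean intervals between rising mean-crossings.

    Returns ``(frequency_hz, oscillatory)``; a signal with fewer than two
    rising crossings of its mean is flagged non-oscillatory and scored
    0 Hz. With ``spectral_check`` the periodogram peak is also computed
    and returned as a third element.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or len(s) < 4:
        raise ValueError("signal must be a 1-D trace with at least 4 samples")
    centered = s - s.mean()
    # ignore numerically flat traces
    if np.ptp(s) < 1e-12:
        crossings = np.array([])
    else:
        sign = centered > 0
        rising = np.flatnonzero(~sign[:-1] & sign[1:])
        crossings = rising
    if len(crossings) < 2:
        out = (0.0, False)
        return out + (0.0,) if spectral_check else out
    # sub-sample interpolation of crossing times
    idx = crossings
    frac = -centered[idx] / (centered[idx + 1] - centered[idx])
    t_cross = (idx + frac) * dt
    freq = 1.0 / np.mean(np.diff(t_cross))
    if spectral_check:
        f, p = periodogram(centered, fs=1.0 / dt)
        f_spec = float(f[np.argmax(p[1:]) + 1]) if len(f) > 1 else 0.0
        return float(freq), True, f_spec
    return float(freq), True


def total_variation(signal: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(np.asarray(signal, dtype=float)))))


def fitness_f1(
    traces: dict[str, np.ndarray] | np.ndarray,
    dt: float,
    constants: FitnessConstants | None = None,
) -> float:
    """Rhythmic-pattern fitness over the B-class outputs.

    ``traces`` maps the class label ('DB', 'VB') to its output trace, or
    is an (n, 2) array with DB and VB columns. Non-finite traces score 0.
    """
    k = constants or FitnessConstants()
    if isinstance(traces, dict):
        series = [traces["DB"], traces["VB"]]
    else:
        arr = np.asarray(traces, dtype=float)
        series = [arr[:, 0], arr[:, 1]]
    score = 1.0
    for s in series:
        s = np.asarray(s, dtype=float)
        if not np.all(np.isfinite(s)):
            return 0.0
        T = (len(s) - 1) * dt
        if T <= 0:
            return 0.0
        amp = total_variation(s) / (4.0 * k.amplitude_threshold * k.target_frequency * T)
        amp = min(amp, 1.0)
        freq, oscillatory = estimate_frequency(s, dt)
        if not oscillatory:
            return 0.0
        freq_term = max(0.0, 1.0 - abs(freq - k.target_frequency) / k.target_frequency)
        score *= amp * freq_term
    return float(score)


def mean_velocity(com: np.ndarray, dt: float) -> float:
    """Net center-of-mass displacement magnitude over elapsed time (m/s).

    Using the net displacement projects out wiggling and makes pure
    spinning score approximately zero forward velocity.
    """
    com = np.asarray(com, dtype=float)
    if com.ndim != 2 or len(com) < 2:
        raise ValueError("need an (n, 2) trajectory with at least 2 samples")
    T = (len(com) - 1) * dt
    return float(np.linalg.norm(com[-1] - com[0]) / T)


def fitness_f2(
    com: np.ndarray | float,
    dt: float | None = None,
    constants: FitnessConstants | None = None,
) -> float:
    """Velocity-matching fitness 1 - |Vbar - V_a| / V_a, floored at 0.

    Accepts either a mean velocity (m/s) directly or an (n, 2) COM
    trajectory plus its sampling interval.
    """
    k = constants or FitnessConstants()
    if np.ndim(com) == 0:
        vbar = float(com)
    else:
        if dt is None:
            raise ValueError("dt required when passing a trajectory")
        vbar = mean_velocity(np.asarray(com), dt)
    return float(max(0.0, 1.0 - abs(vbar - k.target_velocity) / k.target_velocity))
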
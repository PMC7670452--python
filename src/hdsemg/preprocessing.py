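"""Filtering, epoching, RMS estimation and torque handling.

Signals are band-pass filtered 12-350 Hz with a 4th-order Butterworth applied
forward and backward (zero phase); maps use non-overlapping 500 ms epochs and
classification features use 150 ms epochs. The analysed 3 s interval of each
10 s contraction is the window of greatest torque stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, iirnotch, filtfilt

__all__ = ["EpochSpec", "bandpass_zero_phase", "notch_line", "epoch_signal",
           "rms", "select_stability_window", "net_torque", "effort_fraction"]


@dataclass(frozen=True)
class EpochSpec:
    """Epoch length/overlap at a sampling rate; 0.5 s for maps, 0.15 s for features."""
    length_s: float
    fs: float
    overlap: float = 0.0

    def __post_init__(self):
        if round(self.length_s * self.fs) < 1:
            raise ValueError("epoch shorter than one sample")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def length(self) -> int:
        # floor convention: 150 ms at 2048 Hz -> 307 samples
        return int(self.length_s * self.fs)

    @property
    def hop(self) -> int:
        return max(1, int(round(self.length * (1.0 - self.overlap))))


def bandpass_zero_phase(signals: np.ndarray, fs: float, low_hz: float = 12.0,
                        high_hz: float = 350.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The effective magnitude response is the squared single-pass response and
    the group delay is zero at every frequency. Edge transients are
    suppressed by odd reflective padding over one settling length
    (scipy's default for ``sosfiltfilt``).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high cut-off {high_hz} Hz >= Nyquist {fs / 2} Hz")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, signals, axis=-1)


def notch_line(signals: np.ndarray, fs: float, f0: float = 50.0,
               q: float = 30.0) -> np.ndarray:
    """Optional zero-phase notch for residual line interference (off by default
    in every pipeline stage)."""
    b, a = iirnotch(f0, q, fs=fs)
    return filtfilt(b, a, np.atleast_2d(np.asarray(signals, float)), axis=-1)


def epoch_signal(signals: np.ndarray, spec: EpochSpec) -> np.ndarray:
    """Split channels x samples into epochs (floor division; the trailing
    partial epoch is discarded). Returns (n_epochs, channels, epoch_length)."""
    signals = np.atleast_2d(np.asarray(signals))
    n = signals.shape[-1]
    L, hop = spec.length, spec.hop
    if n < L:
        raise ValueError(f"signal of {n} samples shorter than one epoch ({L})")
    n_epochs = 1 + (n - L) // hop
    idx = np.arange(L)[None, :] + hop * np.arange(n_epochs)[:, None]
    return signals[..., idx].transpose(1, 0, 2)


def rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Root mean square along ``axis``; non-negative, zero iff all-zero."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty array is undefined")
    return np.sqrt(np.mean(x**2, axis=axis))


def select_stability_window(torque: np.ndarray, fs: float, window_s: float = 3.0,
                            cost: str = "std", step_s: float = 0.5
                            ) -> tuple[int, int]:
    """Start/end sample of the most stable contiguous torque window.

    The stability cost (standard deviation by default, ``"range"`` for
    max-min) is evaluated on the mean of the per-channel absolute torque so
    the same code serves the equal-sign (flexion/extension) and opposite-sign
    (pronation/supination) conventions. Candidate windows start every
    ``step_s`` seconds; ties go to the earliest window.
    """
    torque = np.atleast_2d(np.asarray(torque, dtype=float))
    net = np.mean(np.abs(torque), axis=0)
    L = int(round(window_s * fs))
    if L > net.size:
        raise ValueError(f"window of {L} samples longer than trace ({net.size})")
    if cost not in ("std", "range"):
        raise ValueError(f"unknown stability cost {cost!r}")
    step = max(1, int(round(step_s * fs)))
    starts = np.arange(0, net.size - L + 1, step)
    costs = np.empty(starts.size)
    for i, s in enumerate(starts):
        w = net[s:s + L]
        costs[i] = np.std(w) if cost == "std" else np.ptp(w)
    best = int(starts[int(np.argmin(costs))])
    return best, best + L


def net_torque(torque: np.ndarray, task: str) -> np.ndarray:
    """Combine the two torque channels into a net trace.

    Flexion/extension: the meters agree in sign, net = mean of the channels.
    Pronation/supination: they oppose, net = half the channel difference.
    """
    torque = np.atleast_2d(np.asarray(torque, dtype=float))
    if torque.shape[0] != 2:
        raise ValueError("expected a two-channel torque trace")
    if task in ("flexion", "extension"):
        return 0.5 * (torque[0] + torque[1])
    if task in ("supination", "pronation"):
        return 0.5 * (torque[0] - torque[1])
    raise ValueError(f"unknown task {task!r}")


def effort_fraction(torque: np.ndarray, task: str, mvc_value: float,
                    window: tuple[int, int] | None = None) -> float:
    """|mean net torque| over ``window`` (default: whole trace) as a fraction
    of the maximal voluntary contraction reference."""
    if mvc_value <= 0:
        raise ValueError("MVC reference must be positive")
    net = net_torque(torque, task)
    if window is not None:
        net = net[window[0]:window[1]]
    return float(abs(np.mean(net)) / mvc_value)
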
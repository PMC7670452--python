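"""In-memory container for a multi-channel monopolar grid recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ElectrodeGrid, channels_to_grid

__all__ = ["MultiChannelRecording"]


@dataclass
class MultiChannelRecording:
    """Time-aligned monopolar signals from one electrode array.

    ``signals`` is channels x samples, in arbitrary units unless ``gain`` is
    set (then raw / gain gives mV). Channel order follows ``grid.order``.
    """

    signals: np.ndarray
    fs: float
    grid: ElectrodeGrid
    subject: str | None = None
    task: str | None = None
    effort: float | None = None
    montage: str = "monopolar"
    gain: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.signals.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"{self.signals.shape[0]} channels but grid declares "
                f"{self.grid.n_channels}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def as_grid(self) -> np.ndarray:
        """Signals laid out as (rows, cols, samples)."""
        return channels_to_grid(self.signals, self.grid)

    def validate_finite(self) -> None:
        if not np.isfinite(self.signals).all():
            raise ValueError("recording contains non-finite samples")
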
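"""Stimulus-locked multichannel EEG epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from painrct.errors import InvalidArgumentError

__all__ = ["CHANNELS", "EEGEpoch"]

#: Recording montage (modified 10–20 positions used for neonatal recordings).
CHANNELS = ("Cz", "CPz", "C3", "C4", "FCz", "T3", "T4", "Oz")


@dataclass
class EEGEpoch:
    """One stimulus-locked epoch: ``data`` is channels x samples in microvolts.

    ``stimulus_index`` is the sample index of time 0 (the stimulus);
    ``epoch_window`` gives the covered interval in seconds relative to it.
    """

    sampling_rate: float
    channels: tuple[str, ...]
    data: np.ndarray
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    stimulus_index: int | None = None
    event_kind: str = "lance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InvalidArgumentError(
                f"data must be (n_channels={len(self.channels)}, n_samples), "
                f"got shape {self.data.shape}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise InvalidArgumentError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.stimulus_index is None:
            self.stimulus_index = int(round(-self.epoch_window[0] * self.sampling_rate))
        n = self.data.shape[1]
        if not 0 <= self.stimulus_index < n:
            raise InvalidArgumentError(
                f"stimulus_index {self.stimulus_index} outside epoch of {n} samples"
            )
        if self.event_kind not in ("sham", "lance"):
            raise InvalidArgumentError(f"event_kind must be sham or lance, got {self.event_kind}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the stimulus."""
        return (np.arange(self.n_samples) - self.stimulus_index) / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"channel {label!r} not in epoch") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice covering ``window`` seconds relative to the stimulus."""
        lo, hi = window
        if lo < self.times[0] - 0.5 / self.sampling_rate or hi > self.times[-1] + 0.5 / self.sampling_rate:
            raise InvalidArgumentError(
                f"window {window} outside epoch coverage "
                f"[{self.times[0]:.3f}, {self.times[-1]:.3f}] s"
            )
        start = int(np.ceil(lo * self.sampling_rate - 1e-9)) + self.stimulus_index
        stop = int(np.floor(hi * self.sampling_rate + 1e-9)) + self.stimulus_index + 1
        return slice(max(start, 0), min(stop, self.n_samples))

    def copy(self) -> "EEGEpoch":
        return replace(self, data=self.data.copy())
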
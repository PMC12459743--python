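"""Shared in-memory containers for continuous and epoched multichannel signals.

Sensor-space amplitudes are in microvolts; source/node time courses are in
arbitrary units.  Epochs are stored as a dense ``trials x channels x samples``
array with an explicit sampling rate and the time of the first sample relative
to stimulus onset, which is all the downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContinuousSignal:
    """A continuous multichannel recording (channels x samples)."""

    data: np.ndarray
    fs_hz: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be channels x samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class EpochedSignal:
    """Stimulus-locked epochs: ``data`` is trials x channels x samples.

    ``t0_ms`` is the time of the first sample relative to stimulus onset
    (negative for pre-stimulus baseline).  ``trial_indices`` are the 1-based
    indices into the task design the epochs were cut from, so behavioral and
    neurophysiological records stay aligned after rejection.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    channel_names: list[str] = field(default_factory=list)
    trial_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be trials x channels x samples")
        if np.isnan(self.data).any():
            raise ValueError("epoched data contains NaN")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match data")
        if self.trial_indices is None:
            self.trial_indices = np.arange(1, self.data.shape[0] + 1)
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        if self.trial_indices.shape[0] != self.data.shape[0]:
            raise ValueError("trial_indices length does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def copy(self) -> "EpochedSignal":
        return EpochedSignal(
            data=self.data.copy(),
            fs_hz=self.fs_hz,
            t0_ms=self.t0_ms,
            channel_names=list(self.channel_names),
            trial_indices=self.trial_indices.copy(),
        )

    def window(self, start_ms: float, end_ms: float) -> "EpochedSignal":
        """Return the half-open [start_ms, end_ms) sub-window of every epoch."""
        i0 = int(round((start_ms - self.t0_ms) * self.fs_hz / 1000.0))
        i1 = int(round((end_ms - self.t0_ms) * self.fs_hz / 1000.0))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"window [{start_ms}, {end_ms}) ms outside epoch support "
                f"[{self.t0_ms}, {self.times_ms[-1]}] ms"
            )
        return EpochedSignal(
            data=self.data[:, :, i0:i1].copy(),
            fs_hz=self.fs_hz,
            t0_ms=start_ms,
            channel_names=list(self.channel_names),
            trial_indices=self.trial_indices.copy(),
        )
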
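"""Uniformly sampled multichannel signal container.

All pipeline stages exchange :class:`SignalStream` objects: a channels-by-time
sample matrix plus sampling rate, start time, modality tag and channel names.
Units are fixed per modality: gyroscope channels in deg/s, accelerometer in
m/s^2, joint angles in degrees, sEMG in arbitrary volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("emg", "imu_gyro", "imu_accel", "envelope", "angle")


@dataclass
class SignalStream:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        Sample matrix. A 1-D array is promoted to a single channel.
    fs : float
        Sampling rate in Hz, strictly positive.
    modality : str
        One of ``emg, imu_gyro, imu_accel, envelope, angle``.
    t0 : float, default 0.0
        Time of the first sample in seconds.
    channel_names : list of str, optional
        Defaults to ``ch_00, ch_01, ...``.
    """

    data: np.ndarray
    fs: float
    modality: str
    t0: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch_{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Signal duration in seconds (sample count over rate)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self, data: np.ndarray | None = None, **overrides) -> "SignalStream":
        """Shallow-config copy, optionally replacing the sample matrix."""
        kwargs = dict(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            modality=self.modality,
            t0=self.t0,
            channel_names=list(self.channel_names),
        )
        kwargs.update(overrides)
        return SignalStream(**kwargs)

    def channel(self, name: str) -> np.ndarray:
        """Return the samples of one channel by name."""
        return self.data[self.channel_names.index(name)]

    def slice_time(self, start: float, end: float) -> "SignalStream":
        """Half-open time slice [start, end) in seconds."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        return self.copy(data=self.data[:, i0:i1], t0=self.t0 + i0 / self.fs)

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with a ``time_s`` column followed by one column per channel."""
        frame = pd.DataFrame(self.data.T, columns=self.channel_names)
        frame.insert(0, "time_s", self.times)
        return frame

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, fs: float, modality: str
    ) -> "SignalStream":
        """Rebuild a stream from :meth:`to_frame` output (or a matching CSV)."""
        cols = [c for c in frame.columns if c != "time_s"]
        t0 = float(frame["time_s"].iloc[0]) if "time_s" in frame else 0.0
        return cls(
            data=frame[cols].to_numpy().T,
            fs=fs,
            modality=modality,
            t0=t0,
            channel_names=cols,
        )
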
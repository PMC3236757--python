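"""Core containers for multichannel EEG-like signals and frequency bands.

These are deliberately thin wrappers around numpy arrays: the payload of a
scalp recording is a channels x samples matrix plus a sampling rate and
channel labels, and everything downstream (epoching, wavelet decomposition,
mutual-information connectivity) operates on that triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "MultichannelRecording",
    "EpochSet",
    "BandSeries",
    "DEFAULT_BANDS",
]


@dataclass(frozen=True)
class Band:
    """A frequency band [low, high) in Hz.

    The default alpha/beta/gamma edges partition 7.97-50.78 Hz exactly:
    alpha.high == beta.low and beta.high == gamma.low.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: low={self.low}, high={self.high}")

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} [{self.low}, {self.high}] Hz exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Printed band edges, stored as exact constants (they are not re-derived
#: from a wavelet scale formula).
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("alpha", 7.97, 15.05),
    Band("beta", 15.05, 31.25),
    Band("gamma", 31.25, 50.78),
)


def _check_matrix(data: np.ndarray, n_labels: int) -> None:
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D channels x samples matrix, got shape {data.shape}")
    if data.shape[0] != n_labels:
        raise ValueError(f"{data.shape[0]} channel rows but {n_labels} labels")
    if data.shape[1] < 1:
        raise ValueError("recording must contain at least one sample")
    if not np.isfinite(data).all():
        raise ValueError("recording contains NaN or Inf samples")


@dataclass
class MultichannelRecording:
    """A channels x samples recording with sampling rate and channel labels."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        _check_matrix(self.data, len(self.labels))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "MultichannelRecording":
        return replace(self, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        """Write as a delimited matrix: rows = samples, columns = channels."""
        df = pd.DataFrame(self.data.T, columns=list(self.labels))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float, reference: str = "unknown") -> "MultichannelRecording":
        df = pd.read_csv(path)
        return cls(data=df.to_numpy().T, fs=fs, labels=tuple(df.columns), reference=reference)

    @classmethod
    def from_edf(cls, path: str | Path, reference: str = "unknown") -> "MultichannelRecording":
        """Read a recording from EDF (sampling rate taken from the header)."""
        from mne.io import read_raw_edf

        raw = read_raw_edf(str(path), preload=True, verbose="error")
        return cls(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            labels=tuple(raw.ch_names),
            reference=reference,
        )


@dataclass
class EpochSet:
    """Non-overlapping equal-length epochs: epochs x channels x samples."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected epochs x channels x samples, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("epochs contain NaN or Inf samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_len(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BandSeries:
    """Band-limited signal per epoch and channel (real-valued by default).

    Produced by summing Morlet wavelet coefficients over the in-band scales;
    shares the epoch/channel/sample layout of its source :class:`EpochSet`.
    """

    data: np.ndarray
    band: Band
    fs: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected epochs x channels x samples, got shape {self.data.shape}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def bands_from_mapping(mapping: dict[str, Sequence[float]]) -> tuple[Band, ...]:
    """Build Band objects from e.g. {"alpha": [7.97, 15.05], ...}."""
    return tuple(Band(name, float(lo), float(hi)) for name, (lo, hi) in mapping.items())
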
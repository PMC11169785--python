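"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three representations:

``RawRecording``
    A channels x samples voltage matrix (microvolts) with its sampling
    rate, 3-D electrode positions and a per-channel quality mask.
``FeatureTable``
    Binned band-envelope features: a bins x channels x bands array of
    envelope means, each bin carrying a behavioral label and a boolean
    keep flag (false for artifact-contaminated or unlabeled bins).
``BandTable``
    The ordered list of frequency bands whose Hilbert envelopes are
    extracted.  Defaults are the five canonical ECoG bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Band",
    "BandTable",
    "DEFAULT_BANDS",
    "RawRecording",
    "FeatureTable",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got "
                             f"({self.low}, {self.high})")

    @property
    def center(self) -> float:
        """Geometric mean of the band edges (Hz).

        Used as the carrier frequency for synthetic oscillations; the
        geometric mean sits well inside the passband of the analysis
        filter on a log-frequency axis.
        """
        return float(np.sqrt(self.low * self.high))


@dataclass(frozen=True)
class BandTable:
    """Ordered collection of analysis bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def __getitem__(self, key: str | int) -> Band:
        if isinstance(key, int):
            return self.bands[key]
        for b in self.bands:
            if b.name == key:
                return b
        raise KeyError(f"no band named {key!r}")

    def index(self, name: str) -> int:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise KeyError(f"no band named {name!r}")

    def validate_against_fs(self, fs: float) -> None:
        for b in self.bands:
            if b.high >= fs / 2:
                raise ValueError(
                    f"band {b.name!r} upper edge {b.high} Hz >= Nyquist "
                    f"({fs / 2} Hz)")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, float, float]]) -> "BandTable":
        return cls(tuple(Band(n, lo, hi) for n, lo, hi in pairs))


#: The five canonical analysis bands.  Note that beta (8-32 Hz) overlaps
#: alpha (8-12 Hz); the overlap is intentional and configurable.
DEFAULT_BANDS = BandTable.from_pairs([
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 8.0, 32.0),
    ("low_gamma", 32.0, 55.0),
    ("high_gamma", 70.0, 110.0),
])


@dataclass
class RawRecording:
    """Multichannel voltage recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    positions : ndarray, shape (n_channels, 3)
        Electrode coordinates in millimetres.
    good_mask : ndarray of bool, shape (n_channels,)
        True for channels usable in analysis.
    block_duration_s : float
        Duration of one behavioral annotation block (seconds).
    labels : list of str or None
        Optional per-block behavioral labels riding along with the
        recording (one label per ``block_duration_s`` of signal).
    seed : int or None
        Seed used to generate the recording, if synthetic.
    """

    data: np.ndarray
    fs: float
    positions: np.ndarray
    good_mask: np.ndarray = None  # type: ignore[assignment]
    block_duration_s: float = 120.0
    labels: list[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.n_channels, 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.good_mask is None:
            self.good_mask = np.ones(self.n_channels, dtype=bool)
        self.good_mask = np.asarray(self.good_mask, dtype=bool)
        if self.good_mask.shape != (self.n_channels,):
            raise ValueError("good_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "RawRecording":
        """Return a copy with some fields replaced (data is not copied
        unless a new array is passed)."""
        out = replace(self)
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out


@dataclass
class FeatureTable:
    """Binned band-envelope features.

    ``values[b, c, k]`` is the mean Hilbert envelope of channel ``c`` in
    band ``k`` over time bin ``b``.
    """

    values: np.ndarray
    bin_s: float
    band_table: BandTable
    positions: np.ndarray
    labels: np.ndarray | None = None
    keep_mask: np.ndarray = None  # type: ignore[assignment]
    block_duration_s: float = 120.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (bins x channels x bands)")
        if self.values.shape[2] != len(self.band_table):
            raise ValueError("third axis must match band table length")
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.n_bins, dtype=bool)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.n_bins,):
                raise ValueError("labels length must equal bin count")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def bins_per_block(self) -> int:
        ratio = self.block_duration_s / self.bin_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("block duration must be a multiple of bin_s")
        return int(round(ratio))

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep_mask)

    def copy_with(self, **kwargs) -> "FeatureTable":
        out = replace(self)
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out
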
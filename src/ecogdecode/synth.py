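"""Synthetic ECoG-like recordings with known spectro-spatial structure.

The generator produces labeled multichannel recordings in which the
mean Hilbert envelope of chosen (region, band) combinations shifts by a
known multiplicative factor between behavioral states.  Every channel
is a sum of

* one band-limited sinusoidal carrier per analysis band, at the
  geometric-mean frequency of the band, with a per-channel random phase
  and a block-wise amplitude ``base_amplitude * multiplier`` where the
  multiplier comes from the :class:`EffectMap` for the channel's region
  and the current block's state (1.0 when unmapped);
* broadband 1/f ("pink") background noise, generated by spectral
  shaping of white Gaussian noise;
* a slow sinusoidal drift term, to exercise the z-scoring and the
  temporal cross-validation buffer downstream.

Randomness is organized as one stream per recording, split into
per-channel substreams keyed by channel index, so adding channels never
reshuffles the noise of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BandTable, RawRecording

__all__ = [
    "ElectrodeLayout",
    "EffectMap",
    "BehaviorLabels",
    "NoiseSpec",
    "make_layout",
    "make_labels",
    "synthesize_recording",
    "inject_artifacts",
]

#: Approximate left-hemisphere centroids (mm) for the eight cortical
#: regions of interest used throughout; configurable everywhere.
DEFAULT_ROI_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "precentral": (-39.0, -6.0, 52.0),
    "postcentral": (-42.0, -23.0, 49.0),
    "inferior_parietal": (-43.0, -46.0, 47.0),
    "supramarginal": (-56.0, -34.0, 30.0),
    "superior_temporal": (-53.0, -21.0, 7.0),
    "middle_temporal": (-56.0, -34.0, -2.0),
    "inferior_temporal": (-50.0, -28.0, -23.0),
    "frontal_middle": (-33.0, 33.0, 35.0),
}


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode identifiers, 3-D positions, and ROI centroids (mm)."""

    electrode_ids: tuple[str, ...]
    positions: np.ndarray
    roi_centroids: dict[str, np.ndarray]
    #: ROI name each electrode was generated around (ground truth).
    true_roi: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("electrode_ids must be unique")
        if pos.shape != (len(self.electrode_ids), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(self.roi_centroids) < 1:
            raise ValueError("need at least one ROI centroid")
        cents = {k: np.asarray(v, dtype=float) for k, v in self.roi_centroids.items()}
        object.__setattr__(self, "roi_centroids", cents)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_centroids)


@dataclass(frozen=True)
class EffectMap:
    """Ground-truth envelope-mean multipliers.

    ``entries[(roi, band, state)] = m`` scales the carrier amplitude of
    ``band`` on all electrodes of ``roi`` during blocks labeled
    ``state``.  Unmapped combinations default to 1.0 (no effect).
    """

    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, m in self.entries.items():
            if m <= 0:
                raise ValueError(f"multiplier for {key} must be > 0")

    def multiplier(self, roi: str | None, band: str, state: str) -> float:
        if roi is None:
            return 1.0
        return self.entries.get((roi, band, state), 1.0)

    def validate(self, layout: ElectrodeLayout, bands: BandTable,
                 states: set[str] | None = None) -> None:
        rois = set(layout.roi_names)
        band_names = set(bands.names)
        for roi, band, state in self.entries:
            if roi not in rois:
                raise ValueError(f"effect references unknown ROI {roi!r}")
            if band not in band_names:
                raise ValueError(f"effect references unknown band {band!r}")
            if states is not None and state not in states:
                raise ValueError(f"effect references unknown state {state!r}")


@dataclass(frozen=True)
class BehaviorLabels:
    """One coarse behavioral label per fixed-duration block."""

    labels: tuple[str, ...]
    block_duration: float = 120.0

    def __post_init__(self) -> None:
        if self.block_duration <= 0:
            raise ValueError("block_duration must be positive")
        if len(self.labels) == 0:
            raise ValueError("need at least one block label")

    @property
    def n_blocks(self) -> int:
        return len(self.labels)

    @property
    def states(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.labels:
            seen.setdefault(s, None)
        return list(seen)


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise parameters for the generator.

    pink_exponent is the spectral slope beta of the 1/f^beta background,
    noise_sd its time-domain standard deviation in microvolts.  The
    drift term is ``drift_amplitude * sin(2 pi t / drift_period)`` with
    a per-channel random phase.

    am_cv adds slow multiplicative fluctuation to each carrier's
    amplitude (coefficient of variation, smoothed over am_timescale_s),
    emulating the large spontaneous bin-to-bin band-power variability
    of real cortical recordings; without it, band envelopes are nearly
    deterministic and any classifier saturates.  Set am_cv = 0 for
    exact-envelope checks.
    """

    pink_exponent: float = 1.0
    noise_sd: float = 5.0
    drift_amplitude: float = 10.0
    drift_period: float = 600.0
    am_cv: float = 0.25
    am_timescale_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")
        if self.am_cv < 0 or self.am_timescale_s <= 0:
            raise ValueError("am_cv must be >= 0 and am_timescale_s > 0")


def _channel_rngs(seed: int, n_channels: int) -> list[np.random.Generator]:
    """One independent substream per channel, keyed by channel index."""
    children = np.random.SeedSequence(seed).spawn(n_channels)
    return [np.random.Generator(np.random.SFC64(c)) for c in children]


def make_layout(n_per_roi: int, roi_centroids: dict[str, tuple[float, float, float]],
                jitter_sd: float, seed: int) -> ElectrodeLayout:
    """Place ``n_per_roi`` electrodes around each ROI centroid.

    Positions are centroid + isotropic Gaussian jitter of SD
    ``jitter_sd`` mm, deterministic in ``seed``.
    """
    if n_per_roi < 1:
        raise ValueError("n_per_roi must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if len(roi_centroids) == 0:
        raise ValueError("roi_centroids must not be empty")
    rng = np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))
    ids: list[str] = []
    pos: list[np.ndarray] = []
    true_roi: list[str] = []
    for roi, c in roi_centroids.items():
        c = np.asarray(c, dtype=float)
        jitter = rng.normal(0.0, jitter_sd, size=(n_per_roi, 3)) if jitter_sd > 0 \
            else np.zeros((n_per_roi, 3))
        for k in range(n_per_roi):
            ids.append(f"{roi}_{k}")
            pos.append(c + jitter[k])
            true_roi.append(roi)
    return ElectrodeLayout(tuple(ids), np.asarray(pos), dict(roi_centroids),
                           tuple(true_roi))


def make_labels(n_blocks: int, states, persistence: float, seed: int,
                block_duration: float = 120.0) -> BehaviorLabels:
    """Markov chain of block labels with self-transition ``persistence``.

    The remaining probability mass is split uniformly over the other
    states; the start state is uniform.
    """
    states = list(states)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not states:
        raise ValueError("state set must not be empty")
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must be in [0, 1]")
    rng = np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))
    if len(states) == 1:
        return BehaviorLabels(tuple(states * n_blocks), block_duration)
    labels = [states[rng.integers(len(states))]]
    p_other = (1.0 - persistence) / (len(states) - 1)
    for _ in range(n_blocks - 1):
        cur = labels[-1]
        probs = [persistence if s == cur else p_other for s in states]
        labels.append(states[rng.choice(len(states), p=probs)])
    return BehaviorLabels(tuple(labels), block_duration)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float,
                sd: float, fs: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, rescaled to SD ``sd``."""
    if sd == 0:
        return np.zeros(n, dtype=np.float32)
    n_freq = n // 2 + 1
    spec = (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones(n_freq)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC power
    x = np.fft.irfft(spec * shape, n=n)
    x *= sd / x.std()
    return x.astype(np.float32)


def _slow_am(rng: np.random.Generator, n: int, fs: float, cv: float,
             timescale_s: float) -> np.ndarray:
    """Slow positive amplitude-modulation track with unit mean and the
    requested coefficient of variation.

    A Gaussian process is drawn on a 1-s grid, smoothed to the given
    correlation timescale, rescaled to SD = cv, and held piecewise
    constant at 1-s resolution (10-s feature bins average it out).
    """
    from scipy.ndimage import gaussian_filter1d
    step = int(round(fs))  # 1-s resolution
    n_coarse = int(np.ceil(n / step))
    g = rng.standard_normal(n_coarse + 1)
    sigma = max(timescale_s, 1.0)
    g = gaussian_filter1d(g, sigma=sigma, mode="wrap")
    sd = g.std()
    if sd > 0:
        g = g / sd
    track = np.clip(1.0 + cv * g[:n_coarse], 0.05, None).astype(np.float32)
    return np.repeat(track, step)[:n]


def _block_amplitudes(layout: ElectrodeLayout, labels: BehaviorLabels,
                      bands: BandTable, effects: EffectMap,
                      base_amplitude: float) -> np.ndarray:
    """(n_channels, n_bands, n_blocks) carrier amplitudes."""
    n_ch = layout.n_electrodes
    amp = np.empty((n_ch, len(bands), labels.n_blocks), dtype=np.float32)
    rois = layout.true_roi if layout.true_roi else (None,) * n_ch
    for c in range(n_ch):
        for k, band in enumerate(bands):
            for b, state in enumerate(labels.labels):
                amp[c, k, b] = base_amplitude * effects.multiplier(
                    rois[c], band.name, state)
    return amp


def synthesize_recording(layout: ElectrodeLayout, labels: BehaviorLabels,
                         bands: BandTable, effects: EffectMap,
                         noise: NoiseSpec, fs: float = 500.0,
                         base_amplitude: float = 5.0) -> RawRecording:
    """Generate a labeled synthetic recording.

    Each channel is the sum of per-band sinusoidal carriers (amplitude
    modulated block-wise by the effect map), pink background noise, and
    slow drift.  Deterministic given ``noise.seed``.
    """
    if fs < 2 * max(b.high for b in bands):
        raise ValueError("fs must be at least twice the highest band edge")
    effects.validate(layout, bands)
    n_ch = layout.n_electrodes
    spb = int(round(labels.block_duration * fs))
    n = spb * labels.n_blocks
    t = np.arange(n, dtype=np.float64) / fs

    # carriers computed once per band; per-channel phase applied via the
    # angle-sum identity so no per-channel sin() evaluation is needed
    carriers = []
    for band in bands:
        w = 2.0 * np.pi * band.center
        carriers.append((np.sin(w * t).astype(np.float32),
                         np.cos(w * t).astype(np.float32)))

    amp = _block_amplitudes(layout, labels, bands, effects, base_amplitude)
    rngs = _channel_rngs(noise.seed, n_ch)
    data = np.zeros((n_ch, n), dtype=np.float32)
    for c in range(n_ch):
        rng = rngs[c]
        sig = np.zeros(n, dtype=np.float32)
        for k in range(len(bands)):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sin_t, cos_t = carriers[k]
            a = np.repeat(amp[c, k], spb)
            if noise.am_cv > 0:
                a = a * _slow_am(rng, n, fs, noise.am_cv, noise.am_timescale_s)
            sig += a * (np.float32(np.cos(phase)) * sin_t
                        + np.float32(np.sin(phase)) * cos_t)
        sig += _pink_noise(rng, n, noise.pink_exponent, noise.noise_sd, fs)
        if noise.drift_amplitude > 0:
            dphase = rng.uniform(0.0, 2.0 * np.pi)
            sig += (noise.drift_amplitude
                    * np.sin(2.0 * np.pi * t / noise.drift_period + dphase)
                    ).astype(np.float32)
        data[c] = sig
    return RawRecording(data=data, fs=fs, positions=layout.positions.copy(),
                        block_duration_s=labels.block_duration,
                        labels=list(labels.labels), seed=noise.seed)


def inject_artifacts(rec: RawRecording, segments, seed: int) -> RawRecording:
    """Add square high-amplitude bursts to a random channel subset.

    ``segments`` is a list of ``(start_s, duration_s, channel_fraction,
    amplitude_uv)`` tuples.  Each burst adds a constant offset of the
    given amplitude to ``ceil(channel_fraction * n_channels)`` randomly
    chosen channels over the window.  The input recording is not
    modified.
    """
    data = rec.data.copy()
    rng = np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))
    for start_s, dur_s, frac, amp in segments:
        if not 0 < frac <= 1:
            raise ValueError("channel fraction must be in (0, 1]")
        i0 = int(round(start_s * rec.fs))
        i1 = int(round((start_s + dur_s) * rec.fs))
        if start_s < 0 or i1 > rec.n_samples:
            raise ValueError(
                f"artifact segment ({start_s}s + {dur_s}s) outside recording "
                f"of {rec.duration_s:.1f}s")
        n_hit = int(np.ceil(frac * rec.n_channels))
        hit = rng.choice(rec.n_channels, size=n_hit, replace=False)
        data[hit, i0:i1] += np.asarray(amp, dtype=data.dtype)
    out = rec.copy_with()
    out.data = data
    return out
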
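"""Complex Morlet time-frequency power, band averaging, and segment means.

Each channel is convolved with unit-energy complex Morlet wavelets (Gaussian
windowed complex exponentials) at 1-Hz spaced center frequencies.  The kernel
at center frequency ``f_c`` with ``n`` cycles has temporal standard deviation
``sigma_t = n / (2 pi f_c)`` and is truncated at +-5 sigma_t.  Squared
magnitudes of the convolution give instantaneous spectral power; per-frequency
power is then averaged into the five classical EEG bands and into 10-ms
non-overlapping segments tiling the prestimulus window, producing the
``trial x electrode x band x segment`` feature reservoir.

Segment boundaries are laid out every ``seg_len`` ms from the window start and
converted to sample indices by rounding, so the sample axis is tiled exactly;
a 738-ms prestimulus window with 10-ms segments yields 73 full segments plus a
truncated 8-ms segment adjacent to stimulus onset (74 in total).  Band edges
are half-open ``[low, high)`` except the uppermost band, which is closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.fft import next_fast_len

from .epochs_io import EpochSet

__all__ = [
    "WaveletSpec",
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "BandPowerTensor",
    "time_resolution",
    "morlet_kernel",
    "morlet_power",
    "edge_mask",
    "band_segment_power",
    "compute_band_power",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet decomposition settings: cycle count, frequency grid, sampling rate."""

    fs: float
    n_cycles: float = 4.0
    freqs: tuple[float, ...] = tuple(float(f) for f in range(1, 41))

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        f = np.asarray(self.freqs, dtype=float)
        if f.size == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be non-empty and strictly increasing")
        if f[0] <= 0:
            raise ValueError("frequencies must be positive")
        if f[-1] >= self.fs / 2:
            raise ValueError(
                f"max frequency {f[-1]} Hz is not below Nyquist ({self.fs / 2} Hz)"
            )


def time_resolution(f_c: float, n_cycles: float = 4.0) -> float:
    """Temporal resolution sigma_t = n / (2 pi f_c) of a Morlet wavelet, seconds.

    This is the standard deviation of the wavelet's Gaussian envelope; it
    bounds how finely power at center frequency ``f_c`` can be localized in
    time and therefore the minimum usable analysis-window length.
    """
    if f_c <= 0:
        raise ValueError("center frequency must be positive")
    return n_cycles / (2.0 * math.pi * f_c)


@lru_cache(maxsize=256)
def morlet_kernel(f_c: float, n_cycles: float, fs: float) -> np.ndarray:
    """Unit-energy complex Morlet kernel, truncated at +-5 sigma_t."""
    sigma_t = time_resolution(f_c, n_cycles)
    half = int(math.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * math.pi * f_c * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    return kernel


def _as_data(epochs: EpochSet | np.ndarray) -> np.ndarray:
    if isinstance(epochs, EpochSet):
        return epochs.data
    arr = np.asarray(epochs, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a (trial, channel, sample) array")
    return arr


def morlet_power(
    epochs: EpochSet | np.ndarray,
    spec: WaveletSpec,
    picks: Sequence[str] | None = None,
) -> np.ndarray:
    """Wavelet power tensor ``(trial, channel, freq, sample)``.

    Squared magnitude of the convolution of each channel with the Morlet
    kernel at every frequency of ``spec``.  Samples closer to an epoch edge
    than the kernel half-length are computed against implicit zero padding
    (see :func:`edge_mask` for which ones).
    """
    if picks is not None:
        if not isinstance(epochs, EpochSet):
            raise TypeError("picks requires an EpochSet input")
        epochs = epochs.pick(picks)
    data = _as_data(epochs)
    n_trials, n_channels, n_samples = data.shape
    out = np.empty((n_trials, n_channels, len(spec.freqs), n_samples))
    for fi, power in _freq_power_iter(data, spec):
        out[:, :, fi, :] = power
    return out


def _freq_power_iter(data: np.ndarray, spec: WaveletSpec):
    """Yield ``(freq_index, power (trial, channel, sample))`` per frequency.

    Convolution with a complex kernel splits into two real convolutions
    (real and imaginary kernel parts), done with real FFTs zero-padded so
    circular equals linear convolution.  Frequencies sharing a padded length
    reuse one forward transform of the data.  The result equals 'same'-mode
    convolution against zero padding; yield order is not frequency order.
    """
    n_samples = data.shape[-1]
    kernels = [
        morlet_kernel(float(f), float(spec.n_cycles), float(spec.fs))
        for f in spec.freqs
    ]
    by_length: dict[int, list[int]] = {}
    for fi, k in enumerate(kernels):
        by_length.setdefault(next_fast_len(n_samples + len(k) - 1), []).append(fi)
    for length, members in by_length.items():
        spectrum = np.fft.rfft(data, n=length, axis=-1)
        for fi in members:
            kernel = kernels[fi]
            k_re = np.fft.rfft(kernel.real, n=length)
            k_im = np.fft.rfft(kernel.imag, n=length)
            conv_re = np.fft.irfft(spectrum * k_re, n=length, axis=-1)
            conv_im = np.fft.irfft(spectrum * k_im, n=length, axis=-1)
            offset = (len(kernel) - 1) // 2
            yield fi, (
                conv_re[..., offset : offset + n_samples] ** 2
                + conv_im[..., offset : offset + n_samples] ** 2
            )


def edge_mask(spec: WaveletSpec, n_samples: int) -> np.ndarray:
    """Boolean ``(freq, sample)`` mask flagging zero-padded edge samples.

    A sample is flagged when the wavelet kernel centered on it overruns the
    epoch, i.e. its distance to either epoch boundary is less than the kernel
    half-length at that frequency.
    """
    mask = np.zeros((len(spec.freqs), n_samples), dtype=bool)
    idx = np.arange(n_samples)
    for fi, f in enumerate(spec.freqs):
        half = (len(morlet_kernel(float(f), float(spec.n_cycles), float(spec.fs))) - 1) // 2
        mask[fi] = (idx < half) | (idx >= n_samples - half)
    return mask


# -- band / segment averaging ----------------------------------------------


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float


#: Classical EEG bands: delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-40 Hz.
DEFAULT_BANDS = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 40.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Contiguous named frequency bands covering the analysis range."""

    bands: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if not math.isclose(a.high, b.low):
                raise ValueError(f"bands {a.name} and {b.name} are not contiguous")
        for b in self.bands:
            if b.low >= b.high:
                raise ValueError(f"band {b.name} has empty range")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def member_mask(self, freqs: Sequence[float]) -> np.ndarray:
        """Boolean ``(band, freq)`` membership.

        Shared boundaries belong to the upper band (half-open ``[low, high)``)
        except the top edge of the last band, which is included.
        """
        f = np.asarray(freqs, dtype=float)
        masks = []
        for i, b in enumerate(self.bands):
            upper = f <= b.high if i == len(self.bands) - 1 else f < b.high
            masks.append((f >= b.low) & upper)
        return np.stack(masks)


@dataclass
class BandPowerTensor:
    """Mean wavelet power per ``trial x electrode x band x segment`` (microvolt^2)."""

    power: np.ndarray
    segment_times: tuple[tuple[float, float], ...]
    bands: BandScheme
    channels: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 4:
            raise ValueError("power must be (trial, electrode, band, segment)")
        if self.power.shape[1] != len(self.channels):
            raise ValueError("channel names do not match power tensor")
        if self.power.shape[2] != len(self.bands.bands):
            raise ValueError("band scheme does not match power tensor")
        if self.power.shape[3] != len(self.segment_times):
            raise ValueError("segment times do not match power tensor")
        if np.any(self.power < 0):
            raise ValueError("band power must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_segments(self) -> int:
        return self.power.shape[3]


def _segment_edges(
    window: tuple[float, float], seg_len: float, fs: float, t0_sample: int, n_samples: int
) -> tuple[list[tuple[float, float]], list[int]]:
    """Millisecond segment bounds and the sample indices partitioning them.

    Segments run every ``seg_len`` ms from the window start; the final one is
    truncated at the window end when the window length is not a multiple of
    ``seg_len``.  Edges map to sample indices by rounding, tiling the sample
    range exactly.
    """
    w0, w1 = float(window[0]), float(window[1])
    if w1 <= w0:
        raise ValueError("window end must exceed window start")
    if seg_len <= 0 or seg_len > (w1 - w0):
        raise ValueError("seg_len must be positive and no longer than the window")
    n_seg = int(math.ceil((w1 - w0) / seg_len - 1e-9))
    bounds_ms = [
        (w0 + k * seg_len, min(w0 + (k + 1) * seg_len, w1)) for k in range(n_seg)
    ]
    edges_ms = [w0 + k * seg_len for k in range(n_seg)] + [w1]
    idx = [int(round(ms / 1000.0 * fs)) + t0_sample for ms in edges_ms]
    if idx[0] < 0 or idx[-1] > n_samples:
        raise ValueError(
            f"window {window} ms falls outside the epoch sample range"
        )
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("segments shorter than one sample; reduce seg_len or fs")
    return bounds_ms, idx


def band_segment_power(
    power: np.ndarray,
    freqs: Sequence[float],
    *,
    fs: float,
    t0_sample: int,
    bands: BandScheme | None = None,
    window: tuple[float, float] = (-738.0, 0.0),
    seg_len: float = 10.0,
    channels: Sequence[str] | None = None,
    labels: np.ndarray | None = None,
) -> BandPowerTensor:
    """Average a ``(trial, channel, freq, sample)`` power tensor into bands/segments.

    Per-frequency power is first averaged over the in-band frequencies, then
    over the samples of each 10-ms (default) segment tiling ``window``.
    """
    power = np.asarray(power, dtype=np.float64)
    if power.ndim != 4:
        raise ValueError("power must be (trial, channel, freq, sample)")
    if power.shape[2] != len(freqs):
        raise ValueError("freqs does not match power tensor")
    bands = bands or BandScheme()
    bounds_ms, idx = _segment_edges(window, seg_len, fs, t0_sample, power.shape[3])
    member = bands.member_mask(freqs)
    if not member.any(axis=1).all():
        empty = [b.name for b, m in zip(bands.bands, member) if not m.any()]
        raise ValueError(f"bands without any frequency on the grid: {empty}")
    # mean over in-band frequencies
    band_power = np.stack(
        [power[:, :, m, :].mean(axis=2) for m in member], axis=2
    )
    # mean over in-segment samples
    segs = np.stack(
        [band_power[:, :, :, a:b].mean(axis=3) for a, b in zip(idx, idx[1:])],
        axis=3,
    )
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(power.shape[1]))
    return BandPowerTensor(
        power=segs,
        segment_times=tuple(bounds_ms),
        bands=bands,
        channels=tuple(channels),
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )


def compute_band_power(
    epochs: EpochSet,
    spec: WaveletSpec | None = None,
    *,
    bands: BandScheme | None = None,
    window: tuple[float, float] | None = None,
    seg_len: float = 10.0,
    picks: Sequence[str] | None = None,
    max_chunk_bytes: int = 200_000_000,
) -> BandPowerTensor:
    """Epochs -> :class:`BandPowerTensor` without materializing the full TFR.

    Convenience pipeline: Morlet decomposition frequency by frequency (trials
    chunked to bound memory), accumulated directly into band/segment means.
    ``window`` defaults to the full prestimulus period.
    """
    if picks is not None:
        epochs = epochs.pick(picks)
    spec = spec or WaveletSpec(fs=epochs.fs)
    if spec.fs != epochs.fs:
        raise ValueError("wavelet spec sampling rate does not match epochs")
    bands = bands or BandScheme()
    if window is None:
        window = (-epochs.t0_sample / epochs.fs * 1000.0, 0.0)
    bounds_ms, idx = _segment_edges(
        window, seg_len, epochs.fs, epochs.t0_sample, epochs.n_samples
    )
    member = bands.member_mask(spec.freqs)
    if not member.any(axis=1).all():
        empty = [b.name for b, m in zip(bands.bands, member) if not m.any()]
        raise ValueError(f"bands without any frequency on the grid: {empty}")
    data = epochs.data
    n_trials, n_channels, n_samples = data.shape
    n_seg = len(bounds_ms)
    acc = np.zeros((n_trials, n_channels, len(bands.bands), n_seg))
    # padded-FFT spectra dominate memory: chunk trials to stay within budget
    pad = next_fast_len(4 * n_samples + 16)
    chunk = max(1, int(max_chunk_bytes // max(1, 32 * n_channels * pad)))
    band_of = {fi: bi for bi, m in enumerate(member) for fi in np.flatnonzero(m)}
    for lo in range(0, n_trials, chunk):
        for fi, p in _freq_power_iter(data[lo : lo + chunk], spec):
            if fi not in band_of:
                continue
            bi = band_of[fi]
            for si, (a, b) in enumerate(zip(idx, idx[1:])):
                acc[lo : lo + chunk, :, bi, si] += p[:, :, a:b].mean(axis=2)
    counts = member.sum(axis=1)
    acc /= counts[np.newaxis, np.newaxis, :, np.newaxis]
    return BandPowerTensor(
        power=acc,
        segment_times=tuple(bounds_ms),
        bands=bands,
        channels=tuple(epochs.channel_names),
        labels=epochs.labels.copy(),
    )
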
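"""Two-class synthetic epoched EEG with a known injected asymmetry effect.

The generator emulates the statistical structure that the decoding pipeline
assumes, so every downstream stage can be exercised with ground truth:

* per-channel 1/f-type background activity (spectrally shaped white noise),
* band-limited oscillations (amplitude-modulated sinusoids with random
  frequency and uniform random phase per trial and channel),
* a class-conditional left-minus-right power asymmetry: on *face* trials
  only, oscillatory amplitude inside ``effect_band`` and ``effect_window``
  is scaled by ``(1 + effect_size)`` on the left member and
  ``(1 - effect_size)`` on the right member of each configured homologous
  pair (amplitudes floored at zero),
* class imbalance, defaulting to 67 *face* vs 193 *no-face* trials.

With ``effect_size = 0`` the two classes are exchangeable by construction
(labels enter the generation of the signal only through the effect gain).
All randomness flows from one seed; per-trial substreams are derived
deterministically, so identical configurations reproduce bit-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epochs_io import (
    CLASSES,
    DEFAULT_MONTAGE_64,
    FACE,
    NOFACE,
    EpochSet,
    MontagePairing,
    default_pairing,
)

__all__ = ["SyntheticConfig", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic recordings.

    Defaults mirror the emulated study: 512 Hz sampling, epochs from -738 ms
    to +369 ms around stimulus onset, the 64-channel 10-10 montage, a
    67 / 193 face / no-face trial imbalance, and an alpha-band (8-13 Hz)
    left>right asymmetry confined to -615..-369 ms on a small
    parieto-occipital pair subset.

    ``effect_size`` is the dimensionless amplitude asymmetry: the left pair
    member's oscillation amplitude is multiplied by ``1 + effect_size`` and
    the right member's by ``1 - effect_size`` (floored at zero) on face
    trials inside the effect window.
    """

    n_face: int = 67
    n_noface: int = 193
    fs: float = 512.0
    epoch_span: tuple[float, float] = (-738.0, 369.0)
    montage: tuple[str, ...] = DEFAULT_MONTAGE_64
    effect_band: tuple[float, float] = (8.0, 13.0)
    effect_window: tuple[float, float] = (-615.0, -369.0)
    effect_pairs: tuple[tuple[str, str], ...] = (("P7", "P8"), ("PO7", "PO8"))
    effect_size: float = 0.8
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    #: (low Hz, high Hz, amplitude microvolt) per background oscillation.
    oscillations: tuple[tuple[float, float, float], ...] = (
        (4.0, 8.0, 2.0),
        (8.0, 13.0, 5.0),
        (13.0, 30.0, 1.5),
    )
    taper_ms: float = 10.0
    seed: int = 0

    def validate(self, pairing: MontagePairing | None = None) -> None:
        pairing = pairing or default_pairing()
        if self.n_face < 1 or self.n_noface < 1:
            raise ValueError("both classes need at least one trial")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        span0, span1 = self.epoch_span
        if span0 >= 0 or span1 <= span0:
            raise ValueError("epoch_span must start before stimulus onset")
        w0, w1 = self.effect_window
        if not (span0 <= w0 < w1 <= 0):
            raise ValueError(
                f"effect_window {self.effect_window} must lie inside the "
                f"prestimulus span [{span0}, 0]"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        for pair in self.effect_pairs:
            if tuple(pair) not in pairing.pairs:
                raise ValueError(
                    f"{pair} is not a homologous pair of the montage pairing table"
                )
            for ch in pair:
                if ch not in self.montage:
                    raise ValueError(f"effect electrode {ch!r} not in montage")
        lo, hi = self.effect_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("effect_band must be a positive range below Nyquist")


def _shaped_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                  exponent: float, fs: float, rms: float) -> np.ndarray:
    """White noise spectrally shaped to power ~ 1/f^exponent, per-channel RMS fixed."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * rms


def _effect_envelope(times_ms: np.ndarray, window: tuple[float, float],
                     taper_ms: float) -> np.ndarray:
    """Cosine-tapered indicator of the effect window (0 outside, 1 inside)."""
    w0, w1 = window
    env = np.zeros_like(times_ms)
    inside = (times_ms >= w0) & (times_ms <= w1)
    env[inside] = 1.0
    if taper_ms > 0:
        ramp_in = inside & (times_ms < w0 + taper_ms)
        ramp_out = inside & (times_ms > w1 - taper_ms)
        env[ramp_in] = 0.5 * (1 - np.cos(math.pi * (times_ms[ramp_in] - w0) / taper_ms))
        env[ramp_out] = 0.5 * (1 - np.cos(math.pi * (w1 - times_ms[ramp_out]) / taper_ms))
    return env


def generate(config: SyntheticConfig) -> EpochSet:
    """Generate a labeled :class:`~prestim.epochs_io.EpochSet` from ``config``.

    The first ``n_face`` trials carry the *face* label.  Identical
    configuration and seed reproduce bit-identical output.
    """
    config.validate()
    fs = config.fs
    n_pre = int(round(-config.epoch_span[0] / 1000.0 * fs))
    n_post = int(round(config.epoch_span[1] / 1000.0 * fs))
    n_samples = n_pre + n_post
    n_trials = config.n_face + config.n_noface
    n_channels = len(config.montage)
    ch_index = {c: i for i, c in enumerate(config.montage)}

    # per-channel asymmetry sign: +1 on left pair members, -1 on right
    gain_sign = np.zeros(n_channels)
    for left, right in config.effect_pairs:
        gain_sign[ch_index[left]] = +1.0
        gain_sign[ch_index[right]] = -1.0

    times_ms = (np.arange(n_samples) - n_pre) / fs * 1000.0
    t_s = np.arange(n_samples) / fs
    envelope = _effect_envelope(times_ms, config.effect_window, config.taper_ms)

    labels = np.array([FACE] * config.n_face + [NOFACE] * config.n_noface, dtype=object)
    data = np.empty((n_trials, n_channels, n_samples))
    children = np.random.SeedSequence(config.seed).spawn(n_trials)
    band_lo, band_hi = config.effect_band
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        x = _shaped_noise(rng, n_channels, n_samples,
                          config.noise_exponent, fs, config.noise_rms)
        for lo, hi, amp in config.oscillations:
            f = rng.uniform(lo, hi, size=n_channels)
            phase = rng.uniform(0.0, 2.0 * math.pi, size=n_channels)
            a = amp * rng.uniform(0.8, 1.2, size=n_channels)
            osc = a[:, None] * np.sin(2.0 * math.pi * f[:, None] * t_s[None, :] + phase[:, None])
            if labels[i] == FACE and config.effect_size > 0:
                in_band = (f >= band_lo) & (f < band_hi)
                affected = in_band & (gain_sign != 0)
                if affected.any():
                    gain = 1.0 + (gain_sign[affected, None] * config.effect_size) * envelope[None, :]
                    osc[affected] *= np.clip(gain, 0.0, None)
            x += osc
        data[i] = x
    return EpochSet(
        data=data,
        labels=labels,
        channel_names=config.montage,
        fs=fs,
        t0_sample=n_pre,
    )
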
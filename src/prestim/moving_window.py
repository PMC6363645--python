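"""Moving-window re-analysis: decoding accuracy as a function of time.

The prestimulus period is swept with windows of several lengths (default
246, 369, 492, 615 and 738 ms, in arithmetic progression of 123 ms) shifted
by 123 ms.  For each window placement, band/segment features are re-extracted
from that window alone (10-ms sub-segments, the final one truncated) and the
full balanced nested-CV decoder is re-run, yielding a temporal profile of
mean accuracy.

The shortest usable window is bounded below by the temporal resolution of
the slowest wavelet: at the delta-band center frequency (2.6 Hz, 4 cycles)
``sigma_t`` is about 245 ms, so windows shorter than that are flagged with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decoding import DecodingConfig, CVRunResult, nested_cv_run
from .epochs_io import EpochSet
from .features import build_datfps, build_tfps
from .timefreq import BandScheme, WaveletSpec, band_segment_power, morlet_power, time_resolution

__all__ = ["WindowPlan", "enumerate_windows", "windowed_decode", "MIN_WINDOW_MS"]

#: Temporal resolution of the slowest wavelet (delta center 2.6 Hz, 4 cycles), ms.
MIN_WINDOW_MS = 1000.0 * time_resolution(2.6, 4.0)


def enumerate_windows(
    size: float,
    shift: float,
    span: tuple[float, float] = (-738.0, 0.0),
) -> list[tuple[float, float]]:
    """All placements ``[span0 + k*shift, span0 + k*shift + size]`` inside ``span``.

    A window shorter than the slowest wavelet's temporal resolution
    (:data:`MIN_WINDOW_MS`) triggers a warning: band power inside it is no
    longer time-localized for the lowest band.
    """
    span0, span1 = float(span[0]), float(span[1])
    if size <= 0 or shift <= 0:
        raise ValueError("size and shift must be positive")
    if size > span1 - span0 + 1e-9:
        raise ValueError(f"window size {size} ms exceeds the span {span}")
    if size < MIN_WINDOW_MS:
        warnings.warn(
            f"window size {size} ms is below the slowest wavelet's temporal "
            f"resolution ({MIN_WINDOW_MS:.1f} ms)"
        )
    windows = []
    k = 0
    while span0 + k * shift + size <= span1 + 1e-9:
        start = span0 + k * shift
        windows.append((start, start + size))
        k += 1
    return windows


@dataclass(frozen=True)
class WindowPlan:
    """Window lengths and shift of the moving-window sweep."""

    sizes: tuple[float, ...] = (246.0, 369.0, 492.0, 615.0, 738.0)
    shift: float = 123.0
    span: tuple[float, float] = (-738.0, 0.0)

    def windows(self) -> list[tuple[float, float, float]]:
        """All (size, start, end) placements, ordered by size then start."""
        out = []
        for size in self.sizes:
            for start, end in enumerate_windows(size, self.shift, self.span):
                out.append((size, start, end))
        return out


def windowed_decode(
    epochs: EpochSet,
    plan: WindowPlan,
    config: DecodingConfig,
    *,
    feature: str = "datfps",
    pairs: Sequence[tuple[str, str]] | None = None,
    electrodes: Sequence[str] | None = None,
    wavelet: WaveletSpec | None = None,
    bands: BandScheme | None = None,
    seg_len: float = 10.0,
    keep_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[CVRunResult]]:
    """Decode every window of the plan and profile accuracy over time.

    The wavelet decomposition is computed once over the full epoch; each
    window then contributes its own 10-ms sub-segment features (``'datfps'``
    over ``pairs`` or ``'tfps'`` over ``electrodes``) to a fresh
    :func:`~prestim.decoding.nested_cv_run` with the same configuration (and
    seed), so profiles are deterministic and the full-span window reproduces
    the standard run.

    Returns a DataFrame with columns ``window_size_ms, window_start_ms,
    window_end_ms, mean_acc, sem_acc, n_models`` (and the per-window
    :class:`CVRunResult` list when ``keep_results``).
    """
    if feature == "datfps":
        if not pairs:
            raise ValueError("feature='datfps' requires pairs")
        channels = [c for pair in pairs for c in pair]
    elif feature == "tfps":
        if not electrodes:
            raise ValueError("feature='tfps' requires electrodes")
        channels = list(electrodes)
    else:
        raise ValueError("feature must be 'datfps' or 'tfps'")
    sub = epochs.pick(channels)
    wavelet = wavelet or WaveletSpec(fs=epochs.fs)
    bands = bands or BandScheme()
    power = morlet_power(sub, wavelet)
    rows = []
    results: list[CVRunResult] = []
    for size, start, end in plan.windows():
        if end - start < seg_len:
            raise ValueError("window shorter than one segment")
        bp = band_segment_power(
            power, wavelet.freqs,
            fs=sub.fs, t0_sample=sub.t0_sample,
            bands=bands, window=(start, end), seg_len=seg_len,
            channels=sub.channel_names, labels=sub.labels,
        )
        if feature == "datfps":
            fset = build_datfps(bp, pairs)
        else:
            fset = build_tfps(bp, electrodes)
        res = nested_cv_run(fset, config)
        rows.append(
            {
                "window_size_ms": size,
                "window_start_ms": start,
                "window_end_ms": end,
                "mean_acc": res.mean_accuracy,
                "sem_acc": res.sem_accuracy,
                "n_models": res.model_count,
            }
        )
        if keep_results:
            results.append(res)
    profile = pd.DataFrame(rows)
    return (profile, results) if keep_results else profile
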
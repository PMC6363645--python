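"""Feature-usage consistency: occurrence histograms, dominance, commonality.

Every (repetition, fold) model of a CV run selects its own feature subset.
Counting how often each feature is selected across all models gives an
occurrence histogram; features whose count reaches a fraction of the maximum
count (e.g. at least 60% for within-subject analyses, 75% for cross-subject
ones) are *dominant*.  Dominant features can be localized by frequency band
and by prestimulus time window, and compared across subjects through the
commonality index ``C_i`` - the number of subjects in which a feature is
dominant.  Features with ``C_i`` at or above a threshold (default 5 of 7
subjects) form the common feature set, whose electrodes/pairs can be fed
back into :func:`prestim.features.subset_features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureDescriptor

__all__ = [
    "OccurrenceHistogram",
    "CommonalityMap",
    "occurrence_histogram",
    "dominant_features",
    "band_occurrence",
    "window_occurrence",
    "default_time_windows",
    "commonality_index",
    "common_electrode_set",
]


@dataclass
class OccurrenceHistogram:
    """Per-feature selection count over all trained models of a run."""

    counts: np.ndarray
    model_count: int
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.descriptors):
            raise ValueError("counts do not match descriptors")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.model_count:
            raise ValueError("counts must lie in [0, model_count]")


@dataclass
class CommonalityMap:
    """Per-feature number of subjects in which the feature is dominant."""

    c_i: np.ndarray
    n_subjects: int
    descriptors: tuple[FeatureDescriptor, ...]
    threshold: int = 5

    def __post_init__(self) -> None:
        self.c_i = np.asarray(self.c_i, dtype=np.int64)
        if len(self.c_i) != len(self.descriptors):
            raise ValueError("c_i does not match descriptors")
        if self.c_i.min(initial=0) < 0 or self.c_i.max(initial=0) > self.n_subjects:
            raise ValueError("c_i must lie in [0, n_subjects]")

    @property
    def common_mask(self) -> np.ndarray:
        return self.c_i >= self.threshold


def occurrence_histogram(
    selected_lists: Sequence[Sequence[FeatureDescriptor]],
    descriptors: Sequence[FeatureDescriptor],
) -> OccurrenceHistogram:
    """Count, per feature, the number of models that selected it.

    ``selected_lists`` holds one descriptor list per trained model (e.g. from
    :meth:`prestim.decoding.CVRunResult.selected_lists`).
    """
    if len(selected_lists) == 0:
        raise ValueError("need at least one model")
    descriptors = tuple(descriptors)
    index = {d: i for i, d in enumerate(descriptors)}
    counts = np.zeros(len(descriptors), dtype=np.int64)
    for model in selected_lists:
        for d in model:
            if d not in index:
                raise KeyError(f"selected descriptor {d} not in feature space")
            counts[index[d]] += 1
    return OccurrenceHistogram(counts, len(selected_lists), descriptors)


def dominant_features(h: OccurrenceHistogram, fraction: float) -> np.ndarray:
    """Mask of features whose count reaches ``fraction`` of the maximum count.

    The cutoff is inclusive (count >= fraction * max).
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    max_count = int(h.counts.max(initial=0))
    if max_count == 0:
        raise ValueError("no feature was ever selected")
    return h.counts >= fraction * max_count


def band_occurrence(h: OccurrenceHistogram, mask: np.ndarray) -> dict[str, int]:
    """Number of dominant features per frequency band."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != h.counts.shape:
        raise ValueError("mask does not match histogram")
    bands: dict[str, int] = {}
    for d in h.descriptors:
        bands.setdefault(d.band, 0)
    for d, m in zip(h.descriptors, mask):
        if m:
            bands[d.band] += 1
    return bands


def default_time_windows() -> tuple[tuple[float, float], ...]:
    """Eight prestimulus windows: seven of 100 ms and a final 38-ms window."""
    return tuple((-738.0 + 100.0 * k, -638.0 + 100.0 * k) for k in range(7)) + (
        (-38.0, 0.0),
    )


def window_occurrence(
    h: OccurrenceHistogram,
    mask: np.ndarray,
    windows: Sequence[tuple[float, float]] | None = None,
) -> list[tuple[tuple[float, float], int]]:
    """Number of dominant features per prestimulus time window.

    Each feature is assigned to the window containing its segment start time
    (so a truncated final segment belongs to the last window).  Windows must
    be non-overlapping and ordered.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != h.counts.shape:
        raise ValueError("mask does not match histogram")
    windows = tuple(windows) if windows is not None else default_time_windows()
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if a1 > b0:
            raise ValueError("time windows overlap or are unordered")
    counts = [0] * len(windows)
    for d, m in zip(h.descriptors, mask):
        if not m:
            continue
        start = d.seg_ms[0]
        for wi, (w0, w1) in enumerate(windows):
            last = wi == len(windows) - 1
            if w0 <= start < w1 or (last and np.isclose(start, w1)):
                counts[wi] += 1
                break
        else:
            raise ValueError(f"feature segment at {start} ms not covered by windows")
    return [(w, c) for w, c in zip(windows, counts)]


def commonality_index(
    masks: Sequence[np.ndarray],
    descriptors: Sequence[FeatureDescriptor],
    threshold: int = 5,
) -> CommonalityMap:
    """Commonality index: in how many subjects is each feature dominant.

    All per-subject dominance masks must live on the same feature space.
    """
    descriptors = tuple(descriptors)
    if len(masks) == 0:
        raise ValueError("need at least one subject mask")
    stacked = []
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != (len(descriptors),):
            raise ValueError("subject mask does not match the feature space")
        stacked.append(m)
    c_i = np.sum(stacked, axis=0).astype(np.int64)
    return CommonalityMap(c_i, len(masks), descriptors, threshold)


def common_electrode_set(
    c: CommonalityMap,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Electrodes and pairs appearing in the common feature set.

    Returns the sorted unique electrode labels (both members of every common
    pair feature plus the electrodes of common single-electrode features) and
    the list of common pairs, ready for
    :func:`prestim.features.subset_features`.
    """
    electrodes: set[str] = set()
    pairs: list[tuple[str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    for d, common in zip(c.descriptors, c.common_mask):
        if not common:
            continue
        if d.kind == "pair":
            pair = tuple(d.site)
            electrodes.update(pair)
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                pairs.append(pair)
        else:
            electrodes.add(d.site)
    if not electrodes:
        warnings.warn("common feature set is empty at the current threshold")
    return sorted(electrodes), pairs
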
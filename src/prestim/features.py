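"""Flatten band/segment power into trial x feature matrices.

Two feature families are supported, both derived from the
``trial x electrode x band x segment`` power tensor:

* **TFPS** - the per-electrode time-frequency power spectrum: one feature per
  (electrode, band, segment) cell, for any electrode subset (all 64 scalp
  electrodes give 64 x 5 x 74 = 23,680 features; one electrode gives 370).
* **DATFPS** - differential asymmetry: for each homologous (left, right)
  pair, the left-electrode power minus the right-electrode power per
  (band, segment) cell; 27 pairs give 9,990 features.

Columns are ordered electrode-major, then band, then segment, and every
column carries a descriptor naming its (electrode or pair, band, segment),
which keeps selection histograms reproducible and reversible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .timefreq import BandPowerTensor

__all__ = [
    "FeatureDescriptor",
    "FeatureSet",
    "build_tfps",
    "build_datfps",
    "subset_features",
    "export_csv",
    "import_csv",
]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column.

    ``site`` is an electrode label for ``kind='single'`` or a (left, right)
    label pair for ``kind='pair'``; ``segment`` indexes the 10-ms segment and
    ``seg_ms`` is its (start, end) in milliseconds relative to stimulus onset.
    """

    kind: str
    site: str | tuple[str, str]
    band: str
    segment: int
    seg_ms: tuple[float, float]

    def __str__(self) -> str:
        site = self.site if isinstance(self.site, str) else "-".join(self.site)
        return f"{site}|{self.band}|seg{self.segment}[{self.seg_ms[0]:g},{self.seg_ms[1]:g})"


@dataclass
class FeatureSet:
    """Trial x feature matrix plus per-column descriptors and trial labels."""

    matrix: np.ndarray
    descriptors: tuple[FeatureDescriptor, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be (trial, feature)")
        if self.matrix.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match matrix columns")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("descriptors must be unique")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count does not match matrix rows")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


def _labels_from(b: BandPowerTensor, labels: np.ndarray | None) -> np.ndarray:
    if labels is not None:
        return np.asarray(labels, dtype=object)
    if b.labels is None:
        raise ValueError("band power tensor carries no labels; pass labels=")
    return b.labels


def build_tfps(
    b: BandPowerTensor,
    electrodes: Sequence[str] | None = None,
    labels: np.ndarray | None = None,
) -> FeatureSet:
    """Single-electrode band/segment power features over an electrode subset.

    ``electrodes`` defaults to every channel of the tensor.  The feature
    dimension is ``len(electrodes) x n_bands x n_segments``.
    """
    electrodes = tuple(electrodes if electrodes is not None else b.channels)
    if not electrodes:
        raise ValueError("electrode selection is empty")
    ch_index = {c: i for i, c in enumerate(b.channels)}
    missing = [e for e in electrodes if e not in ch_index]
    if missing:
        raise KeyError(f"electrodes not in band power tensor: {missing}")
    idx = [ch_index[e] for e in electrodes]
    n_trials = b.n_trials
    sub = b.power[:, idx, :, :]  # (trial, electrode, band, segment)
    matrix = sub.reshape(n_trials, -1)
    descriptors = tuple(
        FeatureDescriptor("single", e, band, s, b.segment_times[s])
        for e in electrodes
        for band in b.bands.names
        for s in range(b.n_segments)
    )
    return FeatureSet(matrix, descriptors, _labels_from(b, labels))


def build_datfps(
    b: BandPowerTensor,
    pairs: Sequence[tuple[str, str]],
    labels: np.ndarray | None = None,
) -> FeatureSet:
    """Left-minus-right asymmetry features for homologous electrode pairs.

    Each feature is ``power(left) - power(right)`` for one
    (pair, band, segment) cell; asymmetry by raw power subtraction.
    """
    pairs = tuple((l, r) for l, r in pairs)
    if not pairs:
        raise ValueError("pair selection is empty")
    ch_index = {c: i for i, c in enumerate(b.channels)}
    for l, r in pairs:
        if l not in ch_index or r not in ch_index:
            raise KeyError(f"pair ({l}, {r}) not fully present in band power tensor")
    left_idx = [ch_index[l] for l, _ in pairs]
    right_idx = [ch_index[r] for _, r in pairs]
    diff = b.power[:, left_idx, :, :] - b.power[:, right_idx, :, :]
    matrix = diff.reshape(b.n_trials, -1)
    descriptors = tuple(
        FeatureDescriptor("pair", pair, band, s, b.segment_times[s])
        for pair in pairs
        for band in b.bands.names
        for s in range(b.n_segments)
    )
    return FeatureSet(matrix, descriptors, _labels_from(b, labels))


def subset_features(
    f: FeatureSet, items: Iterable[str | tuple[str, str]]
) -> FeatureSet:
    """Column subset restricted to the given electrodes or pairs.

    ``items`` may mix electrode labels (matching ``kind='single'`` columns)
    and (left, right) tuples (matching ``kind='pair'`` columns).  Column
    order of the parent set is preserved.
    """
    wanted = {i if isinstance(i, str) else tuple(i) for i in items}
    if not wanted:
        raise ValueError("empty feature subset requested")
    present = {d.site for d in f.descriptors}
    missing = wanted - present
    if missing:
        raise KeyError(f"items not present in feature set: {sorted(map(str, missing))}")
    keep = [i for i, d in enumerate(f.descriptors) if d.site in wanted]
    return FeatureSet(
        matrix=f.matrix[:, keep].copy(),
        descriptors=tuple(f.descriptors[i] for i in keep),
        labels=f.labels.copy(),
    )


def export_csv(f: FeatureSet, path: str | Path) -> None:
    """Write a feature set to CSV for inspection (header = descriptor strings).

    The first column holds the trial label; descriptor metadata is embedded
    in the column headers as ``kind:site:band:segment:start:end``.
    """
    columns = {
        f"{d.kind}:{d.site if isinstance(d.site, str) else '-'.join(d.site)}"
        f":{d.band}:{d.segment}:{d.seg_ms[0]:g}:{d.seg_ms[1]:g}": f.matrix[:, i]
        for i, d in enumerate(f.descriptors)
    }
    frame = pd.DataFrame({"label": f.labels.astype(str), **columns})
    frame.to_csv(path, index=False)


def import_csv(path: str | Path) -> FeatureSet:
    """Read a feature set written by :func:`export_csv`."""
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValueError("feature CSV must have a 'label' column")
    descriptors = []
    for name in frame.columns[1:]:
        kind, site, band, segment, start, end = name.split(":")
        descriptors.append(
            FeatureDescriptor(
                kind,
                site if kind == "single" else tuple(site.split("-")),
                band,
                int(segment),
                (float(start), float(end)),
            )
        )
    return FeatureSet(
        matrix=frame.iloc[:, 1:].to_numpy(dtype=np.float64),
        descriptors=tuple(descriptors),
        labels=frame["label"].to_numpy(dtype=object),
    )
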
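"""Epoched-EEG container, on-disk format, and the 10-10 montage pairing table.

The :class:`EpochSet` is the universal input of the pipeline: a
``trial x channel x sample`` tensor of EEG voltages (microvolt), per-trial
class labels (*face* / *noface*), ordered 10-10 channel labels, the sampling
rate, and the sample index of stimulus onset.  Epochs span a prestimulus
period (used for decoding) and a short poststimulus tail.

The on-disk container is deliberately plain: a directory holding
``header.json`` (all metadata) and ``data.f32`` (little-endian 32-bit floats,
trial-major, then channel, then sample).  EDF+ files with annotation-delimited
events can also be imported.

The montage pairing table splits the 64-channel 10-10 layout into 10 midline
electrodes and 27 homologous (left, right) pairs used for hemispheric and
asymmetry feature sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FACE",
    "NOFACE",
    "CLASSES",
    "MIDLINE_10",
    "HOMOLOGOUS_PAIRS_27",
    "DEFAULT_MONTAGE_64",
    "EpochSet",
    "MontagePairing",
    "default_pairing",
    "write_epochs",
    "read_epochs",
    "read_edf_epochs",
]

#: Class label of trials on which a face was reported.
FACE = "face"
#: Class label of trials on which no face was reported.
NOFACE = "noface"
CLASSES = (FACE, NOFACE)

#: The ten midline electrodes excluded from hemispheric feature sets.
MIDLINE_10 = ("Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz")

#: 27 homologous (left, right) electrode pairs of the 64-channel 10-10 layout.
HOMOLOGOUS_PAIRS_27 = (
    ("Fp1", "Fp2"),
    ("AF7", "AF8"),
    ("AF3", "AF4"),
    ("F7", "F8"),
    ("F5", "F6"),
    ("F3", "F4"),
    ("F1", "F2"),
    ("FT7", "FT8"),
    ("FC5", "FC6"),
    ("FC3", "FC4"),
    ("FC1", "FC2"),
    ("T7", "T8"),
    ("C5", "C6"),
    ("C3", "C4"),
    ("C1", "C2"),
    ("TP7", "TP8"),
    ("CP5", "CP6"),
    ("CP3", "CP4"),
    ("CP1", "CP2"),
    ("P9", "P10"),
    ("P7", "P8"),
    ("P5", "P6"),
    ("P3", "P4"),
    ("P1", "P2"),
    ("PO7", "PO8"),
    ("PO3", "PO4"),
    ("O1", "O2"),
)

#: Anterior-to-posterior channel order of the full 64-channel montage.
DEFAULT_MONTAGE_64 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz",
)


@dataclass
class EpochSet:
    """Labeled, montage-annotated trial x channel x sample container.

    Parameters
    ----------
    data
        Voltage tensor, shape ``(n_trials, n_channels, n_samples)``, microvolt.
    labels
        Per-trial class, each one of :data:`FACE` / :data:`NOFACE`.
    channel_names
        Ordered, unique 10-10 electrode labels, one per channel.
    fs
        Sampling rate in Hz.
    t0_sample
        Index of stimulus onset along the sample axis; sample ``k`` sits at
        ``(k - t0_sample) / fs * 1000`` milliseconds.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    t0_sample: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.channel_names = tuple(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trial, channel, sample); got shape {self.data.shape}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.labels) != n_trials:
            raise ValueError(
                f"{len(self.labels)} labels for {n_trials} trials"
            )
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown trial labels: {sorted(bad)}")
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} data channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not (0 <= self.t0_sample < n_samples):
            raise ValueError(
                f"t0_sample {self.t0_sample} outside sample axis [0, {n_samples})"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    # -- derived geometry ---------------------------------------------------

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
    def times(self) -> np.ndarray:
        """Per-sample time in ms relative to stimulus onset (strictly increasing)."""
        k = np.arange(self.n_samples)
        return (k - self.t0_sample) / self.fs * 1000.0

    def pick(self, channels: Sequence[str]) -> "EpochSet":
        """Return a channel-subset copy, in the requested order."""
        idx = [self._channel_index(c) for c in channels]
        return EpochSet(
            data=self.data[:, idx, :].copy(),
            labels=self.labels.copy(),
            channel_names=tuple(channels),
            fs=self.fs,
            t0_sample=self.t0_sample,
        )

    def _channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@dataclass(frozen=True)
class MontagePairing:
    """Split of a 64-channel 10-10 montage into midline and homologous pairs."""

    midline: tuple[str, ...] = MIDLINE_10
    pairs: tuple[tuple[str, str], ...] = HOMOLOGOUS_PAIRS_27

    def __post_init__(self) -> None:
        flat = [c for pair in self.pairs for c in pair]
        everything = list(self.midline) + flat
        if len(set(everything)) != len(everything):
            raise ValueError("midline and pair labels must not overlap")

    @property
    def left(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.pairs)

    @property
    def right(self) -> tuple[str, ...]:
        return tuple(r for _, r in self.pairs)

    @property
    def all_labels(self) -> tuple[str, ...]:
        return tuple(self.midline) + self.left + self.right

    def pair_of(self, label: str) -> tuple[str, str]:
        """The (left, right) pair containing ``label``."""
        for pair in self.pairs:
            if label in pair:
                return pair
        raise KeyError(f"{label!r} is not a paired electrode")

    def mirror(self, label: str) -> str:
        """The homologous electrode on the opposite hemisphere."""
        left, right = self.pair_of(label)
        return right if label == left else left


def default_pairing() -> MontagePairing:
    """The 27-pair table for the standard 64-channel 10-10 layout.

    The ten midline electrodes (Fpz, AFz, Fz, FCz, Cz, CPz, Pz, POz, Oz, Iz)
    are excluded from pairing; every remaining electrode is paired with its
    mirror across the midline (Fp1 with Fp2, and so on).
    """
    return MontagePairing()


# -- on-disk container ------------------------------------------------------

_HEADER_NAME = "header.json"
_DATA_NAME = "data.f32"


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to ``path`` (a directory, created if needed).

    Layout: ``header.json`` holds fs, t0_sample, channel names, labels and the
    tensor shape; ``data.f32`` holds the voltages as little-endian 32-bit
    floats in trial-major, then channel, then sample order.  Round-trips
    bit-exactly at 32-bit precision.

    Raises
    ------
    ValueError
        If the tensor contains non-finite values (the offending trial and
        channel are reported).
    """
    epochs.validate()
    finite = np.isfinite(epochs.data)
    if not finite.all():
        t, c, s = np.argwhere(~finite)[0]
        raise ValueError(
            f"non-finite sample at trial {t}, channel {c} ({epochs.channel_names[c]}), sample {s}"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format": "prestim-epochs",
        "version": 1,
        "fs": float(epochs.fs),
        "t0_sample": int(epochs.t0_sample),
        "channel_names": list(epochs.channel_names),
        "labels": [str(l) for l in epochs.labels],
        "dtype": "<f4",
        "order": ["trial", "channel", "sample"],
        "shape": list(epochs.data.shape),
    }
    (path / _HEADER_NAME).write_text(json.dumps(header, indent=1))
    data32 = np.ascontiguousarray(epochs.data, dtype="<f4")
    (path / _DATA_NAME).write_bytes(data32.tobytes())
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch container directory or an EDF+ file.

    Directories must have been produced by :func:`write_epochs`.  Files ending
    in ``.edf`` are imported with :func:`read_edf_epochs` using its default
    epoch span.
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() == ".edf":
        return read_edf_epochs(path)
    header_path = path / _HEADER_NAME
    if not header_path.is_file():
        raise FileNotFoundError(f"no {_HEADER_NAME} under {path}")
    header = json.loads(header_path.read_text())
    if header.get("format") != "prestim-epochs":
        raise ValueError(f"{header_path} is not a prestim epoch header")
    shape = tuple(header["shape"])
    if len(shape) != 3:
        raise ValueError(f"malformed shape in header: {shape}")
    if len(header["channel_names"]) != shape[1]:
        raise ValueError(
            f"header names {len(header['channel_names'])} channels but data has {shape[1]}"
        )
    raw = (path / _DATA_NAME).read_bytes()
    expected = 4 * int(np.prod(shape))
    if len(raw) != expected:
        raise ValueError(
            f"data.f32 holds {len(raw)} bytes, header shape requires {expected}"
        )
    data = np.frombuffer(raw, dtype="<f4").reshape(shape).astype(np.float64)
    return EpochSet(
        data=data,
        labels=np.array(header["labels"], dtype=object),
        channel_names=tuple(header["channel_names"]),
        fs=float(header["fs"]),
        t0_sample=int(header["t0_sample"]),
    )


def read_edf_epochs(
    path: str | Path,
    *,
    pre_ms: float = 738.0,
    post_ms: float = 369.0,
    classes: Sequence[str] = CLASSES,
) -> EpochSet:
    """Import epochs from an EDF+ file with annotation-delimited events.

    Every annotation whose description matches one of ``classes`` marks a
    stimulus onset; an epoch of ``round(pre_ms/1000*fs)`` samples before and
    ``round(post_ms/1000*fs)`` samples after the onset is cut around it.

    Annotations whose epoch would overrun the recording raise an error.
    """
    import mne  # local import: mne is heavy and only needed for EDF files

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne loads EEG in volts; container is microvolt
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    trials, labels = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc not in classes:
            continue
        k = int(round(onset * fs))
        lo, hi = k - n_pre, k + n_post
        if lo < 0 or hi > data.shape[1]:
            raise ValueError(
                f"annotation {desc!r} at {onset:.3f}s overruns the recording"
            )
        trials.append(data[:, lo:hi])
        labels.append(desc)
    if not trials:
        raise ValueError(f"no {classes} annotations found in {path}")
    return EpochSet(
        data=np.stack(trials, axis=0),
        labels=np.array(labels, dtype=object),
        channel_names=tuple(raw.ch_names),
        fs=fs,
        t0_sample=n_pre,
    )
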
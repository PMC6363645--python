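"""Shared fixtures: study-scale simulation runs and a minimal EDF+ writer.

The stochastic parameter-recovery and null-calibration suites all run the
same pipeline (synthetic epochs -> band power -> asymmetry features ->
balanced nested CV) under a fixed set of study conditions; the session-scoped
fixtures below compute each batch of seeded runs once and share it across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from prestim import (
    DecodingConfig,
    SyntheticConfig,
    WindowPlan,
    build_datfps,
    compute_band_power,
    empirical_chance,
    generate,
    nested_cv_run,
    windowed_decode,
)

# Reduced parieto-occipital + control montage used by the simulation studies:
# six homologous pairs (two of which carry the injected effect) plus two
# midline electrodes, keeping the wavelet decomposition affordable.
STUDY_MONTAGE = (
    "F3", "F4", "C3", "C4", "P3", "P4",
    "P7", "P8", "PO7", "PO8", "O1", "O2", "Pz", "Oz",
)
STUDY_PAIRS = (
    ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
    ("P7", "P8"), ("PO7", "PO8"), ("O1", "O2"),
)
EFFECT_PAIRS = (("P7", "P8"), ("PO7", "PO8"))
EFFECT_WINDOW = (-615.0, -369.0)


def study_config(effect_size: float, seed: int, **overrides) -> SyntheticConfig:
    """Synthetic study conditions on the reduced montage."""
    fields = dict(
        montage=STUDY_MONTAGE,
        effect_pairs=EFFECT_PAIRS,
        effect_window=EFFECT_WINDOW,
        effect_size=effect_size,
        seed=seed,
    )
    fields.update(overrides)
    return SyntheticConfig(**fields)


def decode_datfps(
    config: SyntheticConfig,
    *,
    pairs=STUDY_PAIRS,
    n_reps: int = 5,
    max_epochs: int = 200,
    p_threshold: float = 0.05,
):
    """Full pipeline run: generate -> band power -> DATFPS -> nested CV."""
    epochs = generate(config)
    channels = [c for pair in pairs for c in pair]
    bp = compute_band_power(epochs, picks=channels)
    fset = build_datfps(bp, pairs)
    dconf = DecodingConfig(
        n_reps=n_reps,
        max_epochs=max_epochs,
        p_threshold=p_threshold,
        seed=(config.seed * 7919 + 13) % (2**31 - 1),
    )
    return nested_cv_run(fset, dconf)


N_CALIBRATION_SEEDS = 20


@pytest.fixture(scope="session")
def null_runs():
    """20 seeded pipeline runs with no injected effect (label-exchangeable data)."""
    return [decode_datfps(study_config(0.0, seed)) for seed in range(N_CALIBRATION_SEEDS)]


@pytest.fixture(scope="session")
def effect_runs():
    """20 seeded pipeline runs with the injected alpha asymmetry (effect 0.8)."""
    return [decode_datfps(study_config(0.8, seed)) for seed in range(N_CALIBRATION_SEEDS)]


@pytest.fixture(scope="session")
def mid_effect_runs():
    """10 seeded runs at intermediate effect size 0.4 (monotonicity check)."""
    return [decode_datfps(study_config(0.4, seed)) for seed in range(10)]


@pytest.fixture(scope="session")
def chance_level(null_runs):
    """Empirical chance for the balanced evaluation size of the study runs."""
    return empirical_chance(null_runs[0].n_balanced, alpha=0.05)


@pytest.fixture(scope="session")
def subject_sims():
    """10 replications of a 7-subject study (smaller per-subject recordings).

    Returns a list of replications; each holds the 7 per-subject CV results.
    """
    replications = []
    for rep in range(10):
        subjects = []
        for subj in range(7):
            config = study_config(
                0.8, seed=1000 + rep * 7 + subj, n_face=40, n_noface=80
            )
            subjects.append(decode_datfps(config, n_reps=3))
        replications.append(subjects)
    return replications


MW_PAIRS = (("P3", "P4"), ("P7", "P8"), ("PO7", "PO8"), ("O1", "O2"))
MW_PLAN = WindowPlan(sizes=(246.0,), shift=123.0)


def moving_window_profile(effect_size: float, seed: int):
    """Accuracy profile of 246-ms windows stepped by 123 ms over the prestimulus span."""
    config = study_config(effect_size, seed, n_face=30, n_noface=60)
    epochs = generate(config)
    dconf = DecodingConfig(
        n_reps=2, max_epochs=200, p_threshold=0.05,
        seed=(seed * 7919 + 13) % (2**31 - 1),
    )
    return windowed_decode(epochs, MW_PLAN, dconf, pairs=MW_PAIRS)


@pytest.fixture(scope="session")
def mw_null_profiles():
    """20 seeded moving-window profiles on null data."""
    return [moving_window_profile(0.0, seed) for seed in range(N_CALIBRATION_SEEDS)]


@pytest.fixture(scope="session")
def mw_effect_profiles():
    """10 seeded moving-window profiles with the injected effect."""
    return [moving_window_profile(0.8, seed) for seed in range(10)]


# -- minimal EDF+ writer for import tests -----------------------------------


def write_minimal_edf(path, signals: np.ndarray, fs: int, annotations,
                      phys_range=(-200.0, 200.0)) -> None:
    """Write a small synthetic EDF+C file (int16, 1-s records, TAL annotations).

    ``signals`` is (channel, sample) in microvolt; ``annotations`` is a list
    of (onset_seconds, description).  Purely a test fixture generator.
    """
    n_ch, n_samp = signals.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = signals
    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767
    digital = np.round(
        (padded - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")
    ann_len = 60  # int16 samples reserved for the annotation signal per record
    ns = n_ch + 1
    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2024 X X X".ljust(80)
    hdr += b"01.01.24" + b"00.00.00"
    hdr += str(256 * (ns + 1)).encode().ljust(8)
    hdr += b"EDF+C".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(ns).encode().ljust(4)

    def field(values, width):
        return b"".join(str(v).encode().ljust(width) for v in values)

    hdr += field([f"EEG ch{i + 1}" for i in range(n_ch)] + ["EDF Annotations"], 16)
    hdr += field([""] * ns, 80)
    hdr += field(["uV"] * n_ch + [""], 8)
    hdr += field([pmin] * n_ch + [-1], 8)
    hdr += field([pmax] * n_ch + [1], 8)
    hdr += field([dmin] * n_ch + [-32768], 8)
    hdr += field([dmax] * n_ch + [32767], 8)
    hdr += field([""] * ns, 80)
    hdr += field([fs] * n_ch + [ann_len], 8)
    hdr += field([""] * ns, 32)
    assert len(hdr) == 256 * (ns + 1)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            tal = f"+{r}\x14\x14\x00".encode()
            for onset, desc in annotations:
                if r <= onset < r + 1:
                    tal += f"+{onset:g}\x14{desc}\x14\x00".encode()
            fh.write(tal.ljust(ann_len * 2, b"\x00"))
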
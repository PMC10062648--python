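"""Shared fixtures: small simulated cohorts and a minimal EDF writer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import emostim as e


@pytest.fixture(scope="session")
def reference_scores() -> pd.DataFrame:
    return e.validation_reference_scores()


@pytest.fixture(scope="session")
def small_rating_table() -> pd.DataFrame:
    """Two-group cohort rating one stimulus per emotion category."""
    cfg = e.RatingSimConfig(n_per_cell=8, seed=11)
    stimuli = [(f"{cat}_stim", cat) for cat in e.EMOTION_CATEGORIES]
    return e.gen_ratings(cfg, stimuli)


@pytest.fixture(scope="session")
def catalog_ratings() -> pd.DataFrame:
    """Ratings of the full 54-video catalog by all six groups (small n)."""
    cfg = e.RatingSimConfig(
        n_per_cell=6, seed=7, stimulus_sd=0.5, hit_gap=1.2, noise_sd=1.2
    )
    catalog = [d for d in e.full_catalog()]
    return e.gen_ratings(cfg, catalog)


@pytest.fixture(scope="session")
def short_recording():
    """Three 20-s labelled trials, no blink artifacts."""
    cfg = e.EEGSimConfig(trial_length_s=(20, 20), blink_rate_per_min=0.0, seed=3)
    rec, truth = e.gen_eeg(
        cfg,
        [
            ("positive_1_1_1", "positive"),
            ("neutral_1_1_1", "neutral"),
            ("negative_1_1_1", "negative"),
        ],
    )
    return rec, truth


def write_minimal_edf(path, data_uv: np.ndarray, fs: int, labels) -> None:
    """Write a bare-bones EDF file (16-bit, one 1-s record per second).

    Test-only helper so the EDF read path can be exercised without any
    EDF-writing dependency; trailing partial seconds are dropped.
    """
    n_ch, n_samp = data_uv.shape
    n_rec = n_samp // fs
    data_uv = data_uv[:, : n_rec * fs]
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 + 256 * n_ch, 8),
            pad("", 44),
            pad(n_rec, 8),
            pad(1, 8),
            pad(n_ch, 4),
        ]
    )
    fields = [
        (labels, 16),
        (["" for _ in labels], 80),
        (["uV" for _ in labels], 8),
        ([phys_min for _ in labels], 8),
        ([phys_max for _ in labels], 8),
        ([dig_min for _ in labels], 8),
        ([dig_max for _ in labels], 8),
        (["" for _ in labels], 80),
        ([fs for _ in labels], 8),
        (["" for _ in labels], 32),
    ]
    for values, width in fields:
        header += b"".join(pad(v, width) for v in values)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch, r * fs : (r + 1) * fs].tobytes())
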
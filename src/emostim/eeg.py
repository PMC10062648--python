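"""EEG preprocessing and differential-entropy feature extraction.

The pipeline mirrors common consumer-EEG emotion-recognition practice:
a 14-channel 10-20 montage sampled at 256 Hz is band-pass filtered to
0.1-50 Hz, notch filtered at 50 Hz, screened for high-amplitude artifacts
(with a hard cap on how much data may be discarded), sliced into
non-overlapping 1-second epochs, and summarised per epoch as differential
entropy (DE) in five canonical bands.

For a zero-mean Gaussian signal of variance sigma^2 the differential
entropy is ``0.5 * ln(2 * pi * e * sigma^2)``; band-limited DE therefore
equals log band power up to constants, which is what makes it a robust
EEG emotion feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

#: Emotiv EPOC electrode montage, canonical order.
CANONICAL_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

CONDITIONS = ("positive", "neutral", "negative")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low {self.low} must be < high {self.high}")


#: canonical analysis bands (Hz)
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 31.0, 45.0),
)


@dataclass(frozen=True)
class Trial:
    """A labelled window of the recording (sample indices, end exclusive)."""

    stimulus_id: str
    condition: str
    start_sample: int
    end_sample: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("trial window must satisfy 0 <= start < end")


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for t in self.trials:
            if t.end_sample > self.n_samples:
                raise ValueError(f"trial {t.stimulus_id} extends past the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PreprocessReport:
    """What artifact screening removed, and under which settings."""

    removed_fraction: float
    removed_segments: list[tuple[int, int]]
    filter_settings: dict
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.removed_fraction > 0.10 + 1e-12:
            raise ValueError("removed fraction exceeds the 10% cap")


class DegenerateBandError(ValueError):
    """Band variance is zero, so differential entropy is -inf."""


def _check_corners(fs: float, *freqs: float) -> None:
    for f in freqs:
        if not 0 < f < fs / 2:
            raise ValueError(f"corner frequency {f} Hz outside (0, fs/2={fs / 2})")


def _padlen(n: int, fs: float, corner: float) -> int:
    """Forward-backward padding sized to the slowest corner's time scale."""
    return int(min(n - 1, max(27, 3 * fs / corner)))


def bandpass_filter(
    rec: EEGRecording, low: float = 0.1, high: float = 50.0, order: int = 8
) -> EEGRecording:
    """Zero-phase Butterworth band-pass copy of the recording.

    Implemented as a low-pass (given ``order``) followed by a gentle
    2nd-order high-pass, each applied forward-backward. Running the
    low-pass first keeps the slow ringing of the 0.1 Hz corner from
    leaking stopband energy back into the passband; with the defaults a
    60 Hz line component drops below 10% RMS at fs = 256 Hz while the
    passband stays flat within 1 dB.
    """
    _check_corners(rec.fs, low, high)
    if low >= high:
        raise ValueError("low corner must be below high corner")
    n = rec.n_samples
    sos_lp = signal.butter(order, high, btype="lowpass", fs=rec.fs, output="sos")
    sos_hp = signal.butter(2, low, btype="highpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(
        sos_lp, rec.data, axis=-1, padlen=_padlen(n, rec.fs, high)
    )
    # even padding keeps the level continuous at the edges so the slow
    # high-pass corner is barely excited by boundary effects
    out = signal.sosfiltfilt(
        sos_hp, out, axis=-1, padtype="even", padlen=_padlen(n, rec.fs, low)
    )
    return replace(rec, data=out)


def notch_filter(rec: EEGRecording, f0: float = 50.0, quality: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at ``f0`` (mains frequency)."""
    _check_corners(rec.fs, f0)
    b, a = signal.iirnotch(f0, quality, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=out)


def _segment_extremity(seg: np.ndarray, med: np.ndarray, mad: np.ndarray) -> float:
    """Worst robust z-score of any sample in a channels x samples segment."""
    z = np.abs(seg - med[:, None]) / mad[:, None]
    return float(z.max())


def remove_artifacts(
    rec: EEGRecording,
    amplitude_threshold_uv: float = 100.0,
    robust_z_threshold: float = 5.0,
    cap: float = 0.10,
) -> tuple[EEGRecording, PreprocessReport]:
    """Excise 1-second segments containing high-amplitude artifacts.

    A segment on the global 1-s grid is flagged when any sample exceeds the
    absolute amplitude threshold or a per-channel robust z-score threshold
    (median/MAD over the whole recording). If flagging would discard more
    than ``cap`` of the data, only the most extreme segments up to the cap
    are removed and the report carries a warning. Trial windows are
    remapped onto the shortened recording.
    """
    fs = int(round(rec.fs))
    n_seg = rec.n_samples // fs
    med = np.median(rec.data, axis=1)
    mad = np.median(np.abs(rec.data - med[:, None]), axis=1) * 1.4826
    mad = np.where(mad <= 0, np.inf, mad)

    flagged: list[tuple[float, int]] = []  # (extremity, segment index)
    for i in range(n_seg):
        seg = rec.data[:, i * fs:(i + 1) * fs]
        amp = float(np.abs(seg).max())
        zmax = _segment_extremity(seg, med, mad)
        if amp > amplitude_threshold_uv or zmax > robust_z_threshold:
            flagged.append((max(zmax, amp / amplitude_threshold_uv), i))

    warnings: list[str] = []
    max_remove = int(math.floor(cap * n_seg))
    if len(flagged) > max_remove:
        flagged.sort(reverse=True)  # keep the least-extreme flagged segments
        warnings.append(
            f"{len(flagged)} segments flagged but only {max_remove} removed "
            f"to honor the {cap:.0%} cap"
        )
        flagged = flagged[:max_remove]
    removed_idx = sorted(i for _, i in flagged)
    removed_segments = [(i * fs, (i + 1) * fs) for i in removed_idx]

    keep = np.ones(rec.n_samples, dtype=bool)
    for start, end in removed_segments:
        keep[start:end] = False
    # cumulative count of kept samples strictly before each original index
    new_pos = np.concatenate([[0], np.cumsum(keep)])
    trials = []
    for t in rec.trials:
        start = int(new_pos[t.start_sample])
        end = int(new_pos[t.end_sample])
        if end - start >= fs:
            trials.append(replace(t, start_sample=start, end_sample=end))
        else:
            warnings.append(f"trial {t.stimulus_id} shrank below 1 s and was dropped")
    out = replace(rec, data=rec.data[:, keep], trials=trials)
    report = PreprocessReport(
        removed_fraction=len(removed_idx) / n_seg if n_seg else 0.0,
        removed_segments=removed_segments,
        filter_settings={
            "amplitude_threshold_uv": amplitude_threshold_uv,
            "robust_z_threshold": robust_z_threshold,
            "cap": cap,
        },
        warnings=warnings,
    )
    return out, report


def epoch_signal(rec: EEGRecording) -> tuple[np.ndarray, pd.DataFrame]:
    """Slice each trial into non-overlapping 1-second epochs.

    Returns ``(epochs, meta)`` where ``epochs`` has shape
    (n_epochs, n_channels, fs) and ``meta`` one row per epoch with columns
    ``stimulus_id, condition, trial_index, epoch_index``. The trailing
    partial second of a trial is discarded; a trial shorter than 1 s is an
    error.
    """
    if not rec.trials:
        raise ValueError("recording has no trials to epoch")
    fs = int(round(rec.fs))
    chunks, meta = [], []
    for ti, t in enumerate(rec.trials):
        n = (t.end_sample - t.start_sample) // fs
        if n < 1:
            raise ValueError(f"trial {t.stimulus_id} shorter than 1 s")
        for k in range(n):
            s = t.start_sample + k * fs
            chunks.append(rec.data[:, s:s + fs])
            meta.append((t.stimulus_id, t.condition, ti, k))
    epochs = np.stack(chunks)
    meta_df = pd.DataFrame(
        meta, columns=["stimulus_id", "condition", "trial_index", "epoch_index"]
    )
    return epochs, meta_df


def band_variance(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Variance of ``x`` ideally band-limited to ``band``, along the last axis.

    Spectral (Parseval) estimator: the mean-removed periodogram power in
    the half-open frequency interval ``[low, high)``. Equivalent to
    brick-wall filtering followed by the N-denominator variance, with a
    flat passband so a band-limited signal keeps its full variance.
    Works on any leading shape.
    """
    _check_corners(fs, band.low, band.high)
    x = np.asarray(x, float)
    n = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = np.abs(spec) ** 2 / n**2
    # one-sided spectrum: interior bins carry the conjugate half too
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    in_band = (freqs >= band.low) & (freqs < band.high)
    return np.sum(power[..., in_band] * weights[in_band], axis=-1)


def de_feature(epoch_channel: np.ndarray, band: BandDefinition, fs: float) -> float:
    """Differential entropy of one channel-epoch in one band (nats).

    ``0.5 * ln(2 pi e sigma^2)`` with sigma^2 the band-limited variance.
    Raises :class:`DegenerateBandError` when the band variance is zero.
    """
    x = np.asarray(epoch_channel, float)
    if x.ndim != 1 or x.size < fs:
        raise ValueError("epoch must be a 1-D array of at least fs samples")
    var = float(band_variance(x, band, fs))
    if var <= 0:
        raise DegenerateBandError(f"zero variance in band {band.name}")
    return 0.5 * math.log(2 * math.pi * math.e * var)


class DifferentialEntropyExtractor(TransformerMixin, BaseEstimator):
    """Transform raw epochs into per-band differential-entropy features.

    Input ``X`` has shape (n_epochs, n_channels, n_samples); the output is
    (n_epochs, n_channels * n_bands) with channels as the outer (slow)
    index and bands as the inner one, i.e. column ``i`` holds channel
    ``i // n_bands``, band ``i % n_bands``.

    Parameters
    ----------
    bands : sequence of BandDefinition
        Analysis bands; defaults to the canonical five (delta 1-4,
        theta 4-8, alpha 8-12, beta 13-30, gamma 31-45 Hz).
    fs : float
        Sampling rate of the epochs in Hz.
    """

    def __init__(
        self,
        bands: Sequence[BandDefinition] = CANONICAL_BANDS,
        fs: float = 256.0,
    ):
        self.bands = bands
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_samples)")
        self.n_channels_ = X.shape[1]
        self.n_features_out_ = X.shape[1] * len(self.bands)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_samples)")
        per_band = []
        for band in self.bands:
            var = band_variance(X, band, self.fs)
            if np.any(var <= 0):
                raise DegenerateBandError(f"zero variance in band {band.name}")
            per_band.append(0.5 * np.log(2 * np.pi * np.e * var))
        # stack to (n_epochs, n_channels, n_bands) then flatten channel-major
        de = np.stack(per_band, axis=-1)
        return de.reshape(X.shape[0], -1)

    def feature_names(self, channel_labels: Optional[Sequence[str]] = None) -> list[str]:
        """Human-readable column names, channel-major."""
        if channel_labels is None:
            channel_labels = [f"ch{i}" for i in range(getattr(self, "n_channels_", 0))]
        return [f"{ch}_{b.name}" for ch in channel_labels for b in self.bands]


@dataclass
class EpochFeatureMatrix:
    """Epochs x (channels * bands) DE features with per-epoch labels."""

    features: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    channel_labels: tuple[str, ...]
    bands: tuple[BandDefinition, ...]
    participant_id: Optional[str] = None
    group: Optional[str] = None

    @property
    def column_map(self) -> list[tuple[str, str]]:
        return [(ch, b.name) for ch in self.channel_labels for b in self.bands]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f_{i:03d}" for i in range(self.features.shape[1])]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "label", self.labels)
        for i, c in enumerate(self.meta.columns):
            df.insert(i, c, self.meta[c].to_numpy())
        if self.participant_id is not None:
            df.insert(0, "participant_id", self.participant_id)
        if self.group is not None:
            df.insert(1, "group", self.group)
        return df


def extract_feature_matrix(
    rec: EEGRecording,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    participant_id: Optional[str] = None,
    group: Optional[str] = None,
) -> EpochFeatureMatrix:
    """Epoch a preprocessed recording and compute the DE feature matrix.

    For the canonical 14-channel montage and five bands this yields an
    epochs x 70 matrix; each epoch inherits the condition label of its
    trial. The computation is deterministic given the input.
    """
    epochs, meta = epoch_signal(rec)
    extractor = DifferentialEntropyExtractor(bands=tuple(bands), fs=rec.fs)
    features = extractor.fit(epochs).transform(epochs)
    return EpochFeatureMatrix(
        features=features,
        labels=meta["condition"].to_numpy(),
        meta=meta,
        channel_labels=rec.channel_labels,
        bands=tuple(bands),
        participant_id=participant_id,
        group=group,
    )
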
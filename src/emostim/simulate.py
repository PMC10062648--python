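"""Synthetic rating tables and EEG recordings with known ground truth.

The study design these generators emulate has no public raw data, so every
pipeline stage is exercised on simulated cohorts instead: Likert ratings
arise from a clipped-and-rounded continuous latent (grand mean + category
effect + group shift + participant effect + stimulus effect + noise), and
EEG channels are sums of band-limited Gaussian noise with per-condition
band variances, a 1/f background, and raised-cosine blink transients on
the frontal electrodes. Every planted parameter is recoverable by the
corresponding analysis stage, which is the module's core purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GroupKey, StimulusDescriptor, all_groups
from .eeg import CANONICAL_BANDS, CANONICAL_CHANNELS, EEGRecording, Trial
from .reference import recognition_reference_accuracies, validation_reference_scores

__all__ = [
    "EMOTION_CATEGORIES",
    "CATEGORY_VALENCE_STATE",
    "RatingSimConfig",
    "EEGSimConfig",
    "gen_ratings",
    "gen_eeg",
    "participant_category_means",
    "validation_reference_scores",
    "recognition_reference_accuracies",
]

EMOTION_CATEGORIES = (
    "disgust", "anger", "fear", "sadness",
    "neutrality", "tenderness", "amusement", "joy",
)

#: collapse of the eight discrete categories onto three valence states
CATEGORY_VALENCE_STATE = {
    "disgust": "negative", "anger": "negative", "fear": "negative", "sadness": "negative",
    "neutrality": "neutral",
    "tenderness": "positive", "amusement": "positive", "joy": "positive",
}

# Published cohort-level category means (valence / arousal on the 1-9 scale)
# and female-minus-male shifts; these are the generator's default conditions
# so that simulated cohorts reproduce the qualitative pattern of the study
# population (neutral arousal ~2.2, emotional arousal ~6.2, female > male).
_DEFAULT_VALENCE = {
    "disgust": 2.29, "anger": 2.68, "fear": 2.38, "sadness": 2.22,
    "neutrality": 4.86, "tenderness": 6.39, "amusement": 6.56, "joy": 6.47,
}
_DEFAULT_AROUSAL = {
    "disgust": 6.38, "anger": 6.08, "fear": 6.21, "sadness": 6.14,
    "neutrality": 2.21, "tenderness": 6.47, "amusement": 6.18, "joy": 6.26,
}
_DEFAULT_GENDER_SHIFT_VALENCE = {
    "disgust": -0.61, "anger": 0.34, "fear": 0.27, "sadness": -0.11,
    "neutrality": 0.26, "tenderness": 0.34, "amusement": 0.16, "joy": 0.25,
}
_DEFAULT_GENDER_SHIFT_AROUSAL = {
    "disgust": 0.15, "anger": 0.06, "fear": 0.11, "sadness": 0.20,
    "neutrality": 0.26, "tenderness": 0.67, "amusement": 0.21, "joy": 0.21,
}


@dataclass
class RatingSimConfig:
    """Conditions of the simulated rating cohort.

    ``gender_shift_*`` maps a category to the female-minus-male latent
    difference; ``age_shift_*`` maps (age_band, category) to an additive
    latent offset. ``hit_gap`` is the mean latent advantage of the target
    emotional state over the non-target states on the emotional-evaluation
    scale; each stimulus draws its own gap from
    ``N(hit_gap, hit_gap_sd^2)``, which is what spreads hit rates across
    stimuli (the defaults land them roughly in the 60-100% range seen in
    validated stimulus sets) and gives the success index something to
    rank.
    """

    n_per_cell: int = 20
    category_valence: dict = field(default_factory=lambda: dict(_DEFAULT_VALENCE))
    category_arousal: dict = field(default_factory=lambda: dict(_DEFAULT_AROUSAL))
    gender_shift_valence: dict = field(
        default_factory=lambda: dict(_DEFAULT_GENDER_SHIFT_VALENCE)
    )
    gender_shift_arousal: dict = field(
        default_factory=lambda: dict(_DEFAULT_GENDER_SHIFT_AROUSAL)
    )
    age_shift_valence: dict = field(default_factory=dict)
    age_shift_arousal: dict = field(default_factory=dict)
    target_intensity_mean: float = 7.2
    hit_gap: float = 2.2
    hit_gap_sd: float = 0.5
    participant_sd: float = 0.5
    stimulus_sd: float = 0.3
    noise_sd: float = 0.8
    include_extended_sam: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_per_cell",):
            if self.n_per_cell < 2:
                raise ValueError("n_per_cell must be >= 2")
        for sd in (self.participant_sd, self.stimulus_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


def _clip_round(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 1, 9).astype(int)


def _category_of(stimulus: tuple[str, str] | StimulusDescriptor) -> tuple[str, str]:
    """(stimulus_id, category) from either a pair or a descriptor."""
    if isinstance(stimulus, StimulusDescriptor):
        return stimulus.stimulus_id, stimulus.valence
    sid, cat = stimulus
    return str(sid), str(cat)


def _state_mean(table: dict, category: str) -> float:
    """Latent mean for a category; valence-state names average their members."""
    if category in table:
        return float(table[category])
    members = [c for c, s in CATEGORY_VALENCE_STATE.items() if s == category]
    if not members:
        raise ValueError(f"unknown emotion category {category!r}")
    return float(np.mean([table[c] for c in members]))


def gen_ratings(
    cfg: RatingSimConfig,
    stimuli: Sequence[tuple[str, str] | StimulusDescriptor],
    groups: Optional[Sequence[GroupKey]] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a long-format rating table.

    ``stimuli`` is a sequence of descriptors or (stimulus_id, category)
    pairs, where the category is one of the eight discrete emotions or
    directly a valence state. Every participant of every group rates every
    stimulus on both scales; ratings are the clipped, rounded latents.
    Deterministic for a fixed config and seed.
    """
    if not stimuli:
        raise ValueError("need at least one stimulus")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    groups = list(groups) if groups is not None else all_groups()
    stim = [_category_of(s) for s in stimuli]

    # stimulus effects, one per (stimulus, scale), plus a per-stimulus gap
    s_eff = {
        sid: rng.normal(0, cfg.stimulus_sd, size=3)  # valence, arousal, intensity
        for sid, _ in stim
    }
    s_gap = {sid: rng.normal(cfg.hit_gap, cfg.hit_gap_sd) for sid, _ in stim}
    rows = []
    for group in groups:
        sign = +0.5 if group.gender == "female" else -0.5
        for i in range(cfg.n_per_cell):
            pid = f"{group.gender[0]}{group.age_code}_{i:03d}"
            p_eff = rng.normal(0, cfg.participant_sd, size=3)
            for sid, cat in stim:
                state = CATEGORY_VALENCE_STATE.get(cat, cat)
                lat_v = (
                    _state_mean(cfg.category_valence, cat)
                    + sign * cfg.gender_shift_valence.get(cat, 0.0)
                    + cfg.age_shift_valence.get((group.age_band, cat), 0.0)
                    + p_eff[0] + s_eff[sid][0] + rng.normal(0, cfg.noise_sd)
                )
                lat_a = (
                    _state_mean(cfg.category_arousal, cat)
                    + sign * cfg.gender_shift_arousal.get(cat, 0.0)
                    + cfg.age_shift_arousal.get((group.age_band, cat), 0.0)
                    + p_eff[1] + s_eff[sid][1] + rng.normal(0, cfg.noise_sd)
                )
                lat_target = (
                    cfg.target_intensity_mean
                    + p_eff[2] + s_eff[sid][2] + rng.normal(0, cfg.noise_sd)
                )
                ee = {}
                for v in ("positive", "neutral", "negative"):
                    if v == state:
                        ee[v] = lat_target
                    else:
                        ee[v] = lat_target - s_gap[sid] + rng.normal(0, cfg.noise_sd)
                row = {
                    "participant_id": pid,
                    "gender": group.gender,
                    "age_band": group.age_band,
                    "stimulus_id": sid,
                    "category": cat,
                    "ee_positive": int(_clip_round(np.array([ee["positive"]]))[0]),
                    "ee_neutral": int(_clip_round(np.array([ee["neutral"]]))[0]),
                    "ee_negative": int(_clip_round(np.array([ee["negative"]]))[0]),
                    "sam_valence": int(_clip_round(np.array([lat_v]))[0]),
                    "sam_arousal": int(_clip_round(np.array([lat_a]))[0]),
                }
                if cfg.include_extended_sam:
                    for extra in ("sam_dominance", "sam_liking", "sam_familiarity"):
                        row[extra] = int(_clip_round(rng.normal(5.0, 1.0, size=1))[0])
                else:
                    row.update(
                        {"sam_dominance": None, "sam_liking": None, "sam_familiarity": None}
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def participant_category_means(ratings: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Average ``dv`` per participant and emotion category.

    This is the aggregation feeding the mixed ANOVA: one value per
    (participant, category), with the group labels carried along.
    """
    cols = ["participant_id", "gender", "age_band", "category"]
    out = ratings.groupby(cols, observed=True)[dv].mean().reset_index()
    return out.rename(columns={dv: "value"})


# ---------------------------------------------------------------------------
# EEG


def _default_band_power() -> dict:
    base = {"delta": 4.0, "theta": 2.0, "alpha": 2.0, "beta": 1.0, "gamma": 0.5}
    scale = {"positive": 2.0, "neutral": 1.0, "negative": 1.5}
    return {
        cond: {b: (v * s if b == "gamma" else v) for b, v in base.items()}
        for cond, s in scale.items()
    }


@dataclass
class EEGSimConfig:
    """Conditions of the simulated EEG recordings.

    ``band_power`` maps condition -> band name -> variance (uV^2) of the
    band-limited Gaussian component; the per-condition gamma offset is the
    planted, analytically recoverable effect. Blink transients are
    raised-cosine pulses on AF3/AF4 (half amplitude on F3/F4).
    """

    n_channels: int = 14
    fs: float = 256.0
    trial_length_s: tuple[int, int] = (91, 229)
    band_power: dict = field(default_factory=_default_band_power)
    background_exponent: float = 1.0
    background_var: float = 0.5
    blink_rate_per_min: float = 2.0
    blink_amplitude_uv: float = 400.0
    blink_duration_s: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_channels != len(CANONICAL_CHANNELS):
            raise ValueError("the montage has exactly 14 channels")
        if self.fs <= 2 * 45:
            raise ValueError("sampling rate must exceed twice the highest band edge")
        lo, hi = self.trial_length_s
        if not 1 <= lo <= hi:
            raise ValueError("invalid trial length range")
        for cond, bands in self.band_power.items():
            for b, v in bands.items():
                if v <= 0:
                    raise ValueError(f"band variance must be positive ({cond}/{b})")


def _band_limited_noise(
    rng: np.random.Generator, n: int, low: float, high: float, fs: float, var: float
) -> np.ndarray:
    """Gaussian noise ideally band-limited to [low, high) with exact variance.

    Spectral construction (zero all out-of-band bins of white noise), so
    the signal has no filter edge transients and its variance is exactly
    the analytic value used by the DE tests.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs >= high)] = 0.0
    x = np.fft.irfft(spec, n)
    x = x - x.mean()
    return x * np.sqrt(var) / x.std()


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, var: float) -> np.ndarray:
    """1/f^exponent background via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]
    spec *= freqs ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x = x - x.mean()
    sd = x.std()
    return x * (np.sqrt(var) / sd if sd > 0 else 0.0)


def _blink_pulse(fs: float, duration_s: float, amplitude: float) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 2)
    t = np.linspace(0, 1, n)
    return amplitude * 0.5 * (1 - np.cos(2 * np.pi * t))


def gen_eeg(
    cfg: EEGSimConfig,
    trial_conditions: Sequence[tuple[str, str]],
    seed: Optional[int] = None,
) -> tuple[EEGRecording, pd.DataFrame]:
    """Simulate a labelled multichannel recording.

    ``trial_conditions`` is a sequence of (stimulus_id, condition) pairs;
    trials are laid back-to-back with lengths drawn uniformly from the
    configured range. Returns the recording and a ground-truth table of
    injected blink spans (``start_sample, end_sample, channel``).
    """
    if not trial_conditions:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.fs
    lo, hi = cfg.trial_length_s
    lengths = rng.integers(lo, hi + 1, size=len(trial_conditions))
    n_total = int(lengths.sum() * fs)

    data = np.zeros((cfg.n_channels, n_total))
    trials: list[Trial] = []
    start = 0
    for (sid, cond), dur in zip(trial_conditions, lengths):
        n = int(dur * fs)
        band_vars = cfg.band_power[cond]
        for ch in range(cfg.n_channels):
            x = np.zeros(n)
            for band in CANONICAL_BANDS:
                if band.name in band_vars:
                    x += _band_limited_noise(
                        rng, n, band.low, band.high, fs, band_vars[band.name]
                    )
            if cfg.background_var > 0:
                x += _pink_noise(rng, n, cfg.background_exponent, cfg.background_var)
            data[ch, start:start + n] = x
        trials.append(
            Trial(stimulus_id=sid, condition=cond, start_sample=start, end_sample=start + n)
        )
        start += n

    # blink transients on the frontal channels
    truth_rows = []
    if cfg.blink_rate_per_min > 0 and cfg.blink_amplitude_uv > 0:
        pulse = _blink_pulse(fs, cfg.blink_duration_s, cfg.blink_amplitude_uv)
        n_blinks = rng.poisson(cfg.blink_rate_per_min * n_total / fs / 60.0)
        frontal = {"AF3": 1.0, "AF4": 1.0, "F3": 0.5, "F4": 0.5}
        starts = np.sort(rng.integers(0, max(n_total - pulse.size, 1), size=n_blinks))
        for s0 in starts:
            for label, gain in frontal.items():
                ch = CANONICAL_CHANNELS.index(label)
                data[ch, s0:s0 + pulse.size] += gain * pulse
            truth_rows.append(
                {"start_sample": int(s0), "end_sample": int(s0 + pulse.size)}
            )
    truth = pd.DataFrame(truth_rows, columns=["start_sample", "end_sample"])
    rec = EEGRecording(
        data=data, fs=fs, channel_labels=CANONICAL_CHANNELS, trials=trials
    )
    return rec, truth
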
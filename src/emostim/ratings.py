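"""Stimulus-validation statistics for emotional rating tables.

The scoring logic follows the classical success-index procedure for
emotion-eliciting stimuli: for each stimulus, the *intensity* is the mean
target-state rating on the emotional-evaluation scale, the *hit rate* is
the fraction of raters whose target-state rating exceeds every other state
by at least one scale point, and the *success index* is the sum of the two
within-pool z-scores. Group differences are tested with t-tests on
intensities and Yates-corrected chi-square tests on hit counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import VALENCES, parse_stimulus_filename

_EE_COLUMN = {"positive": "ee_positive", "neutral": "ee_neutral", "negative": "ee_negative"}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation-layer convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class StimulusScore:
    stimulus_id: str
    pool_id: str
    intensity: DescriptiveStats
    hit_rate: float
    z_intensity: float
    z_hit: float

    @property
    def success_index(self) -> float:
        return self.z_intensity + self.z_hit


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group-1 hit/miss, (c, d) = group-2 hit/miss."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str


class DegeneratePoolError(ValueError):
    """A scoring pool has zero variance in intensity or hit rate."""


def compute_intensity(records: pd.DataFrame, target: str) -> DescriptiveStats:
    """Mean and sample SD of the target-state rating for one stimulus."""
    if target not in _EE_COLUMN:
        raise ValueError(f"target must be one of {VALENCES}")
    vals = pd.to_numeric(records[_EE_COLUMN[target]], errors="raise").dropna().to_numpy(float)
    if vals.size < 2:
        raise ValueError("need at least 2 complete ratings")
    return DescriptiveStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=vals.size)


def compute_hit_rate(records: pd.DataFrame, target: str) -> float:
    """Fraction of raters with target rating >= every other rating + 1.

    An exact tie with any non-target state is a miss.
    """
    if target not in _EE_COLUMN:
        raise ValueError(f"target must be one of {VALENCES}")
    cols = [_EE_COLUMN[v] for v in VALENCES]
    complete = records.dropna(subset=cols)
    if complete.empty:
        raise ValueError("no complete emotional-evaluation triples")
    tgt = complete[_EE_COLUMN[target]].to_numpy(float)
    others = complete[[c for c in cols if c != _EE_COLUMN[target]]].to_numpy(float)
    hits = (tgt[:, None] >= others + 1).all(axis=1)
    return float(hits.mean())


def compute_success_index(
    pool: Mapping[str, tuple[float, float]],
    pool_id: str = "",
    intensity_stats: Optional[Mapping[str, DescriptiveStats]] = None,
) -> list[StimulusScore]:
    """Success index for every stimulus in one scoring pool.

    ``pool`` maps stimulus_id to (intensity mean, hit rate). Z-scores use
    the population (N-denominator) SD within the pool, so they sum to zero
    and the success indices do too. A zero-variance series raises
    :class:`DegeneratePoolError`.
    """
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 stimuli")
    ids = list(pool)
    intens = np.array([pool[s][0] for s in ids], float)
    hits = np.array([pool[s][1] for s in ids], float)
    for name, series in (("intensity", intens), ("hit rate", hits)):
        if series.std() == 0:
            raise DegeneratePoolError(f"pool {pool_id or '<unnamed>'}: zero {name} variance")
    z_i = (intens - intens.mean()) / intens.std()
    z_h = (hits - hits.mean()) / hits.std()
    scores = []
    for sid, zi, zh, m in zip(ids, z_i, z_h, intens):
        ds = (
            intensity_stats[sid]
            if intensity_stats is not None
            else DescriptiveStats(mean=float(m), sd=0.0, n=1)
        )
        scores.append(
            StimulusScore(
                stimulus_id=sid,
                pool_id=pool_id,
                intensity=ds,
                hit_rate=float(pool[sid][1]),
                z_intensity=float(zi),
                z_hit=float(zh),
            )
        )
    return scores


def score_ratings(
    ratings: pd.DataFrame,
    pool_by: Sequence[str] = ("gender", "age_band"),
) -> pd.DataFrame:
    """Score every stimulus in a rating table within (group x valence) pools.

    The target state of each stimulus is its name's valence. Returns one
    row per (pool, stimulus) with intensity M/SD, hit rate, z-scores and
    success index.
    """
    rows = []
    for keys, pool_df in ratings.groupby(list(pool_by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for valence in VALENCES:
            stim_ids = [
                s for s in pool_df["stimulus_id"].unique()
                if parse_stimulus_filename(s + ".MP4").valence == valence
            ]
            if len(stim_ids) < 2:
                continue
            pool, stats_map = {}, {}
            for sid in sorted(stim_ids):
                recs = pool_df[pool_df["stimulus_id"] == sid]
                ds = compute_intensity(recs, valence)
                pool[sid] = (ds.mean, compute_hit_rate(recs, valence))
                stats_map[sid] = ds
            pool_id = "_".join(str(k) for k in keys) + f"_{valence}"
            for sc in compute_success_index(pool, pool_id, stats_map):
                rows.append(
                    {
                        "stimulus_id": sc.stimulus_id,
                        "pool_id": sc.pool_id,
                        "valence": valence,
                        **dict(zip(pool_by, keys)),
                        "intensity_m": sc.intensity.mean,
                        "intensity_sd": sc.intensity.sd,
                        "hit_rate": sc.hit_rate,
                        "z_intensity": sc.z_intensity,
                        "z_hit": sc.z_hit,
                        "success_index": sc.success_index,
                    }
                )
    return pd.DataFrame(rows)


def select_stimuli(scores: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Top-``k`` stimuli by success index within every pool.

    Ties break by higher hit rate, then higher intensity mean, then
    lexicographic stimulus id. Raises on pools with fewer than ``k``
    candidates.
    """
    required = {"pool_id", "stimulus_id", "success_index", "hit_rate", "intensity_m"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    out = []
    for pool_id, grp in scores.groupby("pool_id"):
        if len(grp) < k:
            raise ValueError(f"pool {pool_id!r} has only {len(grp)} candidates, need {k}")
        ranked = grp.sort_values(
            by=["success_index", "hit_rate", "intensity_m", "stimulus_id"],
            ascending=[False, False, False, True],
            kind="mergesort",
        )
        out.append(ranked.head(k))
    return pd.concat(out, ignore_index=True)


def hits_from_rate(rate: float, n: int) -> int:
    """Reconstruct a hit count from a proportion (or percentage) and n."""
    if rate > 1:
        rate = rate / 100.0
    return int(math.floor(rate * n + 0.5))


def yates_chi_square(table: ContingencyTable2x2, correction: bool = True) -> TestResult:
    """Chi-square test of a 2x2 table, Yates-corrected by default.

    ``chi2 = N * max(|ad - bc| - N/2, 0)^2 / ((a+b)(c+d)(a+c)(b+d))``;
    the clamp at zero makes near-null tables report exactly 0. A zero
    margin leaves the statistic undefined and raises ``ValueError``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2, 0.0)
    chi2 = n * num**2 / math.prod(margins)
    return TestResult(
        statistic=float(chi2),
        df=1.0,
        p=float(stats.chi2.sf(chi2, 1)),
        kind="chi_square_yates" if correction else "chi_square_pearson",
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], kind: str = "independent_pooled"
) -> TestResult:
    """Two-sided t-test: pooled-variance, Welch, or paired."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if kind == "paired":
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if d.std(ddof=1) == 0:
            if d.mean() == 0:  # identical samples: t is 0 by convention
                return TestResult(statistic=0.0, df=float(x.size - 1), p=1.0, kind=kind)
            raise ValueError("constant nonzero paired difference: t undefined")
        res = stats.ttest_rel(x, y)
        df = x.size - 1
    elif kind in ("independent_pooled", "welch"):
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ValueError("zero variance in both samples")
        res = stats.ttest_ind(x, y, equal_var=(kind == "independent_pooled"))
        df = float(res.df)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return TestResult(statistic=float(res.statistic), df=float(df), p=float(res.pvalue), kind=kind)


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, kind: str = "independent_pooled"
) -> TestResult:
    """Pooled or Welch t-test from summary statistics."""
    res = stats.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=(kind == "independent_pooled")
    )
    df = n1 + n2 - 2 if kind == "independent_pooled" else float(res.df)
    return TestResult(statistic=float(res.statistic), df=float(df), p=float(res.pvalue), kind=kind)


def bonferroni_adjust(p_values: Iterable[float]) -> list[float]:
    """Multiply each p by the family size, capped at 1 (order-preserving)."""
    ps = [float(p) for p in p_values]
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def normality_check(values: Sequence[float], alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality screen used before the parametric analyses."""
    vals = np.asarray(values, float)
    if vals.size < 3:
        raise ValueError("need at least 3 observations")
    if vals.std() == 0:
        raise ValueError("constant input")
    stat, p = stats.shapiro(vals)
    return {"statistic": float(stat), "p": float(p), "pass": bool(p >= alpha)}
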
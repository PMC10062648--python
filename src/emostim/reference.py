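"""Published reference values bundled as regression fixtures.

Two small tables from the short-video stimulus database this package
analyses are shipped verbatim:

* the emotional-evaluation results of the 20-24-year-old male and female
  validation cohorts (n = 20 each): per-stimulus intensity mean/SD, hit
  rate (%), the between-gender paired t and Yates chi-square statistics,
  and the published success indices;
* the per-group EEG emotion-recognition accuracies by stimulus source
  (specific short videos, comparison short videos, film clips).

They serve as ground truth for regression tests: recomputing the success
indices and chi-squares from the printed inputs must reproduce the
printed outputs.
"""

from __future__ import annotations

import pandas as pd

# stimulus, male (M, SD, hit%), female (M, SD, hit%), t, chi2, SI male, SI female
_VALIDATION_ROWS = [
    ("positive_1_1_1", 7.55, 1.20, 85.0, 6.55, 1.83, 65.0, 1.99, 1.20, 1.34, -2.47),
    ("positive_1_1_2", 7.80, 1.21, 80.0, 6.40, 1.11, 70.0, 3.71, 0.13, 1.05, -2.32),
    ("positive_1_1_3", 7.80, 1.03, 90.0, 6.70, 1.42, 85.0, 2.74, 0.00, 2.40, -0.61),
    ("positive_2_1_1", 6.80, 1.96, 80.0, 7.80, 0.75, 100.0, -2.07, 2.50, -0.48, 2.43),
    ("positive_2_1_2", 7.35, 1.15, 90.0, 7.75, 0.94, 100.0, -1.17, 0.53, 1.72, 2.35),
    ("positive_2_1_3", 6.95, 1.53, 80.0, 7.20, 1.17, 100.0, -0.57, 2.50, -0.25, 1.43),
    ("positive_film_1", 5.65, 2.22, 75.0, 6.20, 1.63, 90.0, -0.87, 0.96, -2.92, -1.04),
    ("positive_film_2", 6.65, 1.35, 85.0, 6.10, 1.64, 95.0, 1.13, 0.28, -0.03, -0.80),
    ("positive_film_3", 6.60, 1.24, 65.0, 7.20, 1.63, 95.0, -1.28, 3.91, -2.82, 1.03),
    ("neutral_1_1_1", 7.90, 1.51, 95.0, 7.15, 1.62, 95.0, 1.47, 0.00, 2.21, 0.24),
    ("neutral_1_1_2", 7.55, 1.28, 90.0, 7.25, 1.30, 95.0, 0.72, 0.00, 1.41, 0.44),
    ("neutral_1_1_3", 8.00, 1.10, 100.0, 6.40, 2.08, 95.0, 2.96, 0.00, 2.70, -1.25),
    ("neutral_2_1_1", 7.05, 1.66, 70.0, 8.05, 0.74, 100.0, -2.40, 4.90, -0.68, 2.60),
    ("neutral_2_1_2", 6.95, 1.99, 80.0, 7.25, 1.34, 100.0, -0.55, 2.50, -0.07, 1.00),
    ("neutral_2_1_3", 7.15, 1.28, 85.0, 7.25, 1.04, 100.0, -0.26, 1.44, 0.55, 1.00),
    ("neutral_film_1", 6.15, 2.29, 60.0, 6.30, 0.95, 70.0, -0.26, 0.11, -2.53, -4.21),
    ("neutral_film_2", 5.30, 2.47, 60.0, 6.80, 1.57, 90.0, -2.23, 3.33, -3.58, -1.01),
    ("neutral_film_3", 6.70, 1.71, 85.0, 7.35, 1.19, 100.0, -1.36, 1.44, -0.01, 1.20),
    ("negative_1_1_1", 7.85, 0.96, 100.0, 7.65, 1.06, 95.0, 0.61, 0.00, 1.62, -0.56),
    ("negative_1_1_2", 8.75, 0.54, 95.0, 7.90, 0.77, 100.0, 3.96, 0.00, 2.07, 1.94),
    ("negative_1_1_3", 7.70, 1.10, 100.0, 6.90, 1.26, 95.0, 2.08, 0.00, 1.48, -2.05),
    ("negative_2_1_1", 6.85, 1.31, 95.0, 8.10, 0.94, 100.0, -3.37, 0.00, 0.31, 2.34),
    ("negative_2_1_2", 7.85, 1.46, 95.0, 8.25, 1.04, 100.0, -0.97, 0.00, 1.24, 2.64),
    ("negative_2_1_3", 7.10, 1.14, 90.0, 7.55, 0.97, 100.0, -1.31, 0.53, 0.16, 1.25),
    ("negative_film_1", 4.85, 2.50, 60.0, 7.20, 1.78, 95.0, -3.34, 5.16, -4.20, -1.46),
    ("negative_film_2", 6.00, 2.07, 70.0, 7.00, 1.48, 95.0, -1.71, 2.77, -2.37, -1.85),
    ("negative_film_3", 7.00, 1.41, 85.0, 6.80, 1.17, 95.0, 0.48, 0.28, -0.31, -2.25),
]

#: group size behind each hit-rate percentage in the validation cohorts
VALIDATION_GROUP_N = 20


def validation_reference_scores() -> pd.DataFrame:
    """The published per-stimulus validation table for the 20-24 cohorts.

    Columns: ``stimulus_id, valence``, male/female ``intensity_m,
    intensity_sd, hit_rate_pct``, the published ``t_value`` and
    ``chi_square`` statistics, and the published ``success_index`` per
    gender. Hit rates are percentages of n = 20 raters per gender.
    """
    df = pd.DataFrame(
        _VALIDATION_ROWS,
        columns=[
            "stimulus_id",
            "male_intensity_m", "male_intensity_sd", "male_hit_rate_pct",
            "female_intensity_m", "female_intensity_sd", "female_hit_rate_pct",
            "t_value", "chi_square",
            "male_success_index", "female_success_index",
        ],
    )
    df.insert(1, "valence", df["stimulus_id"].str.split("_").str[0])
    return df


_ACCURACY_ROWS = [
    ("gender", "20-24 male", 96.12, 91.22, 84.58),
    ("gender", "20-24 female", 87.28, 83.87, 76.82),
    ("age", "20-24 male", 96.57, 90.05, 85.43),
    ("age", "30-34 male", 90.24, 87.32, 81.67),
    ("age_gender", "20-24 male", 95.18, 89.81, 86.25),
    ("age_gender", "30-34 female", 89.41, 80.56, 72.34),
    ("specific_random", "25-29 male", 92.18, 89.79, 81.65),
    ("specific_random", "25-29 female", 84.16, 78.33, 80.19),
]


def recognition_reference_accuracies() -> pd.DataFrame:
    """Published EEG emotion-recognition accuracies (%) per participant
    group and stimulus source (specific / comparison short videos, film
    clips)."""
    return pd.DataFrame(
        _ACCURACY_ROWS,
        columns=["influence_factor", "participants", "specific", "comparison", "film"],
    )
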
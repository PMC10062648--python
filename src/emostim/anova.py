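"""Three-way mixed (split-plot) ANOVA and follow-up simple effects.

The design crossed here has one or two between-subject factors (age band,
gender) and one within-subject factor (emotion category): every subject
supplies one averaged rating per category. Between-subject effects are
tested against the subjects-within-groups mean square; effects involving
the within factor are tested against the category-by-subjects-within-
groups mean square. Effect sizes are partial eta squared,
``SS_effect / (SS_effect + SS_error_of_that_effect)``.

Sums of squares come from Type-III OLS fits with sum-to-zero contrasts
(the convention of the major commercial ANOVA packages), which coincides
with the classical split-plot decomposition on balanced data and remains
well-defined on unbalanced complete designs.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .ratings import bonferroni_adjust


def _validate_design(
    data: pd.DataFrame, dv: str, subject: str, between: Sequence[str], within: str
) -> None:
    counts = data.groupby([subject, within], observed=True)[dv].count().unstack(fill_value=0)
    if (counts != 1).any().any():
        bad = counts.index[(counts != 1).any(axis=1)][0]
        raise ValueError(f"subject {bad!r} lacks exactly one value per {within} level")
    cell_sizes = data.groupby(list(between), observed=True)[subject].nunique()
    if (cell_sizes < 2).any():
        raise ValueError("every between-subject cell needs at least 2 subjects")
    group_per_subject = data.groupby(subject, observed=True)[list(between)].nunique()
    if (group_per_subject != 1).any().any():
        raise ValueError("a subject appears in more than one between-subject cell")


def _f_row(ss: float, df: float, ss_err: float, df_err: float) -> tuple[float, float, float]:
    """F, p and partial eta squared with the all-equal-data convention F=0, p=1."""
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err <= 0:
        return 0.0, 1.0, 0.0
    f = (ss / df) / ms_err
    p = float(stats.f.sf(f, df, df_err))
    pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    return float(f), p, float(pes)


def mixed_anova_3way(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: Sequence[str] = ("age_band", "gender"),
    within: str = "category",
) -> pd.DataFrame:
    """Split-plot ANOVA with one or two between factors and one within factor.

    ``data`` is long format with one row per (subject, within-level).
    Returns one row per effect with columns
    ``effect, ss, df_num, df_den, F, p, partial_eta2``, between-subject
    effects first. Error-term rows (``subjects``, ``category:subjects``)
    are included for transparency with F and p set to NaN.
    """
    between = list(between)
    if not 1 <= len(between) <= 2:
        raise ValueError("between must name one or two factors")
    _validate_design(data, dv, subject, between, within)

    names = {dv: "Y", subject: "S", within: "W"}
    for i, b in enumerate(between):
        names[b] = f"B{i}"
    df = data[[dv, subject, within, *between]].rename(columns=names).copy()
    for col in ("S", "W", *[f"B{i}" for i in range(len(between))]):
        df[col] = df[col].astype(str)

    k = df["W"].nunique()
    n_subj = df["S"].nunique()
    b_terms = [f"C(B{i}, Sum)" for i in range(len(between))]
    between_formula = " * ".join(b_terms)

    # sums of squares below float noise (relative to the total) are zero;
    # this makes all-equal data report SS 0, F 0, p 1 instead of noise
    total_ss = float(((df["Y"] - df["Y"].mean()) ** 2).sum())
    eps = 1e-12 * max(total_ss, 1.0)

    def clean(ss: float) -> float:
        return 0.0 if (not np.isfinite(ss) or ss < eps) else float(ss)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank warnings on degenerate data

        # --- between-subject stratum: ANOVA of subject means, SS rescaled by k
        subj = df.groupby(
            ["S", *[f"B{i}" for i in range(len(between))]], observed=True
        )["Y"].mean()
        subj = subj.reset_index()
        fit_b = ols(f"Y ~ {between_formula}", data=subj).fit()
        tab_b = anova_lm(fit_b, typ=3)
        n_cells = int(np.prod([subj[f"B{i}"].nunique() for i in range(len(between))]))
        ss_subj_err = clean(float(tab_b.loc["Residual", "sum_sq"]) * k)
        df_subj_err = n_subj - n_cells

        # --- within-subject stratum: ANOVA of per-subject deviations
        df["Y_dev"] = df["Y"] - df.groupby("S", observed=True)["Y"].transform("mean")
        fit_w = ols(f"Y_dev ~ C(W, Sum) * {between_formula}", data=df).fit()
        tab_w = anova_lm(fit_w, typ=3)
        df_within_err = df_subj_err * (k - 1)
        ss_within_err = clean(float(tab_w.loc["Residual", "sum_sq"]))

    def pretty(term: str) -> str:
        out = term
        for i, b in enumerate(between):
            out = out.replace(f"C(B{i}, Sum)", b)
        return out.replace("C(W, Sum)", within).replace(":", ":")

    rows = []
    for term in tab_b.index:
        if term in ("Intercept", "Residual"):
            continue
        ss = clean(float(tab_b.loc[term, "sum_sq"]) * k)
        dfn = float(tab_b.loc[term, "df"])
        f, p, pes = _f_row(ss, dfn, ss_subj_err, df_subj_err)
        rows.append((pretty(term), ss, dfn, float(df_subj_err), f, p, pes))
    rows.append(("subjects", ss_subj_err, float(df_subj_err), np.nan, np.nan, np.nan, np.nan))
    for term in tab_w.index:
        if term in ("Intercept", "Residual") or "C(W, Sum)" not in term:
            continue
        ss = clean(float(tab_w.loc[term, "sum_sq"]))
        dfn = float(tab_w.loc[term, "df"])
        f, p, pes = _f_row(ss, dfn, ss_within_err, df_within_err)
        rows.append((pretty(term), ss, dfn, float(df_within_err), f, p, pes))
    rows.append(
        (f"{within}:subjects", ss_within_err, float(df_within_err), np.nan, np.nan, np.nan, np.nan)
    )
    return pd.DataFrame(
        rows, columns=["effect", "ss", "df_num", "df_den", "F", "p", "partial_eta2"]
    )


def simple_effects(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    effect: str,
    by: Sequence[str],
    between: Sequence[str] = ("age_band", "gender"),
    within: str = "category",
    anova: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise comparisons of ``effect`` within slices.

    ``by`` names the factor(s) whose level combinations define the slices
    (the interaction context). Each comparison uses the omnibus error term
    appropriate to the effect factor: the within-stratum error when
    ``effect`` is the within factor, the subjects-within-groups error
    otherwise. P-values are adjusted within each slice's family.
    """
    by = list(by)
    if anova is None:
        anova = mixed_anova_3way(data, dv, subject, between=between, within=within)
    err_label = f"{within}:subjects" if effect == within else "subjects"
    err = anova.loc[anova["effect"] == err_label].iloc[0]
    ms_err = err["ss"] / err["df_num"] if err["df_num"] > 0 else 0.0
    df_err = float(err["df_num"])

    rows = []
    for slice_keys, sl in data.groupby(by, observed=True):
        if not isinstance(slice_keys, tuple):
            slice_keys = (slice_keys,)
        cells = sl.groupby(effect, observed=True)[dv].agg(["mean", "count"])
        levels = sorted(cells.index)
        if len(levels) < 2:
            raise ValueError(f"slice {slice_keys} has fewer than 2 {effect} levels")
        raw = []
        for i, la in enumerate(levels):
            for lb in levels[i + 1:]:
                diff = cells.loc[la, "mean"] - cells.loc[lb, "mean"]
                na, nb = cells.loc[la, "count"], cells.loc[lb, "count"]
                if ms_err > 0:
                    se = np.sqrt(ms_err * (1 / na + 1 / nb))
                    t = diff / se
                    p = 2 * float(stats.t.sf(abs(t), df_err))
                else:
                    t, p = 0.0, 1.0
                raw.append((la, lb, float(diff), float(t), p, int(na), int(nb)))
        adj = bonferroni_adjust([r[4] for r in raw])
        for (la, lb, diff, t, p, na, nb), pa in zip(raw, adj):
            rows.append(
                {
                    **dict(zip(by, slice_keys)),
                    "level_a": la,
                    "level_b": lb,
                    "mean_diff": diff,
                    "t": t,
                    "df": df_err,
                    "p_raw": p,
                    "p_adjusted": pa,
                    "n_a": na,
                    "n_b": nb,
                }
            )
    return pd.DataFrame(rows)
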
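"""Group-level inference for the subject x group x cue x position amplitude table.

Implements the balanced mixed-design ANOVA (one between-subject factor with
g levels, two within-subject factors: cue with 3 levels and position with
2) with generalized eta squared, follow-up t-tests with Cohen's d, and the
a priori power computation for two independent means via the noncentral t
distribution.

The ANOVA partitions each within-subject stratum separately (a standard
univariate mixed-model decomposition): subject means carry the Group
effect over the S(G) error, cue profiles carry Cue and Group x Cue over
C x S(G), position profiles carry Position and Group x Position over
P x S(G), and the within-subject interaction residual carries the
remaining effects over C x P x S(G).  Generalized eta squared follows the
observed-effect convention: SS_effect / (SS_effect + sum of all
subject-related error SS).  Sphericity corrections are not applied
(uncorrected df are reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

DV = "mean_amplitude_uv"


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def _pivot_cells(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: tuple[str, str],
    subject: str,
) -> tuple[np.ndarray, np.ndarray, list, list, list]:
    """Return Y[subject, a, b], group index per subject, and level lists."""
    w1, w2 = within
    a_levels = sorted(table[w1].unique())
    b_levels = sorted(table[w2].unique())
    subjects = sorted(table[subject].unique())
    groups_of = table.drop_duplicates(subject).set_index(subject)[between]
    g_levels = sorted(groups_of.unique())
    if len(g_levels) < 2:
        raise DataError("between factor needs >= 2 levels")

    pivot = table.pivot_table(
        index=subject, columns=[w1, w2], values=dv, aggfunc="first", sort=True
    )
    expected = len(a_levels) * len(b_levels)
    if pivot.shape[1] != expected or pivot.isna().any().any():
        raise DataError("unbalanced table: every subject needs every within cell")
    counts = table.groupby([subject, w1, w2]).size()
    if (counts != 1).any():
        raise DataError("duplicate rows for a subject x cell combination")

    y = np.empty((len(subjects), len(a_levels), len(b_levels)))
    for si, s in enumerate(subjects):
        for ai, al in enumerate(a_levels):
            for bi, bl in enumerate(b_levels):
                y[si, ai, bi] = pivot.loc[s, (al, bl)]
    g_index = np.array([g_levels.index(groups_of[s]) for s in subjects])
    return y, g_index, g_levels, a_levels, b_levels


def _stratum(values: np.ndarray, g_index: np.ndarray, n_groups: int, weight: float):
    """Partition one within-subject stratum.

    ``values`` is [subjects x cells] of orthogonal within-subject profile
    components.  Returns (SS_effect, SS_group_x_effect, SS_error).
    """
    overall = values.mean(axis=0)
    ss_effect = weight * len(values) * float(np.sum(overall**2))
    ss_gx = 0.0
    ss_err = 0.0
    for g in range(n_groups):
        sub = values[g_index == g]
        gm = sub.mean(axis=0)
        ss_gx += weight * len(sub) * float(np.sum((gm - overall) ** 2))
        ss_err += weight * float(np.sum((sub - gm) ** 2))
    return ss_effect, ss_gx, ss_err


def mixed_anova(
    table: pd.DataFrame,
    dv: str = DV,
    between: str = "group",
    within: tuple[str, str] = ("cue", "position"),
    subject: str = "subject",
) -> pd.DataFrame:
    """Mixed-design ANOVA table (df, F, p, generalized eta squared).

    Requires a complete within-subject design (every subject contributes
    every cue x position cell exactly once); group sizes may differ.
    Effects with a zero error sum of squares get NaN F/p (flagged
    undefined) rather than a crash.
    """
    y, g_index, g_levels, a_levels, b_levels = _pivot_cells(
        table, dv, between, within, subject
    )
    n, a, b = y.shape
    g = len(g_levels)

    # orthogonal within-subject profile components
    subj_mean = y.mean(axis=(1, 2))                      # [n]
    cue_prof = y.mean(axis=2) - subj_mean[:, None]       # [n x a]
    pos_prof = y.mean(axis=1) - subj_mean[:, None]       # [n x b]
    inter = (
        y
        - y.mean(axis=2, keepdims=True)
        - y.mean(axis=1, keepdims=True)
        + subj_mean[:, None, None]
    ).reshape(n, a * b)

    # between stratum (weight a*b on squared subject-mean deviations)
    grand = subj_mean.mean()
    ss_group = 0.0
    ss_sg = 0.0
    for gi in range(g):
        sub = subj_mean[g_index == gi]
        ss_group += a * b * len(sub) * (sub.mean() - grand) ** 2
        ss_sg += a * b * float(np.sum((sub - sub.mean()) ** 2))

    ss_cue, ss_gc, ss_csg = _stratum(cue_prof, g_index, g, weight=b)
    ss_pos, ss_gp, ss_psg = _stratum(pos_prof, g_index, g, weight=a)
    ss_cp, ss_gcp, ss_cpsg = _stratum(inter, g_index, g, weight=1.0)

    ss_subject_error = ss_sg + ss_csg + ss_psg + ss_cpsg

    rows = []

    def add(effect, ss, df1, ss_err, df2):
        if ss_err > 0 and df2 > 0:
            f = (ss / df1) / (ss_err / df2)
            p = float(stats.f.sf(f, df1, df2))
        else:
            f, p = float("nan"), float("nan")
        ges = ss / (ss + ss_subject_error) if (ss + ss_subject_error) > 0 else 0.0
        rows.append(
            {
                "effect": effect,
                "df_effect": df1,
                "df_error": df2,
                "ss_effect": ss,
                "ss_error": ss_err,
                "F": f,
                "p": p,
                "ges": ges,
            }
        )

    add("group", ss_group, g - 1, ss_sg, n - g)
    add("cue", ss_cue, a - 1, ss_csg, (n - g) * (a - 1))
    add("position", ss_pos, b - 1, ss_psg, (n - g) * (b - 1))
    add("group:cue", ss_gc, (g - 1) * (a - 1), ss_csg, (n - g) * (a - 1))
    add("group:position", ss_gp, (g - 1) * (b - 1), ss_psg, (n - g) * (b - 1))
    add("cue:position", ss_cp, (a - 1) * (b - 1), ss_cpsg, (n - g) * (a - 1) * (b - 1))
    add(
        "group:cue:position",
        ss_gcp,
        (g - 1) * (a - 1) * (b - 1),
        ss_cpsg,
        (n - g) * (a - 1) * (b - 1),
    )
    return pd.DataFrame(rows)


def anova_ss_total(table: pd.DataFrame, dv: str = DV) -> float:
    """Total sum of squares of the table around the grand mean."""
    y = table[dv].to_numpy(dtype=float)
    return float(np.sum((y - y.mean()) ** 2))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    kind: str  # one-sample | paired | independent
    t: float
    df: float
    p: float
    cohen_d: float
    n: int


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> TTestResult:
    """Two-sided one-sample t; Cohen's d = (mean - mu) / SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("one-sample t needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance")
    res = stats.ttest_1samp(x, mu)
    d = (x.mean() - mu) / sd
    return TTestResult("one-sample", float(res.statistic), x.size - 1, float(res.pvalue), d, x.size)


def subject_contrast_values(
    table: pd.DataFrame, weights: dict[tuple[str, str], float], dv: str = DV
) -> pd.Series:
    """Per-subject linear combination of (cue, position) cells."""
    pivot = table.pivot_table(index="subject", columns=["cue", "position"], values=dv)
    missing = [cell for cell in weights if cell not in pivot.columns]
    if missing:
        raise DataError(f"cells missing from table: {missing}")
    out = sum(w * pivot[cell] for cell, w in weights.items())
    if out.isna().any():
        raise DataError("contrast undefined for some subject (incomplete cells)")
    return out


def position_difference_weights(cue: str, scale: float = 1.0) -> dict[tuple[str, str], float]:
    """Weights for the first-minus-second-syllable amplitude difference of one cue."""
    return {(cue, "syll1"): scale, (cue, "syll2"): -scale}


def paired_contrast(
    table: pd.DataFrame, weights: dict[tuple[str, str], float], dv: str = DV
) -> TTestResult:
    """Paired t-test of a within-subject cell contrast across all subjects.

    ``weights`` define the per-subject difference (e.g. the pitch-vs-
    intensity contrast of position differences); df = n_subjects - 1 and
    Cohen's d is mean / SD of the per-subject differences.
    """
    diffs = subject_contrast_values(table, weights, dv).to_numpy()
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):  # identical paired values: no effect, by convention
            return TTestResult("paired", 0.0, diffs.size - 1, 1.0, 0.0, diffs.size)
        raise DataError("zero-variance differences")
    res = one_sample_t(diffs, 0.0)
    return TTestResult("paired", res.t, res.df, res.p, res.cohen_d, res.n)


def independent_t(a: np.ndarray, b: np.ndarray, pooled: bool = True) -> TTestResult:
    """Two-sample t-test (Student pooled-variance by default, Welch optional).

    Cohen's d always uses the pooled SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("need >= 2 values per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise DataError("zero pooled variance")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else float(res.df)
    return TTestResult("independent", float(res.statistic), df, float(res.pvalue), d, a.size + b.size)


def groupwise_position_test(
    table: pd.DataFrame, group: str, method: str = "paired", dv: str = DV
) -> TTestResult:
    """Follow-up test of the position effect within one group.

    ``method="paired"`` is a one-sample t on the group's per-subject
    position differences (df = n_group - 1); ``method="pooled"`` uses the
    across-group pooled SD of those differences (df = N - n_groups),
    matching reports that carry the full between-subject error df.
    """
    cues = sorted(table["cue"].unique())
    weights: dict[tuple[str, str], float] = {}
    for cue in cues:
        weights.update(position_difference_weights(cue, scale=1.0 / len(cues)))
    diffs = subject_contrast_values(table, weights, dv)
    groups_of = table.drop_duplicates("subject").set_index("subject")["group"]
    in_group = diffs[groups_of.reindex(diffs.index) == group].to_numpy()
    if in_group.size == 0:
        raise DataError(f"no subjects in group {group!r}")
    if method == "paired":
        return one_sample_t(in_group, 0.0)
    if method != "pooled":
        raise DataError("method must be 'paired' or 'pooled'")
    levels = groups_of.unique()
    ss = 0.0
    for g in levels:
        vals = diffs[groups_of.reindex(diffs.index) == g].to_numpy()
        ss += np.sum((vals - vals.mean()) ** 2)
    df = diffs.size - len(levels)
    sd = np.sqrt(ss / df)
    if sd == 0:
        raise DataError("zero pooled variance")
    t = in_group.mean() / (sd / np.sqrt(in_group.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult("one-sample", float(t), df, p, in_group.mean() / sd, in_group.size)


# ---------------------------------------------------------------------------
# a priori power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    effect_size_d: float
    alpha: float
    target_power: float
    allocation_ratio: float
    n_per_group: int
    n_total: int
    achieved_power: float


def two_sample_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    ncp = d * np.sqrt(n_per_group / 2.0)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    max_n: int = 1_000_000,
) -> PowerResult:
    """Smallest per-group n with two-sample t-test power >= target (1:1 groups)."""
    if d <= 0:
        raise DataError("effect size d must be positive")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise DataError("alpha and power must lie in (0, 1)")
    n = 2
    while n <= max_n:
        achieved = two_sample_power(d, n, alpha)
        if achieved >= power:
            return PowerResult(d, alpha, power, 1.0, n, 2 * n, achieved)
        n += 1
    raise DataError("power target unreachable within max_n")
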
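"""Group-difference and agreement statistics: means ± SD with Student's t,
prevalences with chi-square, Pearson correlation matrices and Cohen's kappa
concordance of dichotomized measures.

Standard tests are delegated to :mod:`scipy.stats`; kappa is computed from
the marginal-product expected agreement.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedStatisticError

#: Row/column order of the adiposity agreement matrices.
ADIPOSITY_MEASURES = ["body_fat", "visceral_fat", "bmi", "waist"]
#: Row/column order of the risk-score agreement matrices.
SCORE_MEASURES = ["fli", "hsi", "zju", "fld", "lap"]

#: panel-table column behind each matrix label
_MEASURE_COLUMNS = {
    "body_fat": "body_fat_pct",
    "visceral_fat": "visceral_fat_rating",
    "bmi": "bmi",
    "waist": "waist",
    **{s: s for s in SCORE_MEASURES},
}


def group_mean_sd(values, group_labels) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n−1 denominator).

    Empty groups never appear (groupby drops them); a single-member group
    reports SD as NaN, flagged as missing rather than an error.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float),
                          "group": np.asarray(group_labels)})
    out = frame.groupby("group", sort=False)["value"].agg(
        n="size", mean="mean", sd=lambda v: v.std(ddof=1))
    return out.reset_index()


def student_t_test(group_a, group_b, variant: str = "pooled"
                   ) -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p).

    ``variant="pooled"`` is the classical Student test; ``"welch"`` relaxes
    the equal-variance assumption. Two degenerate zero-variance groups with
    equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise DomainError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise UndefinedStatisticError("zero variance in both groups with "
                                      "different means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_test(table) -> tuple[float, float, float]:
    """Pearson chi-square on an r×c contingency table, no continuity
    correction; returns (chi2, df, p)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any():
        raise DomainError("table must be a 2-D array of non-negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        rows = np.nonzero(counts.sum(axis=1) == 0)[0].tolist()
        cols = np.nonzero(counts.sum(axis=0) == 0)[0].tolist()
        raise UndefinedStatisticError(
            f"zero marginal (rows {rows}, columns {cols})")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.dof), float(res.pvalue)


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("need equal-length vectors with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def kappa_from_table(table) -> float:
    """Cohen's kappa from a square contingency table of rater agreement."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise DomainError("kappa needs a square table")
    n = counts.sum()
    if n == 0:
        raise UndefinedStatisticError("empty table")
    p_obs = np.trace(counts) / n
    p_exp = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if p_exp == 1.0:
        raise UndefinedStatisticError(
            "expected agreement is 1 (a single-class marginal): kappa undefined")
    return float((p_obs - p_exp) / (1.0 - p_exp))


def cohen_kappa(a, b) -> float:
    """Cohen's kappa between two equal-length binary/categorical vectors.

    Undefined (raises) when either vector is single-class, since chance
    agreement is then 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DomainError("vectors must have equal length")
    labels = np.unique(np.r_[a, b])
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise UndefinedStatisticError(
            "a vector contains a single class: kappa undefined")
    ia = np.searchsorted(labels, a)
    ib = np.searchsorted(labels, b)
    table = np.zeros((len(labels), len(labels)))
    np.add.at(table, (ia, ib), 1)
    return kappa_from_table(table)


def correlation_matrix(frame: pd.DataFrame, measures: list[str]
                       ) -> pd.DataFrame:
    """Pairwise Pearson matrix over named continuous measures, diagonal
    exactly 1."""
    cols = [_MEASURE_COLUMNS.get(m, m) for m in measures]
    k = len(measures)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                mat[i, j] = mat[j, i] = pearson_r(frame[cols[i]],
                                                  frame[cols[j]])
            except UndefinedStatisticError:
                mat[i, j] = mat[j, i] = math.nan
    return pd.DataFrame(mat, index=measures, columns=measures)


def kappa_matrix(flags: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cohen's kappa over boolean columns; undefined cells are NaN
    (recorded, not raised)."""
    names = list(flags.columns)
    k = len(names)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                mat[i, j] = mat[j, i] = cohen_kappa(
                    flags[names[i]].to_numpy(), flags[names[j]].to_numpy())
            except UndefinedStatisticError:
                mat[i, j] = mat[j, i] = math.nan
    return pd.DataFrame(mat, index=names, columns=names)


def agreement_matrices(panel: pd.DataFrame, sex: str,
                       bmi_cutoff: float = 30.0,
                       waist_cutoffs: dict | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Pearson and kappa matrices for one sex stratum of a scored cohort.

    Continuous matrices cover the adiposity measures (body fat, visceral
    fat, BMI, waist) and the five risk scores. Kappa matrices dichotomize
    each measure at its "high" definition: the shipped adiposity cut-offs
    for fat measures, score high-risk boundaries for scales, and the
    supplied BMI/waist cut-offs (clinical defaults: BMI 30; waist 102 cm
    men / 88 cm women).
    """
    waist_cutoffs = waist_cutoffs or {"male": 102.0, "female": 88.0}
    sub = panel[panel["sex"] == sex]
    flags_adip = pd.DataFrame({
        "body_fat": sub["high_body_fat"].astype(bool),
        "visceral_fat": sub["high_visceral_fat"].astype(bool),
        "bmi": sub["bmi"] >= bmi_cutoff,
        "waist": sub["waist"] >= waist_cutoffs[sex],
    })
    flags_scores = pd.DataFrame(
        {s: (sub[f"{s}_category"] == "high") for s in SCORE_MEASURES})
    return {
        "pearson_adiposity": correlation_matrix(sub, ADIPOSITY_MEASURES),
        "pearson_scores": correlation_matrix(sub, SCORE_MEASURES),
        "kappa_adiposity": kappa_matrix(flags_adip),
        "kappa_scores": kappa_matrix(flags_scores),
    }
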
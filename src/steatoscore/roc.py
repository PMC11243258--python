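"""Empirical ROC analysis: curve, Mann–Whitney AUC, DeLong confidence
interval, and Youden-optimal cut-points.

The convention throughout is that higher predictor values indicate the
positive class and "predicted positive" means ``value >= threshold``.
Cut-point candidates default to midpoints between adjacent distinct
predictor values (plus the two infinite extremes); observed values can be
used instead via ``candidates="observed"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateOutcomeError, DomainError


def _as_arrays(predictor, outcome):
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("predictor and outcome must be 1-D of equal length")
    if np.isnan(x).any():
        raise DomainError("predictor contains missing values; filter first")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateOutcomeError(
            f"outcome has a single class (n_pos={n_pos}, n_neg={n_neg})")
    return x, y, n_pos, n_neg


def empirical_roc(predictor, outcome) -> np.ndarray:
    """Empirical ROC curve as an array of (fpr, tpr) vertices.

    Thresholds sweep the unique predictor values in descending order; ties
    are grouped so the curve has one vertex per distinct value, plus the
    exact endpoints (0,0) and (1,1).
    """
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    order = np.argsort(-x, kind="mergesort")
    xs, ys = x[order], y[order]
    # vertex after each group of tied values
    distinct = np.r_[np.nonzero(np.diff(xs))[0], len(xs) - 1]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(~ys)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return np.column_stack([fpr, tpr])


def trapezoid_auc(curve: np.ndarray) -> float:
    """Trapezoidal area under an ordered (fpr, tpr) polyline."""
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def auc_mann_whitney(predictor, outcome) -> float:
    """AUC as the Mann–Whitney probability that a random positive outranks
    a random negative, ties counted half. Identical to the trapezoidal
    integral of :func:`empirical_roc`."""
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    ranks = stats.rankdata(x)  # midranks
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def delong_variance(predictor, outcome) -> tuple[float, float]:
    """DeLong structural-components estimate: returns (auc, variance).

    Components are computed with midranks (the Sun–Xu O(n log n) form of
    DeLong's placement values).
    """
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    if n_pos < 2 or n_neg < 2:
        raise DegenerateOutcomeError("DeLong variance needs >= 2 per class")
    pos, neg = x[y], x[~y]
    tx = stats.rankdata(np.r_[pos, neg])      # midranks in combined sample
    tpos, tneg = tx[:n_pos], tx[n_pos:]
    rpos = stats.rankdata(pos)                # midranks within class
    rneg = stats.rankdata(neg)
    auc = float((tpos.sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
    v_pos = (tpos - rpos) / n_neg             # placement of each positive
    v_neg = 1.0 - (tneg - rneg) / n_pos       # placement of each negative
    s_pos = np.var(v_pos, ddof=1)
    s_neg = np.var(v_neg, ddof=1)
    return auc, float(s_pos / n_pos + s_neg / n_neg)


def auc_ci_delong(predictor, outcome, level: float = 0.95
                  ) -> tuple[float, float]:
    """Normal-approximation DeLong interval for the AUC, truncated to [0,1]."""
    auc, var = delong_variance(predictor, outcome)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def auc_ci_bootstrap(predictor, outcome, level: float = 0.95,
                     n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Stratified percentile-bootstrap interval, as a sensitivity check on
    the DeLong interval."""
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    rng = np.random.default_rng(seed)
    pos, neg = x[y], x[~y]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, n_pos, replace=True)
        bn = rng.choice(neg, n_neg, replace=True)
        ranks = stats.rankdata(np.r_[bp, bn])
        aucs[b] = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity − 1.

    Inputs above 1 are interpreted as percentages and rescaled.
    """
    sens, spec = float(sensitivity), float(specificity)
    if sens > 1.0:
        sens /= 100.0
    if spec > 1.0:
        spec /= 100.0
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise DomainError("sensitivity/specificity outside [0, 1] after scaling")
    return sens + spec - 1.0


def youden_optimal_cutpoint(predictor, outcome, candidates: str = "midpoint"
                            ) -> tuple[float, float, float, float]:
    """Maximize J = sens + spec − 1 over candidate thresholds.

    Returns ``(cutpoint, sensitivity, specificity, youden)``. Ties in J are
    broken by the larger specificity, then by the smaller cut-point.
    """
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    uniq = np.unique(x)
    if candidates == "midpoint":
        cand = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    elif candidates == "observed":
        cand = np.r_[-np.inf, uniq, np.inf]
    else:
        raise DomainError(f"unknown candidate rule {candidates!r}")
    # counts of x >= t via sorted positions
    xs_pos = np.sort(x[y])
    xs_neg = np.sort(x[~y])
    sens = 1.0 - np.searchsorted(xs_pos, cand, side="left") / n_pos
    spec = np.searchsorted(xs_neg, cand, side="left") / n_neg
    j = sens + spec - 1.0
    # lexicographic argmax: J, then specificity, then smaller cut-point
    best = np.lexsort((cand, -spec, -j))[0]
    return float(cand[best]), float(sens[best]), float(spec[best]), float(j[best])


@dataclass
class RocResult:
    """Full ROC evaluation of one (predictor, outcome) pair."""

    predictor_name: str
    outcome_name: str
    n_pos: int
    n_neg: int
    curve: np.ndarray            # (k, 2) array of (fpr, tpr), endpoints exact
    auc: float
    auc_ci: tuple[float, float]
    cutpoint: float
    sensitivity: float
    specificity: float
    youden: float
    metadata: dict = field(default_factory=dict)

    def curve_frame(self):
        import pandas as pd
        return pd.DataFrame(self.curve, columns=["fpr", "tpr"])


def roc_analysis(predictor, outcome, predictor_name: str = "predictor",
                 outcome_name: str = "outcome", level: float = 0.95,
                 candidates: str = "midpoint",
                 auto_orient: bool = False) -> RocResult:
    """Assemble the complete :class:`RocResult` for one pair.

    With ``auto_orient=True`` the predictor is negated when its AUC falls
    below 0.5 (the flip is recorded in metadata and the reported cut-point
    is mapped back to the original scale as an upper bound).
    """
    x, y, n_pos, n_neg = _as_arrays(predictor, outcome)
    meta = {"ci_method": "delong", "candidates": candidates, "oriented": False}
    auc = auc_mann_whitney(x, y)
    if auto_orient and auc < 0.5:
        x = -x
        auc = 1.0 - auc
        meta["oriented"] = True
    curve = empirical_roc(x, y)
    ci = auc_ci_delong(x, y, level=level)
    cut, sens, spec, j = youden_optimal_cutpoint(x, y, candidates=candidates)
    if meta["oriented"]:
        cut = -cut
    return RocResult(predictor_name, outcome_name, n_pos, n_neg, curve,
                     auc, ci, cut, sens, spec, j, meta)
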
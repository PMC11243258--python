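"""One-command study orchestration.

``run_study`` reads or simulates a cohort, scores every subject, and
assembles a :class:`StudyReport` — the sex-stratified descriptives,
fat-by-score-category tables, AUC/cut-point grids, and Pearson/kappa
agreement matrices, each exportable as CSV — together with run metadata
recording the seed and every defaulted assumption.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .agreement import agreement_matrices, chi_square_test, group_mean_sd, student_t_test
from .errors import DegenerateOutcomeError, InputError
from .records import read_cohort, write_cohort
from .roc import roc_analysis, RocResult
from .scores import SCALES, AdiposityCutoffs, ScoreThresholds, score_cohort
from .simulate import CohortSpec, default_spec, generate_cohort

SEXES = ("male", "female")
PREDICTORS = {"bmi": "BMI", "waist": "Waist", "body_fat_pct": "Body fat",
              "visceral_fat_rating": "Visceral fat"}

QUANT_VARS = ["age", "height", "weight", "waist", "hip", "sbp", "dbp",
              "glucose", "total_chol", "hdl", "ldl", "triglycerides",
              "ggt", "ast", "alt"]
CAT_VARS = ["smoker", "social_class", "physical_activity"]


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class StudyReport:
    """Assembled study tables plus run metadata."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    tables6: dict[str, pd.DataFrame]
    tables7: dict[str, pd.DataFrame]
    roc_results: dict[tuple, RocResult]
    metadata: dict = field(default_factory=dict)
    partial: bool = False

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1_descriptives.csv", index=False)
        self.table2.to_csv(out / "table2_mean_fat_by_category.csv", index=False)
        self.table3.to_csv(out / "table3_high_fat_prevalence.csv", index=False)
        self.table4.to_csv(out / "table4_auc.csv", index=False)
        self.table5.to_csv(out / "table5_cutpoints.csv", index=False)
        for name, frame in {**self.tables6, **self.tables7}.items():
            frame.round(3).to_csv(out / f"{name}.csv")
        curves = out / "roc_curves"
        curves.mkdir(exist_ok=True)
        for (sex, pred, scale), res in self.roc_results.items():
            res.curve_frame().to_csv(
                curves / f"roc_{sex}_{pred}_high_{scale}.csv", index=False)
        (out / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str))

    def report_hash(self) -> str:
        """Stable digest of all table contents, for determinism checks."""
        h = hashlib.sha256()
        for frame in [self.table1, self.table2, self.table3,
                      self.table4, self.table5,
                      *self.tables6.values(), *self.tables7.values()]:
            h.update(frame.round(10).to_csv().encode())
        return h.hexdigest()


def _table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptives: mean (SD) + Student's t for quantitative variables,
    % + chi-square for categoricals, men vs women."""
    men = cohort[cohort["sex"] == "male"]
    women = cohort[cohort["sex"] == "female"]
    rows = []
    for var in QUANT_VARS:
        if var not in cohort.columns or cohort[var].isna().all():
            continue
        a = men[var].dropna().to_numpy(float)
        b = women[var].dropna().to_numpy(float)
        _, _, p = student_t_test(a, b)
        rows.append({"variable": var,
                     "men": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                     "women": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                     "p_value": _fmt_p(p)})
    # age bands as a categorical block
    band = pd.cut(cohort["age"], [17, 29, 39, 49, 59, 69],
                  labels=["18-29", "30-39", "40-49", "50-59", "60-69"])
    for var, series in [("age_band", band)] + [
            (v, cohort[v]) for v in CAT_VARS if v in cohort.columns]:
        tab = pd.crosstab(series, cohort["sex"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        _, _, p = chi_square_test(tab.to_numpy())
        pct = tab / tab.sum(axis=0)
        first = True
        for level in tab.index:
            rows.append({"variable": f"{var}={level}",
                         "men": f"{100 * pct.loc[level, 'male']:.1f}%",
                         "women": f"{100 * pct.loc[level, 'female']:.1f}%",
                         "p_value": _fmt_p(p) if first else ""})
            first = False
    return pd.DataFrame(rows)


_CATEGORY_ORDER = {"fli": ["low", "moderate", "high"],
                   "hsi": ["low", "moderate", "high"],
                   "zju": ["low", "moderate", "high"],
                   "fld": ["low", "moderate", "high"],
                   "lap": ["low", "high"]}


def _table2(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) body fat and visceral fat by score category and sex.
    The k-group p-value is a one-way ANOVA (equal to the pooled Student
    test for the two-tier LAP)."""
    rows = []
    for fat_col, fat_name in [("body_fat_pct", "body_fat"),
                              ("visceral_fat_rating", "visceral_fat")]:
        for sex in SEXES:
            sub = panel[panel["sex"] == sex]
            for scale in SCALES:
                cats = _CATEGORY_ORDER[scale]
                stats_tab = group_mean_sd(sub[fat_col], sub[f"{scale}_category"])
                stats_tab = stats_tab.set_index("group")
                groups = [sub.loc[sub[f"{scale}_category"] == c, fat_col]
                          .to_numpy(float) for c in cats]
                groups = [g for g in groups if len(g) >= 2]
                p = stats.f_oneway(*groups).pvalue if len(groups) >= 2 else np.nan
                for cat in cats:
                    if cat not in stats_tab.index:
                        rows.append({"measure": fat_name, "sex": sex,
                                     "scale": scale, "category": cat,
                                     "n": 0, "mean": np.nan, "sd": np.nan,
                                     "p_value": ""})
                        continue
                    r = stats_tab.loc[cat]
                    rows.append({"measure": fat_name, "sex": sex,
                                 "scale": scale, "category": cat,
                                 "n": int(r["n"]), "mean": round(r["mean"], 1),
                                 "sd": round(r["sd"], 1),
                                 "p_value": _fmt_p(p) if cat == cats[0] else ""})
    return pd.DataFrame(rows)


def _table3(panel: pd.DataFrame) -> pd.DataFrame:
    """Prevalence of very-high body fat / high visceral fat by score
    category and sex, with the chi-square p across categories."""
    rows = []
    for flag, fat_name in [("high_body_fat", "very_high_body_fat"),
                           ("high_visceral_fat", "high_visceral_fat")]:
        for sex in SEXES:
            sub = panel[panel["sex"] == sex]
            for scale in SCALES:
                cats = _CATEGORY_ORDER[scale]
                tab = pd.crosstab(sub[f"{scale}_category"], sub[flag])
                p = np.nan
                if tab.shape == (len(cats), 2) and (tab.to_numpy() >= 0).all():
                    try:
                        _, _, p = chi_square_test(tab.to_numpy())
                    except Exception:
                        p = np.nan
                for cat in cats:
                    n = int((sub[f"{scale}_category"] == cat).sum())
                    k = int(sub.loc[sub[f"{scale}_category"] == cat, flag].sum())
                    rows.append({"measure": fat_name, "sex": sex,
                                 "scale": scale, "category": cat, "n": n,
                                 "count": k,
                                 "prevalence_pct":
                                     round(100.0 * k / n, 1) if n else np.nan,
                                 "p_value": (_fmt_p(p) if cat == cats[0]
                                             and not np.isnan(p) else "")})
    return pd.DataFrame(rows)


def _roc_grid(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """AUC/CI grid (table 4 analog), cut-point grid (table 5 analog), and
    the per-cell RocResult bundle. Cells whose outcome is single-class or
    whose predictor is absent are marked missing, not dropped silently."""
    rows4, rows5, results = [], [], {}
    for sex in SEXES:
        sub = panel[panel["sex"] == sex]
        for pred_col, pred_name in PREDICTORS.items():
            for scale in SCALES:
                base = {"sex": sex, "predictor": pred_name,
                        "outcome": f"high_{scale}"}
                if pred_col not in sub.columns or sub[pred_col].isna().all():
                    rows4.append({**base, "n_pos": 0, "n_neg": 0, "auc": np.nan,
                                  "ci_low": np.nan, "ci_high": np.nan,
                                  "status": "missing predictor"})
                    rows5.append({**base, "cutoff": np.nan, "sensitivity": np.nan,
                                  "specificity": np.nan, "youden": np.nan,
                                  "status": "missing predictor"})
                    continue
                keep = sub[pred_col].notna()
                outcome = (sub.loc[keep, f"{scale}_category"] == "high").to_numpy()
                x = sub.loc[keep, pred_col].to_numpy(float)
                try:
                    res = roc_analysis(x, outcome, pred_name, f"high_{scale}")
                except DegenerateOutcomeError as err:
                    rows4.append({**base, "n_pos": int(outcome.sum()),
                                  "n_neg": int((~outcome).sum()), "auc": np.nan,
                                  "ci_low": np.nan, "ci_high": np.nan,
                                  "status": str(err)})
                    rows5.append({**base, "cutoff": np.nan, "sensitivity": np.nan,
                                  "specificity": np.nan, "youden": np.nan,
                                  "status": str(err)})
                    continue
                results[(sex, pred_col, scale)] = res
                rows4.append({**base, "n_pos": res.n_pos, "n_neg": res.n_neg,
                              "auc": round(res.auc, 3),
                              "ci_low": round(res.auc_ci[0], 3),
                              "ci_high": round(res.auc_ci[1], 3),
                              "status": "ok"})
                rows5.append({**base, "cutoff": round(res.cutpoint, 1),
                              "sensitivity": round(res.sensitivity, 3),
                              "specificity": round(res.specificity, 3),
                              "youden": round(res.youden, 3), "status": "ok"})
    return pd.DataFrame(rows4), pd.DataFrame(rows5), results


def run_study(
    input_csv=None,
    spec: CohortSpec | None = None,
    seed: int = 0,
    thresholds: ScoreThresholds | None = None,
    cutoffs: AdiposityCutoffs | None = None,
    column_map=None,
    bmi_waist_dichotomy: str = "youden",
) -> StudyReport:
    """Run the full analysis on a cohort CSV or a synthetic cohort.

    ``bmi_waist_dichotomy`` selects how BMI and waist are dichotomized in
    the kappa matrices: ``"youden"`` uses each measure's Youden-optimal
    cut-point against the high-FLD outcome, ``"clinical"`` uses fixed
    obesity cut-offs (BMI 30 kg/m²; waist 102 cm men / 88 cm women). The
    report always carries the choice in its metadata.
    """
    thresholds = thresholds or ScoreThresholds()
    cutoffs = cutoffs or AdiposityCutoffs()
    rejections = pd.DataFrame()
    if input_csv is not None:
        cohort, rejections = read_cohort(input_csv, column_map=column_map)
        source = str(input_csv)
    else:
        spec = spec or default_spec()
        cohort = generate_cohort(spec, seed=seed)
        source = "synthetic"
    if cohort.empty:
        raise InputError("no valid subjects")

    panel, score_errors = score_cohort(cohort, thresholds, cutoffs)
    partial = False

    table1 = _table1(cohort)
    table2 = _table2(panel)
    table3 = _table3(panel)
    table4, table5, roc_results = _roc_grid(panel)
    if (table4.get("status") != "ok").any():
        partial = True

    # kappa dichotomization of BMI / waist
    bmi_cut = {"male": 30.0, "female": 30.0}
    waist_cut = {"male": 102.0, "female": 88.0}
    if bmi_waist_dichotomy == "youden":
        for sex in SEXES:
            if (sex, "bmi", "fld") in roc_results:
                bmi_cut[sex] = roc_results[(sex, "bmi", "fld")].cutpoint
            if (sex, "waist", "fld") in roc_results:
                waist_cut[sex] = roc_results[(sex, "waist", "fld")].cutpoint

    tables6, tables7 = {}, {}
    for sex in SEXES:
        mats = agreement_matrices(panel, sex, bmi_cutoff=bmi_cut[sex],
                                  waist_cutoffs=waist_cut)
        tables6[f"table6a_pearson_adiposity_{sex}"] = mats["pearson_adiposity"]
        tables6[f"table6b_pearson_scores_{sex}"] = mats["pearson_scores"]
        tables7[f"table7a_kappa_adiposity_{sex}"] = mats["kappa_adiposity"]
        tables7[f"table7b_kappa_scores_{sex}"] = mats["kappa_scores"]

    metadata = {
        "software_version": __version__,
        "seed": seed,
        "source": source,
        "n_subjects": int(len(panel)),
        "n_rejected_input_rows": int(rejections["row"].nunique())
        if len(rejections) else 0,
        "n_score_errors": int(score_errors["row"].nunique())
        if len(score_errors) else 0,
        "thresholds": asdict(thresholds),
        "visceral_high_cutoff": cutoffs.visceral_high,
        "body_fat_cutoff_table": {f"{k[0]}_{k[1]}_{k[2]}": v
                                  for k, v in cutoffs.body_fat_high.items()},
        "bmi_waist_dichotomy": bmi_waist_dichotomy,
        "bmi_kappa_cutoffs": bmi_cut,
        "waist_kappa_cutoffs": waist_cut,
        "roc_ci_method": "delong",
        "roc_candidates": "midpoint",
        "assumptions": [
            "high boundaries inclusive (score >= boundary)",
            "hyperglycemia = fasting glucose >= "
            f"{thresholds.hyperglycemia_cutoff} mg/dL or diabetes flag",
            f"diabetes rule: {thresholds.diabetes_rule}",
            "kappa dichotomization: high vs not-high (moderate+low merged)",
        ],
    }
    report = StudyReport(table1, table2, table3, table4, table5,
                         tables6, tables7, roc_results, metadata, partial)
    metadata["report_hash"] = report.report_hash()
    return report


def validate_input(path, column_map=None):
    """Validate a cohort CSV; returns (valid cohort, rejection log)."""
    return read_cohort(path, column_map=column_map)


def simulate_to_csv(path, n_male: int = 4104, n_female: int = 4486,
                    seed: int = 0) -> pd.DataFrame:
    """Generate the default-spec synthetic cohort and write it as CSV."""
    cohort = generate_cohort(default_spec(n_male, n_female), seed=seed)
    write_cohort(cohort, path)
    return cohort
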
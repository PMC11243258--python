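"""Hepatic steatosis risk scores and adiposity classification.

Implements the five formula-defined scores used to grade the risk of
metabolic-dysfunction-associated fatty liver disease (MAFLD):

* **FLI** (fatty liver index): ``100·e^L/(1+e^L)`` with the linear predictor
  ``L = 0.953·ln TG + 0.139·BMI + 0.718·ln GGT + 0.053·WC − 15.745``
  (TG in mg/dL, GGT in U/L, WC in cm). High risk from 60.
* **HSI** (hepatic steatosis index): ``8·ALT/AST + BMI + 2·diabetes +
  2·female``. High risk from 36.
* **ZJU** index: ``BMI + FBG + TG + 3·ALT/AST + 2·female`` with fasting
  glucose (FBG) and triglycerides in mmol/L. High risk from 38.
* **FLD** index: ``BMI + TG + 3·ALT/AST + 2·hyperglycemia`` with TG in
  mmol/L. High risk from 37.
* **LAP** (lipid accumulation product): ``(WC − 65)·TG`` for men,
  ``(WC − 58)·TG`` for women, TG in mmol/L. High risk from 42.7.

All functions accept scalars or numpy arrays. Every "high" boundary is
inclusive (a score equal to the boundary is high risk). SubjectRecord fields
are stored in mg/dL; the mmol/L conversions are internal and use the
documented constants below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ValidityError
from .records import SubjectRecord

#: mg/dL per mmol/L for triglycerides (molar mass plumbing).
MGDL_PER_MMOL_TG = 88.57
#: mg/dL per mmol/L for glucose.
MGDL_PER_MMOL_GLUCOSE = 18.016

_CONVERSION = {
    "triglycerides": MGDL_PER_MMOL_TG,
    "glucose": MGDL_PER_MMOL_GLUCOSE,
}

SCALES = ("fli", "hsi", "zju", "fld", "lap")


@dataclass
class ScoreThresholds:
    """Per-scale category boundaries and auxiliary rules.

    ``*_high`` boundaries are the published high-risk onsets and are
    inclusive. The lower-tier boundaries separating "low" from "moderate"
    are not published for these scales; the defaults are conventional
    rule-out values and are echoed into run metadata. LAP is two-tier
    (normal / high).
    """

    fli_high: float = 60.0
    hsi_high: float = 36.0
    zju_high: float = 38.0
    fld_high: float = 37.0
    lap_high: float = 42.7
    fli_low_upper: float = 30.0
    hsi_low_upper: float = 30.0
    zju_low_upper: float = 32.0
    fld_low_upper: float = 27.0
    hyperglycemia_cutoff: float = 100.0   # mg/dL fasting, impaired-fasting floor
    diabetes_glucose_cutoff: float = 126.0
    diabetes_rule: str = "flag_or_glucose"  # or "flag_only"
    tg_friedewald_max: float = 400.0

    def __post_init__(self) -> None:
        pairs = [("fli", self.fli_low_upper, self.fli_high),
                 ("hsi", self.hsi_low_upper, self.hsi_high),
                 ("zju", self.zju_low_upper, self.zju_high),
                 ("fld", self.fld_low_upper, self.fld_high)]
        for name, low, high in pairs:
            if not (0 < low < high):
                raise ConfigurationError(
                    f"{name}: need 0 < low_upper ({low}) < high ({high})")
        if self.lap_high <= 0 or self.tg_friedewald_max <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.diabetes_rule not in ("flag_only", "flag_or_glucose"):
            raise ConfigurationError(f"unknown diabetes_rule {self.diabetes_rule!r}")

    def high_boundary(self, scale: str) -> float:
        return getattr(self, f"{scale}_high")

    def low_upper(self, scale: str) -> float | None:
        return None if scale == "lap" else getattr(self, f"{scale}_low_upper")


#: Default "very high body fat" onsets (%) by sex and age band, in the style
#: of bioimpedance healthy-range charts (upper limit of the "high" band).
DEFAULT_BODY_FAT_CUTOFFS = {
    ("male", 18, 39): 25.0,
    ("male", 40, 59): 28.0,
    ("male", 60, 69): 30.0,
    ("female", 18, 39): 39.0,
    ("female", 40, 59): 40.0,
    ("female", 60, 69): 42.0,
}


@dataclass
class AdiposityCutoffs:
    """High-adiposity definitions: a fixed visceral rating onset and a
    sex/age-banded body-fat table."""

    visceral_high: float = 10.0
    body_fat_high: dict = field(
        default_factory=lambda: dict(DEFAULT_BODY_FAT_CUTOFFS))

    def __post_init__(self) -> None:
        for (sex, lo, hi), cut in self.body_fat_high.items():
            if not (0 < cut < 100):
                raise ConfigurationError(
                    f"body-fat cut-off {cut} for ({sex},{lo}-{hi}) not in (0,100)")
        for sex in ("male", "female"):
            covered = sorted((lo, hi) for (s, lo, hi) in self.body_fat_high
                             if s == sex)
            if not covered or covered[0][0] > 18 or covered[-1][1] < 69:
                raise ConfigurationError(f"body-fat table does not cover 18-69 for {sex}")
            for (_, hi_prev), (lo_next, _) in zip(covered, covered[1:]):
                if lo_next != hi_prev + 1:
                    raise ConfigurationError(f"body-fat table has a gap for {sex}")

    def body_fat_cutoff(self, sex: str, age: float) -> float:
        for (s, lo, hi), cut in self.body_fat_high.items():
            if s == sex and lo <= age <= hi:
                return cut
        raise ConfigurationError(f"no body-fat cut-off for sex={sex}, age={age}")


def _require_positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise DomainError(f"{name} must be strictly positive")


def compute_bmi(weight, height):
    """Body mass index, kg/m², from weight in kg and height in cm."""
    _require_positive("weight", weight)
    _require_positive("height", height)
    return weight / (np.asarray(height) / 100.0) ** 2


def convert_mgdl_to_mmol(value, analyte: str):
    """Convert an analyte concentration from mg/dL to mmol/L."""
    if analyte not in _CONVERSION:
        raise DomainError(f"unknown analyte {analyte!r}; "
                          f"expected one of {sorted(_CONVERSION)}")
    if np.any(np.asarray(value) < 0):
        raise DomainError(f"{analyte} concentration must be >= 0")
    return value / _CONVERSION[analyte]


def friedewald_ldl(total_chol, hdl, triglycerides, tg_max: float = 400.0):
    """LDL cholesterol by the Friedewald formula, TC − HDL − TG/5 (mg/dL).

    Only valid for triglycerides up to ``tg_max`` (400 mg/dL); above that a
    :class:`ValidityError` is raised so the caller can fall back to a
    measured LDL. A negative result is returned with a warning.
    """
    if np.any(np.asarray(triglycerides) > tg_max):
        raise ValidityError(
            f"Friedewald formula invalid for triglycerides > {tg_max} mg/dL")
    ldl = total_chol - hdl - triglycerides / 5.0
    if np.any(np.asarray(ldl) < 0):
        warnings.warn("Friedewald LDL is negative; check lipid inputs",
                      stacklevel=2)
    return ldl


def fli(triglycerides, bmi, ggt, waist):
    """Fatty liver index on the 0–100 logistic scale."""
    _require_positive("triglycerides", triglycerides)
    _require_positive("ggt", ggt)
    L = (0.953 * np.log(triglycerides) + 0.139 * np.asarray(bmi)
         + 0.718 * np.log(ggt) + 0.053 * np.asarray(waist) - 15.745)
    # 100·e^L/(1+e^L), computed stably on both tails
    with np.errstate(over="ignore"):
        return 100.0 / (1.0 + np.exp(-L))


def hsi(alt, ast, bmi, diabetes, female):
    """Hepatic steatosis index."""
    _require_positive("ast", ast)
    return (8.0 * np.asarray(alt) / np.asarray(ast) + np.asarray(bmi)
            + 2.0 * np.asarray(diabetes, dtype=float)
            + 2.0 * np.asarray(female, dtype=float))


def zju(bmi, glucose, triglycerides, alt, ast, female):
    """ZJU index; glucose and triglycerides are supplied in mg/dL and
    converted to mmol/L internally."""
    _require_positive("ast", ast)
    _require_positive("glucose", glucose)
    _require_positive("triglycerides", triglycerides)
    return (np.asarray(bmi)
            + convert_mgdl_to_mmol(glucose, "glucose")
            + convert_mgdl_to_mmol(triglycerides, "triglycerides")
            + 3.0 * np.asarray(alt) / np.asarray(ast)
            + 2.0 * np.asarray(female, dtype=float))


def fld(bmi, triglycerides, alt, ast, hyperglycemia):
    """FLD index; triglycerides converted to mmol/L internally."""
    _require_positive("ast", ast)
    _require_positive("triglycerides", triglycerides)
    return (np.asarray(bmi)
            + convert_mgdl_to_mmol(triglycerides, "triglycerides")
            + 3.0 * np.asarray(alt) / np.asarray(ast)
            + 2.0 * np.asarray(hyperglycemia, dtype=float))


#: Sex-specific waist offsets (cm) in the lipid accumulation product.
LAP_WAIST_OFFSET = {"male": 65.0, "female": 58.0}


def lap(waist, triglycerides, sex):
    """Lipid accumulation product; TG converted to mmol/L internally.

    A waist below the sex offset yields a negative product; it is returned
    as-is (with a warning) to preserve monotone ranking for ROC use.
    """
    _require_positive("triglycerides", triglycerides)
    sex_arr = np.asarray(sex)
    offset = np.where(sex_arr == "female",
                      LAP_WAIST_OFFSET["female"], LAP_WAIST_OFFSET["male"])
    if np.any((sex_arr != "female") & (sex_arr != "male")):
        raise DomainError("sex must be 'male' or 'female'")
    value = (np.asarray(waist) - offset) * convert_mgdl_to_mmol(
        triglycerides, "triglycerides")
    if np.any(np.asarray(value) < 0):
        warnings.warn("negative LAP (waist below sex offset); returned as-is",
                      stacklevel=2)
    if np.isscalar(waist) and np.isscalar(triglycerides):
        return float(value)
    return value


def classify_score(score, scale: str,
                   thresholds: ScoreThresholds | None = None):
    """Assign a score to its risk tier: 'low' / 'moderate' / 'high'.

    "High" is inclusive of the boundary. LAP has no moderate tier, so its
    sub-threshold tier is 'low' (reported as "normal" in tables).
    """
    thresholds = thresholds or ScoreThresholds()
    scale = scale.lower()
    if scale not in SCALES:
        raise DomainError(f"unknown scale {scale!r}")
    arr = np.asarray(score, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    high = thresholds.high_boundary(scale)
    low_upper = thresholds.low_upper(scale)
    out = np.full(arr.shape, "moderate", dtype=object)
    out[arr >= high] = "high"
    if low_upper is None:
        out[arr < high] = "low"
    else:
        out[arr < low_upper] = "low"
    if scalar:
        return str(out[0])
    return out


def classify_adiposity(record: SubjectRecord,
                       cutoffs: AdiposityCutoffs | None = None
                       ) -> tuple[bool, bool]:
    """Return ``(high_body_fat, high_visceral_fat)`` for one subject."""
    cutoffs = cutoffs or AdiposityCutoffs()
    high_vf = record.visceral_fat_rating >= cutoffs.visceral_high
    high_bf = record.body_fat_pct >= cutoffs.body_fat_cutoff(
        record.sex, record.age)
    return bool(high_bf), bool(high_vf)


@dataclass
class ScorePanel:
    """The five computed scores, their risk tiers and adiposity flags for
    one subject."""

    fli: float
    hsi: float
    zju: float
    fld: float
    lap: float
    fli_category: str
    hsi_category: str
    zju_category: str
    fld_category: str
    lap_category: str
    high_body_fat: bool
    high_visceral_fat: bool
    bmi: float
    ldl: float | None = None


def _hyperglycemia(record: SubjectRecord, thresholds: ScoreThresholds) -> bool:
    return bool(record.diabetes
                or record.glucose >= thresholds.hyperglycemia_cutoff)


def _diabetes(record: SubjectRecord, thresholds: ScoreThresholds) -> bool:
    if thresholds.diabetes_rule == "flag_only":
        return bool(record.diabetes)
    return bool(record.diabetes
                or record.glucose >= thresholds.diabetes_glucose_cutoff)


def score_panel(record: SubjectRecord,
                thresholds: ScoreThresholds | None = None,
                cutoffs: AdiposityCutoffs | None = None) -> ScorePanel:
    """Compute the full score panel for one subject.

    BMI is computed once and shared; a missing measured LDL is filled by
    the Friedewald formula when triglycerides allow, else left missing.
    """
    thresholds = thresholds or ScoreThresholds()
    cutoffs = cutoffs or AdiposityCutoffs()
    female = record.sex == "female"
    bmi = float(compute_bmi(record.weight, record.height))
    ldl = record.ldl
    if ldl is None and record.triglycerides <= thresholds.tg_friedewald_max:
        ldl = float(friedewald_ldl(record.total_chol, record.hdl,
                                   record.triglycerides,
                                   tg_max=thresholds.tg_friedewald_max))
    values = {
        "fli": float(fli(record.triglycerides, bmi, record.ggt, record.waist)),
        "hsi": float(hsi(record.alt, record.ast, bmi,
                         _diabetes(record, thresholds), female)),
        "zju": float(zju(bmi, record.glucose, record.triglycerides,
                         record.alt, record.ast, female)),
        "fld": float(fld(bmi, record.triglycerides, record.alt, record.ast,
                         _hyperglycemia(record, thresholds))),
        "lap": float(lap(record.waist, record.triglycerides, record.sex)),
    }
    categories = {f"{k}_category": classify_score(v, k, thresholds)
                  for k, v in values.items()}
    high_bf, high_vf = classify_adiposity(record, cutoffs)
    return ScorePanel(**values, **categories, high_body_fat=high_bf,
                      high_visceral_fat=high_vf, bmi=bmi, ldl=ldl)


def score_cohort(frame: pd.DataFrame,
                 thresholds: ScoreThresholds | None = None,
                 cutoffs: AdiposityCutoffs | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised panel computation over a validated cohort table.

    Rows whose fields break a formula's domain (e.g. AST = 0) are collected
    in an error log and excluded; the run continues for the rest. Returns
    ``(panel_table, error_log)``; the panel table carries the input columns
    plus bmi, the five scores, their categories and the adiposity flags.
    """
    thresholds = thresholds or ScoreThresholds()
    cutoffs = cutoffs or AdiposityCutoffs()

    errors: list[tuple] = []
    ok = pd.Series(True, index=frame.index)
    for col in ("triglycerides", "ggt", "ast", "glucose", "height", "weight"):
        bad = ~(pd.to_numeric(frame[col], errors="coerce") > 0)
        for idx in frame.index[bad]:
            errors.append((idx, col, f"{col} must be > 0"))
        ok &= ~bad
    df = frame[ok].copy()
    error_log = pd.DataFrame(errors, columns=["row", "field", "detail"])
    if df.empty:
        return df, error_log

    female = (df["sex"] == "female").to_numpy()
    bmi = compute_bmi(df["weight"].to_numpy(float), df["height"].to_numpy(float))
    tg = df["triglycerides"].to_numpy(float)
    glucose = df["glucose"].to_numpy(float)
    diabetes_flag = df["diabetes"].fillna(False).astype(bool).to_numpy() \
        if "diabetes" in df else np.zeros(len(df), bool)
    if thresholds.diabetes_rule == "flag_or_glucose":
        diabetes = diabetes_flag | (glucose >= thresholds.diabetes_glucose_cutoff)
    else:
        diabetes = diabetes_flag
    hyper = diabetes_flag | (glucose >= thresholds.hyperglycemia_cutoff)

    df["bmi"] = bmi
    df["fli"] = fli(tg, bmi, df["ggt"].to_numpy(float), df["waist"].to_numpy(float))
    df["hsi"] = hsi(df["alt"].to_numpy(float), df["ast"].to_numpy(float),
                    bmi, diabetes, female)
    df["zju"] = zju(bmi, glucose, tg, df["alt"].to_numpy(float),
                    df["ast"].to_numpy(float), female)
    df["fld"] = fld(bmi, tg, df["alt"].to_numpy(float),
                    df["ast"].to_numpy(float), hyper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative LAP handled per-row below
        df["lap"] = lap(df["waist"].to_numpy(float), tg, df["sex"].to_numpy())
    n_neg = int((df["lap"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} subjects have negative LAP (waist below the "
                      "sex offset); values kept as-is", stacklevel=2)

    for scale in SCALES:
        df[f"{scale}_category"] = classify_score(df[scale].to_numpy(),
                                                 scale, thresholds)

    # Friedewald fill for missing LDL where TG permits
    if "ldl" not in df.columns:
        df["ldl"] = np.nan
    fillable = df["ldl"].isna() & (tg <= thresholds.tg_friedewald_max)
    if fillable.any():
        sub = df.loc[fillable]
        df.loc[fillable, "ldl"] = (sub["total_chol"] - sub["hdl"]
                                   - sub["triglycerides"] / 5.0)

    # adiposity flags via the banded table
    cut = np.array([cutoffs.body_fat_cutoff(s, a)
                    for s, a in zip(df["sex"], df["age"])])
    df["high_body_fat"] = df["body_fat_pct"].to_numpy(float) >= cut
    df["high_visceral_fat"] = (df["visceral_fat_rating"].to_numpy(float)
                               >= cutoffs.visceral_high)
    return df, error_log
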
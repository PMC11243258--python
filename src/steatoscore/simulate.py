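"""Synthetic occupational-health cohorts via a Gaussian copula.

The generator reproduces the statistical structure the downstream analysis
assumes: sex-stratified marginal moments for the measured variables
(anthropometrics and blood pressure as truncated normals, right-skewed
analytes as moment-matched lognormals), a latent correlation structure
among them, and body-fat % / visceral-fat rating built as noisy monotone
functions of BMI and waist tuned to target Pearson correlations. It stands
in for a real bioimpedance-equipped occupational cohort, which cannot be
deposited; only printed summary moments and inter-measure correlations are
emulated, not the true joint distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .scores import compute_bmi

SEXES = ("male", "female")

#: order of the copula-driven marginal variables
COPULA_VARS = ["height", "weight", "waist", "hip", "sbp", "dbp", "glucose",
               "total_chol", "hdl", "ldl", "triglycerides", "ggt", "ast", "alt"]

AGE_BANDS = [(18, 29), (30, 39), (40, 49), (50, 59), (60, 69)]


@dataclass
class MarginalSpec:
    """One variable's marginal distribution on the natural scale."""

    name: str
    family: str          # "normal" or "lognormal"
    mean: float
    sd: float
    lower: float | None = None   # clip bound (normal family only)
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise DomainError(f"unknown family {self.family!r}")
        if self.sd <= 0:
            raise DomainError(f"{self.name}: sd must be > 0")

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws through this marginal."""
        if self.family == "normal":
            x = self.mean + self.sd * z
            if self.lower is not None or self.upper is not None:
                clipped = ((self.lower is not None) & (x < (self.lower or -np.inf))
                           ) | ((self.upper is not None) & (x > (self.upper or np.inf)))
                frac = float(np.mean(clipped))
                if frac > 0.01:
                    warnings.warn(f"{self.name}: {frac:.1%} of draws clipped "
                                  "to the truncation bounds", stacklevel=2)
                x = np.clip(x, self.lower, self.upper)
            return x
        # lognormal, moment-matched on the natural scale
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return np.exp(mu + np.sqrt(sigma2) * z)


@dataclass
class AdiposityRecipe:
    """Targets for the derived body-composition variables of one sex.

    Body fat is a linear blend of standardized BMI and waist plus noise,
    with weights solved at generation time so the realized Pearson
    correlations hit ``r_bmi`` / ``r_waist``. The visceral rating goes
    through a moment-matched lognormal and integer rounding, which
    attenuates its realized correlations slightly.
    """

    body_fat_mean: float
    body_fat_sd: float
    body_fat_r_bmi: float
    body_fat_r_waist: float
    visceral_mean: float
    visceral_sd: float
    visceral_r_bmi: float
    visceral_r_waist: float


@dataclass
class CohortSpec:
    """Everything needed to draw one synthetic cohort."""

    n: dict[str, int]
    marginals: dict[str, dict[str, MarginalSpec]]   # sex -> name -> spec
    latent_corr: pd.DataFrame                        # shared across sexes
    age_band_weights: dict[str, list[float]]
    adiposity: dict[str, AdiposityRecipe]
    smoker_rate: dict[str, float]
    social_class_weights: dict[str, list[float]]     # classes I, II, III
    activity_weights: dict[str, list[float]]         # none, 1-3, >3 d/wk
    labeled_diabetes_rate: float = 0.01
    diabetes_glucose_cutoff: float = 126.0

    def validate(self) -> None:
        corr = self.latent_corr.to_numpy()
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise DomainError("latent correlation must be symmetric with unit diagonal")
        for sex in SEXES:
            if abs(sum(self.age_band_weights[sex]) - 1.0) > 1e-9:
                raise DomainError(f"{sex}: age-band weights must sum to 1")
            if self.n[sex] <= 0:
                raise DomainError(f"{sex}: n must be positive")


def nearest_psd(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite
    correlation matrix (eigenvalue clipping + unit-diagonal rescale)."""
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    fixed = vecs @ np.diag(np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _default_latent_corr() -> pd.DataFrame:
    """Literature-plausible latent correlations among the measured
    variables. Only the adiposity inter-correlations are calibrated to
    printed values; the rest shape realism, not correctness."""
    corr = pd.DataFrame(np.eye(len(COPULA_VARS)),
                        index=COPULA_VARS, columns=COPULA_VARS)

    def set_(a: str, b: str, r: float) -> None:
        corr.loc[a, b] = corr.loc[b, a] = r

    set_("height", "weight", 0.45)
    set_("height", "waist", 0.15)
    set_("height", "hip", 0.35)
    set_("weight", "waist", 0.88)
    set_("weight", "hip", 0.80)
    set_("waist", "hip", 0.78)
    # hip tracks waist's associations at reduced strength (it is a body-size
    # measure too); leaving them at zero makes the matrix indefinite
    set_("hip", "sbp", 0.22)
    set_("hip", "dbp", 0.20)
    set_("hip", "glucose", 0.22)
    set_("hip", "triglycerides", 0.25)
    set_("hip", "hdl", -0.20)
    set_("hip", "ggt", 0.20)
    set_("hip", "alt", 0.22)
    set_("ast", "waist", 0.22)
    set_("ast", "weight", 0.20)
    set_("ast", "triglycerides", 0.22)
    set_("sbp", "dbp", 0.70)
    set_("weight", "sbp", 0.30)
    set_("waist", "sbp", 0.32)
    set_("weight", "dbp", 0.25)
    set_("waist", "dbp", 0.28)
    set_("glucose", "waist", 0.32)
    set_("glucose", "weight", 0.26)
    set_("glucose", "triglycerides", 0.30)
    set_("total_chol", "ldl", 0.90)
    set_("total_chol", "hdl", 0.25)
    set_("total_chol", "triglycerides", 0.30)
    set_("ldl", "triglycerides", 0.25)
    set_("hdl", "triglycerides", -0.35)
    set_("hdl", "waist", -0.30)
    set_("hdl", "weight", -0.25)
    set_("triglycerides", "waist", 0.35)
    set_("triglycerides", "weight", 0.30)
    set_("triglycerides", "ggt", 0.35)
    set_("ggt", "alt", 0.40)
    set_("ggt", "ast", 0.35)
    set_("ggt", "waist", 0.30)
    set_("alt", "ast", 0.70)
    set_("alt", "waist", 0.32)
    set_("alt", "weight", 0.30)
    set_("alt", "triglycerides", 0.30)
    return corr


def default_spec(n_male: int = 4104, n_female: int = 4486) -> CohortSpec:
    """The calibrated default: marginal moments from the study's printed
    sex-stratified summary table, adiposity correlation targets from its
    printed Pearson matrix, and age-band/categorical weights from its
    descriptive percentages."""
    def N(name, mean, sd, lower=None, upper=None):
        return MarginalSpec(name, "normal", mean, sd, lower, upper)

    def LN(name, mean, sd):
        return MarginalSpec(name, "lognormal", mean, sd)

    marginals = {
        "male": {m.name: m for m in [
            N("height", 175.8, 7.2, 120, 230),
            N("weight", 81.2, 14.8, 25, 250),
            N("waist", 89.8, 12.5, 40, 200),
            N("hip", 101.8, 8.7, 50, 200),
            N("sbp", 128.6, 13.3, 70, 260),
            N("dbp", 79.9, 10.2, 40, 160),
            LN("glucose", 93.4, 17.8),
            N("total_chol", 191.8, 36.0, 80, 450),
            N("hdl", 49.2, 11.3, 15, 150),
            LN("ldl", 124.0, 54.6),
            LN("triglycerides", 107.8, 69.4),
            LN("ggt", 31.5, 30.0),
            LN("ast", 24.4, 17.3),
            LN("alt", 29.3, 34.9),
        ]},
        "female": {m.name: m for m in [
            N("height", 162.5, 6.1, 120, 230),
            N("weight", 63.9, 13.6, 25, 250),
            N("waist", 77.0, 12.0, 40, 200),
            N("hip", 99.6, 10.9, 50, 200),
            N("sbp", 117.2, 14.1, 70, 260),
            N("dbp", 74.9, 9.9, 40, 160),
            LN("glucose", 88.9, 12.6),
            N("total_chol", 189.0, 34.8, 80, 450),
            N("hdl", 59.5, 12.8, 15, 150),
            LN("ldl", 113.8, 30.7),
            LN("triglycerides", 81.5, 46.3),
            LN("ggt", 18.5, 15.9),
            LN("ast", 18.2, 7.7),
            LN("alt", 17.3, 13.4),
        ]},
    }
    # Body-fat / visceral-fat overall moments are reconstructed from the
    # printed per-stratum means weighted by stratum sizes; correlation
    # targets are the printed adiposity Pearson cells.
    adiposity = {
        "male": AdiposityRecipe(
            body_fat_mean=19.6, body_fat_sd=7.2,
            body_fat_r_bmi=0.803, body_fat_r_waist=0.789,
            visceral_mean=7.9, visceral_sd=4.4,
            visceral_r_bmi=0.853, visceral_r_waist=0.842),
        "female": AdiposityRecipe(
            body_fat_mean=29.0, body_fat_sd=7.6,
            body_fat_r_bmi=0.875, body_fat_r_waist=0.834,
            visceral_mean=4.7, visceral_sd=2.9,
            visceral_r_bmi=0.873, visceral_r_waist=0.846),
    }
    spec = CohortSpec(
        n={"male": n_male, "female": n_female},
        marginals=marginals,
        latent_corr=_default_latent_corr(),
        age_band_weights={
            "male": [0.155, 0.278, 0.327, 0.190, 0.050],
            "female": [0.168, 0.251, 0.344, 0.197, 0.040],
        },
        adiposity=adiposity,
        smoker_rate={"male": 0.155, "female": 0.158},
        social_class_weights={"male": [0.571, 0.202, 0.227],
                              "female": [0.508, 0.238, 0.254]},
        activity_weights={"male": [0.259, 0.270, 0.471],
                          "female": [0.351, 0.265, 0.384]},
    )
    spec.validate()
    return spec


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _blend_weights(r_bmi: float, r_waist: float, r: float
                   ) -> tuple[float, float, float]:
    """Solve a·z_bmi + b·z_waist + c·ε for target correlations given the
    realized corr(z_bmi, z_waist) = r; weights rescaled (with a warning)
    if the targets are jointly infeasible."""
    a = (r_bmi - r * r_waist) / (1.0 - r * r)
    b = (r_waist - r * r_bmi) / (1.0 - r * r)
    explained = a * a + b * b + 2.0 * a * b * r
    if explained >= 1.0:
        scale = np.sqrt(0.999 / explained)
        warnings.warn("adiposity correlation targets jointly infeasible; "
                      f"weights rescaled by {scale:.3f}", stacklevel=2)
        a, b, explained = a * scale, b * scale, 0.999
    return a, b, float(np.sqrt(1.0 - explained))


def _draw_sex(spec: CohortSpec, sex: str, rng: np.random.Generator
              ) -> pd.DataFrame:
    n = spec.n[sex]
    corr = nearest_psd(spec.latent_corr.loc[COPULA_VARS, COPULA_VARS]
                       .to_numpy())
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(COPULA_VARS))) @ chol.T
    df = pd.DataFrame({name: spec.marginals[sex][name].transform(z[:, i])
                       for i, name in enumerate(COPULA_VARS)})
    df.insert(0, "sex", sex)

    # age: band sampled by weight, uniform integer years within band
    bands = rng.choice(len(AGE_BANDS), size=n, p=spec.age_band_weights[sex])
    lo = np.array([AGE_BANDS[b][0] for b in bands])
    hi = np.array([AGE_BANDS[b][1] for b in bands])
    df.insert(1, "age", rng.integers(lo, hi + 1))

    # derived body composition
    recipe = spec.adiposity[sex]
    z_bmi = _standardize(compute_bmi(df["weight"].to_numpy(),
                                     df["height"].to_numpy()))
    z_waist = _standardize(df["waist"].to_numpy())
    r = float(np.corrcoef(z_bmi, z_waist)[0, 1])

    a, b, c = _blend_weights(recipe.body_fat_r_bmi, recipe.body_fat_r_waist, r)
    g_bf = a * z_bmi + b * z_waist + c * rng.standard_normal(n)
    df["body_fat_pct"] = np.clip(
        recipe.body_fat_mean + recipe.body_fat_sd * g_bf, 3.0, 60.0)

    a, b, c = _blend_weights(recipe.visceral_r_bmi, recipe.visceral_r_waist, r)
    g_vf = a * z_bmi + b * z_waist + c * rng.standard_normal(n)
    sigma2 = np.log1p((recipe.visceral_sd / recipe.visceral_mean) ** 2)
    mu = np.log(recipe.visceral_mean) - sigma2 / 2.0
    df["visceral_fat_rating"] = np.clip(
        np.rint(np.exp(mu + np.sqrt(sigma2) * g_vf)), 1, 59).astype(int)

    # flags and categoricals
    labeled = rng.random(n) < spec.labeled_diabetes_rate
    df["diabetes"] = (df["glucose"] >= spec.diabetes_glucose_cutoff) | labeled
    df["smoker"] = rng.random(n) < spec.smoker_rate[sex]
    df["social_class"] = rng.choice(["I", "II", "III"], size=n,
                                    p=spec.social_class_weights[sex])
    df["physical_activity"] = rng.choice(["none", "1-3", ">3"], size=n,
                                         p=spec.activity_weights[sex])
    return df


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0
                    ) -> pd.DataFrame:
    """Draw a full two-sex cohort; deterministic given (spec, seed)."""
    spec = spec or default_spec()
    spec.validate()
    rng = np.random.default_rng(seed)
    parts = [_draw_sex(spec, sex, rng) for sex in SEXES]
    df = pd.concat(parts, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(df))])
    return df


def inject_outcome_structure(records: pd.DataFrame, target_auc: float,
                             predictor: str = "body_fat_pct",
                             outcome_scale: str = "fld",
                             seed: int = 0) -> pd.DataFrame:
    """Test scaffolding: retune the separation between an adiposity
    predictor and a score-high outcome to an approximate target AUC.

    The outcome flag is computed from the current records; the predictor is
    then shifted for outcome-positive subjects by the binormal increment
    ``δ·sd`` with ``δ = √2·(Φ⁻¹(target) − Φ⁻¹(current AUC))``. This is a
    deliberate distortion for calibrating ROC tests, not a model of any
    physiology.
    """
    if not (0.5 < target_auc < 1.0):
        raise DomainError("target AUC must lie strictly inside (0.5, 1)")
    from .roc import auc_mann_whitney
    from .scores import score_cohort

    panel, _ = score_cohort(records)
    out = (panel[f"{outcome_scale}_category"] == "high").to_numpy()
    df = panel[records.columns].copy()
    x = df[predictor].to_numpy(float)
    current = auc_mann_whitney(x, out)
    current = min(max(current, 1e-6), 1 - 1e-6)
    delta = np.sqrt(2.0) * (stats.norm.ppf(target_auc)
                            - stats.norm.ppf(current))
    df.loc[out, predictor] = x[out] + delta * x.std()
    if predictor == "visceral_fat_rating":
        df[predictor] = np.clip(np.rint(df[predictor]), 0, None).astype(int)
    elif predictor == "body_fat_pct":
        df[predictor] = np.clip(df[predictor], 0.0, 99.0)
    return df
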
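"""Normative z-scoring, spatial release from masking, and norm refitting.

Children's SRTs improve roughly linearly with age across 4-13 years, so
the child norm in each spatial condition is a linear regression of SRT on
age plus a residual SD; the adult norm is a mean and SD. An individual's
z score is the (sign-flipped) deviation from the age-expected SRT in
residual-SD units, so a lower-than-expected SRT (better hearing-in-noise)
gives a positive z. Spatial release from masking (SRM) is the improvement
from moving the masker from 0 deg to +/-90 deg: SRT(0) - SRT(90).
Extrapolating the child regressions to the adult means estimates the age
at which performance matures (~14-15 y).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm


class OutOfNormsError(ValueError):
    """Age outside the ranges for which norms are defined."""


@dataclass(frozen=True)
class ChildNorm:
    """SRT = intercept + slope * age, residual SD in dB."""

    intercept_db: float
    slope_db_per_yr: float
    residual_sd_db: float

    def mean_srt(self, age_years: float) -> float:
        return self.intercept_db + self.slope_db_per_yr * age_years


@dataclass(frozen=True)
class AdultNorm:
    mean_db: float
    sd_db: float


@dataclass(frozen=True)
class NormSet:
    """First-run normative parameters for both spatial conditions."""

    child_0: ChildNorm = ChildNorm(4.5, -0.69, 1.85)
    child_90: ChildNorm = ChildNorm(-0.9, -0.77, 2.31)
    adult_0: AdultNorm = AdultNorm(-5.7, 2.00)
    adult_90: AdultNorm = AdultNorm(-12.5, 1.69)

    def child(self, condition: str) -> ChildNorm:
        return self.child_0 if _cond(condition) == "0" else self.child_90

    def adult(self, condition: str) -> AdultNorm:
        return self.adult_0 if _cond(condition) == "0" else self.adult_90


DEFAULT_NORMS = NormSet()

CHILD_AGE_MIN = 4.0
CHILD_AGE_MAX = 13.0
ADULT_AGE_MIN = 18.0


def _cond(condition) -> str:
    c = str(condition).lower().rstrip("°")
    if c in ("0", "colocated"):
        return "0"
    if c in ("90", "separated"):
        return "90"
    raise ValueError(f"unknown condition {condition!r}")


def z_score(srt_db: float, age, condition: str,
            norms: NormSet = DEFAULT_NORMS, *,
            allow_extrapolation: bool = False) -> float:
    """Normative z for one first-run SRT.

    ``age`` is real-valued years or the string ``"adult"``. No norms exist
    for ages in (13, 18); such ages (and ages < 4) raise
    :class:`OutOfNormsError` unless ``allow_extrapolation`` is set, which
    applies the child regression beyond its fitted range.
    """
    cond = _cond(condition)
    if isinstance(age, str):
        if age.lower() != "adult":
            raise ValueError(f"age must be numeric or 'adult', got {age!r}")
        a = norms.adult(cond)
        return -(srt_db - a.mean_db) / a.sd_db
    age = float(age)
    if age >= ADULT_AGE_MIN:
        a = norms.adult(cond)
        return -(srt_db - a.mean_db) / a.sd_db
    if not (CHILD_AGE_MIN <= age <= CHILD_AGE_MAX) and not allow_extrapolation:
        raise OutOfNormsError(
            f"no norms for age {age:g}; child norms cover 4-13 y and adult "
            f"norms >= 18 y (pass allow_extrapolation=True to override)")
    c = norms.child(cond)
    return -(srt_db - c.mean_srt(age)) / c.residual_sd_db


def srm(srt_0_db: float, srt_90_db: float) -> float:
    """Spatial release from masking: SRT(colocated) - SRT(separated), dB."""
    return srt_0_db - srt_90_db


def maturation_age(norms: NormSet = DEFAULT_NORMS, condition: str = "90") -> float:
    """Age at which the child regression reaches the adult mean (years).

    Solves intercept + slope * age = adult mean, assuming the child trend
    stays linear beyond 13 years.
    """
    cond = _cond(condition)
    c, a = norms.child(cond), norms.adult(cond)
    if c.slope_db_per_yr == 0:
        raise ValueError("child slope is zero; no crossing")
    return (a.mean_db - c.intercept_db) / c.slope_db_per_yr


def fit_norms(cohort: pd.DataFrame, run: int = 1, condition: str = "0",
              group: str = "child") -> ChildNorm | AdultNorm:
    """Refit one norm entry from a cohort table.

    ``cohort`` columns: ``id``, ``group`` ('child'/'adult'), ``age_years``,
    ``condition`` ('0'/'90'), ``run`` (1/2), ``srt_db``. Children: OLS of
    SRT on age, residual SD = sqrt(SSR / (n - 2)). Adults: mean and sample
    SD.
    """
    cond = _cond(condition)
    sub = cohort[(cohort["run"] == run)
                 & (cohort["condition"].map(_cond) == cond)
                 & (cohort["group"] == group)]
    if group == "adult":
        if len(sub) < 2:
            raise ValueError("need >= 2 adult rows")
        return AdultNorm(mean_db=float(sub["srt_db"].mean()),
                         sd_db=float(sub["srt_db"].std(ddof=1)))
    if len(sub) < 10:
        raise ValueError(f"need >= 10 child rows for the slope fit, got {len(sub)}")
    ages = sub["age_years"].to_numpy(float)
    if np.ptp(ages) == 0:
        raise ValueError("degenerate age range: all ages equal")
    X = sm.add_constant(ages)
    fit = sm.OLS(sub["srt_db"].to_numpy(float), X).fit()
    resid_sd = float(np.sqrt(fit.ssr / (len(sub) - 2)))
    return ChildNorm(intercept_db=float(fit.params[0]),
                     slope_db_per_yr=float(fit.params[1]),
                     residual_sd_db=resid_sd)


def fit_norm_set(cohort: pd.DataFrame, run: int = 1) -> NormSet:
    """Refit all four norm entries from a cohort table (first run default)."""
    return NormSet(
        child_0=fit_norms(cohort, run, "0", "child"),
        child_90=fit_norms(cohort, run, "90", "child"),
        adult_0=fit_norms(cohort, run, "0", "adult"),
        adult_90=fit_norms(cohort, run, "90", "adult"),
    )
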
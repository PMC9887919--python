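"""Synthetic cohort generator for overweight/obese adult women.

Emulates the statistical structure the downstream analysis assumes:
printed marginal distributions for age, anthropometry and body
composition; positive body-composition/BMI correlations; right-skewed
(gamma) beverage intakes; and a single latent "healthy beverage
pattern" factor H that simultaneously shifts beverage intakes (on the
log-mean scale) and body composition (raising skeletal muscle mass by
``delta_smm`` kg and lowering fat mass by ``delta_fm`` kg per unit H).
Setting both deltas to zero yields the null model in which beverage
pattern and body composition are independent.

The defaults reproduce the study conditions: n = 210 women, BMI
truncated at >= 25 (cohort inclusion), age 36.18 +/- 8.44 y, BMI
30.79 +/- 4.17 kg/m^2, fat mass 33.42 +/- 8.11 kg, and beverage means
calibrated so the adapted Healthy Beverage Index lands near
mean 65, SD 4.4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hbi import BEVERAGE_CATEGORIES

__all__ = [
    "GeneratorParams",
    "default_params",
    "generate_cohort",
    "set_effect",
    "COHORT_COLUMNS",
    "ENERGY_DENSITY_KCAL_PER_ML",
]

#: kcal per mL for the caloric beverage categories (typical label values).
ENERGY_DENSITY_KCAL_PER_ML: dict[str, float] = {
    "ssb": 0.40,
    "fruit_juice_100": 0.46,
    "full_fat_milk": 0.61,
    "low_fat_milk": 0.42,
}

EDUCATION_LEVELS = ("illiterate", "under_diploma", "diploma", "bachelor_plus")
ECONOMIC_CLASSES = ("poor", "moderate", "good")
#: economic score bins per class (inclusive): poor 0-3, moderate 4-6, good 7-9
_ECONOMIC_BINS = {"poor": (0, 3), "moderate": (4, 6), "good": (7, 9)}

COHORT_COLUMNS = (
    ["id", "age", "height", "weight", "bmi", "wc", "hc", "smm", "fm", "bf_pct",
     "energy", "pa", "education", "economic_score", "economic_class", "marital",
     "job", "sbp", "dbp"]
    + list(BEVERAGE_CATEGORIES)
    + ["total_bev_energy", "total_fluid"]
)


def _default_beverage_means() -> dict[str, float]:
    # mL/day; calibrated so the adapted HBI distribution sits near 65 +/- 4.4
    return {
        "water": 1250.0,
        "unsweetened_coffee_tea": 420.0,
        "low_fat_milk": 210.0,
        "full_fat_milk": 130.0,
        "fruit_juice_100": 70.0,
        "ssb": 150.0,
        "diet_drinks": 8.0,
        "alcohol": 0.0,
    }


def _default_beverage_dispersions() -> dict[str, float]:
    # gamma shape parameters (larger = less skewed)
    return {
        "water": 30.0,
        "unsweetened_coffee_tea": 12.0,
        "low_fat_milk": 6.0,
        "full_fat_milk": 6.0,
        "fruit_juice_100": 4.0,
        "ssb": 16.0,
        "diet_drinks": 2.0,
        "alcohol": 1.0,
    }


def _default_latent_effects() -> dict[str, float]:
    # loading of the latent healthy-pattern factor H on log mean intake
    return {
        "water": 0.25,
        "unsweetened_coffee_tea": 0.20,
        "low_fat_milk": 0.25,
        "full_fat_milk": -0.10,
        "fruit_juice_100": 0.0,
        "ssb": -0.35,
        "diet_drinks": -0.10,
        "alcohol": 0.0,
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort generator (units in field names' docs)."""

    n: int = 210
    seed: int = 0
    # marginal means/SDs
    age_mean: float = 36.18          # years
    age_sd: float = 8.44
    age_range: tuple[float, float] = (18.0, 56.0)
    bmi_mean: float = 30.79          # kg/m^2, truncated at bmi_min
    bmi_sd: float = 4.17
    bmi_min: float = 25.0
    height_mean: float = 161.4       # cm
    height_sd: float = 5.9
    fm_mean: float = 33.42           # kg fat mass
    fm_sd: float = 8.11
    smm_mean: float = 25.7           # kg skeletal muscle mass
    smm_sd: float = 3.40
    energy_mean: float = 2600.0      # kcal/day
    energy_sd: float = 760.0
    pa_mean: float = 1050.0          # MET-min/week
    pa_sd: float = 1150.0
    sbp_mean: float = 112.49         # mmHg
    sbp_sd: float = 13.21
    dbp_mean: float = 78.54
    dbp_sd: float = 10.01
    # body-composition regression on BMI (kg per kg/m^2)
    fm_bmi_slope: float = 1.6
    smm_bmi_slope: float = 0.55
    # beverage model
    beverage_means: Mapping[str, float] = field(default_factory=_default_beverage_means)
    beverage_dispersions: Mapping[str, float] = field(default_factory=_default_beverage_dispersions)
    latent_effect_beverage: Mapping[str, float] = field(default_factory=_default_latent_effects)
    # latent-factor effect on body composition (kg per unit H; >= 0 = protective)
    delta_smm: float = 1.0
    delta_fm: float = 1.5
    # categorical covariates
    education_probs: tuple[float, ...] = (0.014, 0.134, 0.366, 0.486)
    economic_probs: tuple[float, ...] = (0.266, 0.477, 0.257)
    marital_probs: tuple[float, ...] = (0.271, 0.729)
    employed_prob: float = 0.962

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("age_sd", "bmi_sd", "height_sd", "fm_sd", "smm_sd",
                     "energy_sd", "pa_sd", "sbp_sd", "dbp_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.delta_smm < 0 or self.delta_fm < 0:
            raise ValueError("delta_smm and delta_fm must be >= 0 (protective effect)")
        for cat in BEVERAGE_CATEGORIES:
            if self.beverage_means.get(cat, 0.0) < 0:
                raise ValueError(f"beverage mean for {cat} must be >= 0")
            if not self.beverage_dispersions.get(cat, 1.0) > 0:
                raise ValueError(f"beverage dispersion for {cat} must be > 0")
        for name, probs, k in (
            ("education_probs", self.education_probs, len(EDUCATION_LEVELS)),
            ("economic_probs", self.economic_probs, len(ECONOMIC_CLASSES)),
            ("marital_probs", self.marital_probs, 2),
        ):
            if len(probs) != k:
                raise ValueError(f"{name} must have {k} entries")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")


def default_params(**kwargs) -> GeneratorParams:
    """Default generator parameters: the study conditions.

    Keyword arguments replace individual fields (e.g. ``n=2000`` or
    ``seed=7``) without touching the calibration.
    """
    return dataclasses.replace(GeneratorParams(), **kwargs) if kwargs else GeneratorParams()


def set_effect(params: GeneratorParams, delta_smm: float, delta_fm: float) -> GeneratorParams:
    """Return a copy of ``params`` with the latent body-composition effect replaced.

    ``set_effect(p, 0, 0)`` yields the null model (no beverage/body-composition
    link beyond shared covariates).  Negative deltas are invalid.
    """
    if delta_smm < 0 or delta_fm < 0:
        raise ValueError("deltas must be >= 0")
    return dataclasses.replace(params, delta_smm=delta_smm, delta_fm=delta_fm)


def _truncnorm(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None, match_moments=False):
    """Truncated normal draws.

    With ``match_moments`` the underlying location/scale are solved so
    the *truncated* distribution has the requested mean and SD (printed
    cohort moments describe the truncated sample, not a latent normal).
    """
    loc, scale = mean, sd
    if match_moments:
        from scipy import optimize

        def resid(theta):
            l, s = theta
            a, b = (lower - l) / s, (upper - l) / s
            m, v = stats.truncnorm.stats(a, b, loc=l, scale=s, moments="mv")
            return [m - mean, np.sqrt(v) - sd]

        sol = optimize.root(resid, [mean, sd], method="hybr")
        if sol.success and sol.x[1] > 0:
            loc, scale = float(sol.x[0]), float(sol.x[1])
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Draw a cohort table of ``params.n`` participants.

    Deterministic given ``params`` (including ``seed``).  Generation
    order is fixed: latent factor H, age, height, BMI (truncated at the
    inclusion bound), weight from BMI and height, fat mass and skeletal
    muscle mass conditional on BMI and shifted by -delta_fm*H and
    +delta_smm*H, beverage intakes from gammas with log-mean shifted by
    the per-category loading on H, then energy, activity, blood
    pressure and categorical covariates.

    The residual variances of fat mass and muscle mass are reduced so
    that the *marginal* SDs match ``fm_sd`` / ``smm_sd`` regardless of
    the injected latent effect.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n

    h = rng.standard_normal(n)
    age = _truncnorm(rng, p.age_mean, p.age_sd, *p.age_range, size=n, match_moments=True)
    height = rng.normal(p.height_mean, p.height_sd, size=n)
    bmi = _truncnorm(rng, p.bmi_mean, p.bmi_sd, lower=p.bmi_min, size=n, match_moments=True)
    weight = bmi * (height / 100.0) ** 2

    def _conditional(mean, sd, slope, delta, sign):
        explained = (slope * p.bmi_sd) ** 2 + delta**2
        resid_sd = np.sqrt(max(sd**2 - explained, 0.04))
        vals = mean + slope * (bmi - p.bmi_mean) + sign * delta * h \
            + rng.normal(0.0, resid_sd, size=n)
        return np.clip(vals, 0.5, None)

    fm = _conditional(p.fm_mean, p.fm_sd, p.fm_bmi_slope, p.delta_fm, -1.0)
    smm = _conditional(p.smm_mean, p.smm_sd, p.smm_bmi_slope, p.delta_smm, +1.0)
    bf_pct = 100.0 * fm / weight

    # waist/hip circumference track BMI
    wc = 98.70 + 1.9 * (bmi - p.bmi_mean) + rng.normal(0.0, 5.7, size=n)
    hc = 114.0 + 1.8 * (bmi - p.bmi_mean) + rng.normal(0.0, 5.5, size=n)

    intakes = {}
    for cat in BEVERAGE_CATEGORIES:
        mean = float(p.beverage_means.get(cat, 0.0))
        if mean <= 0:
            intakes[cat] = np.zeros(n)
            continue
        shape = float(p.beverage_dispersions.get(cat, 1.0))
        load = float(p.latent_effect_beverage.get(cat, 0.0))
        # exp(load*H - load^2/2) keeps the marginal mean at `mean`
        mean_i = mean * np.exp(load * h - 0.5 * load**2)
        intakes[cat] = rng.gamma(shape, mean_i / shape, size=n)

    total_fluid = np.sum([intakes[c] for c in BEVERAGE_CATEGORIES], axis=0)
    total_bev_energy = np.sum(
        [intakes[c] * d for c, d in ENERGY_DENSITY_KCAL_PER_ML.items()], axis=0
    )

    energy = _truncnorm(rng, p.energy_mean, p.energy_sd, lower=100.0, size=n)
    pa_shape = (p.pa_mean / p.pa_sd) ** 2
    pa = rng.gamma(pa_shape, p.pa_mean / pa_shape, size=n)
    sbp = rng.normal(p.sbp_mean, p.sbp_sd, size=n)
    dbp = rng.normal(p.dbp_mean, p.dbp_sd, size=n)

    education = rng.choice(EDUCATION_LEVELS, size=n, p=np.asarray(p.education_probs))
    economic_class = rng.choice(ECONOMIC_CLASSES, size=n, p=np.asarray(p.economic_probs))
    economic_score = np.array(
        [rng.integers(_ECONOMIC_BINS[c][0], _ECONOMIC_BINS[c][1] + 1) for c in economic_class]
    ) if n else np.array([], dtype=int)
    marital = rng.choice(["single", "married"], size=n, p=np.asarray(p.marital_probs))
    job = np.where(rng.random(n) < p.employed_prob, "employed", "unemployed")

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
            "wc": wc,
            "hc": hc,
            "smm": smm,
            "fm": fm,
            "bf_pct": bf_pct,
            "energy": energy,
            "pa": pa,
            "education": education,
            "economic_score": economic_score,
            "economic_class": economic_class,
            "marital": marital,
            "job": job,
            "sbp": sbp,
            "dbp": dbp,
            **intakes,
            "total_bev_energy": total_bev_energy,
            "total_fluid": total_fluid,
        }
    )
    return table[list(COHORT_COLUMNS)]
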
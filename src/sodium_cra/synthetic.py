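"""Synthetic inputs emulating the study's restricted-access data sources.

Real inputs for this kind of analysis — respondent-level 24-h dietary
recalls linked to a branded food-composition database, and national
mortality extracts — are restricted-access.  This module generates
statistically analogous stand-ins so the full pipeline runs end to end:

* a food supply in which a configurable fraction of products sit above
  their category's sodium benchmark target, with a profile->product match
  map and generic (unmatched) profiles;
* recall microdata: each respondent contributes a first recall day and a
  configurable fraction (default 35%) a second; person-level usual intake
  is drawn from the stratum distribution and day intakes add within-person
  noise; day totals are decomposed into food items priced against the
  profile densities, so re-pricing the items against a capped supply
  reproduces the reformulation mechanism;
* a deaths-by-sex/5-year-band/cause table with a log-linear age gradient,
  scaled to configurable per-sex totals.

Everything is driven by one seeded generator; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .core import (
    CAUSES,
    CHILD_AGE_GROUP,
    MORTALITY_AGE_BANDS,
    SEXES,
    age_band_midpoint,
    load_intake_table,
)


class StratumConfig(BaseModel):
    sex: str
    age_group: str
    weight: float = Field(gt=0, description="relative population share")
    mean_mg: float = Field(gt=0, description="true usual sodium mean, mg/d")
    sd_mg: float = Field(gt=0, description="true between-person SD, mg/d")


def default_strata() -> list[StratumConfig]:
    """Adult strata defaulted to the published Canadian baseline usual
    sodium intake estimates (CCHS-Nutrition 2015 linked to branded food
    composition data), weighted by survey sample size."""
    table = load_intake_table()
    rows = table[table["sex"] != "total"]
    return [
        StratumConfig(
            sex=r.sex, age_group=r.age_group, weight=float(r.n),
            mean_mg=float(r.baseline_mean_mg), sd_mg=float(r.baseline_sd_mg),
        )
        for r in rows.itertuples(index=False)
    ]


#: Deaths split across ICD-10 cause groups, loosely matching the Canadian
#: cardiovascular cause mix (ischaemic heart disease dominant, then stroke).
DEFAULT_CAUSE_SHARES = {
    "I20-25": 0.53,
    "I60-69": 0.23,
    "I50": 0.10,
    "I10-15": 0.075,
    "I71": 0.035,
    "I26": 0.02,
    "I05-09": 0.01,
}


class SyntheticConfig(BaseModel):
    """Knobs for every synthetic input; defaults are the study conditions."""

    seed: int = 0
    # recalls
    n_respondents: int = Field(default=5000, gt=1)
    day2_fraction: float = Field(default=0.35, ge=0.0, le=1.0)
    within_model: Literal["lognormal", "additive"] = "lognormal"
    within_cv: float = Field(default=0.4, ge=0.0,
                             description="CV of multiplicative day-to-day noise")
    within_sd_mg: float | None = Field(
        default=None, description="additive within-person SD (mg/d), "
        "used when within_model='additive'")
    items_per_day: int = Field(default=8, gt=0)
    strata: list[StratumConfig] = Field(default_factory=default_strata)
    include_children: bool = False
    # food supply
    n_products: int = Field(default=1000, gt=0)
    n_categories: int = Field(default=50, gt=0)
    fraction_above_target: float = Field(default=0.5, ge=0.0, le=1.0)
    fraction_uncategorized: float = Field(default=0.05, ge=0.0, le=1.0)
    target_range_mg: tuple[float, float] = (100.0, 1200.0)
    excess_range: tuple[float, float] = (1.05, 1.8)
    n_generic_profiles: int = Field(default=10, ge=0)
    generic_density_range_mg: tuple[float, float] = (10.0, 400.0)
    # demography / mortality
    mortality_total_male: float = Field(default=30663.0, ge=0.0)
    mortality_total_female: float = Field(default=27813.0, ge=0.0)
    mortality_age_gradient: float = Field(
        default=0.10, description="log-linear increase in the deaths share "
        "per year of age (0 gives uniform deaths across bands)")
    cause_shares: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CAUSE_SHARES))
    population_base: float = Field(default=1_300_000.0, gt=0)
    population_decline: float = Field(
        default=0.045, ge=0.0,
        description="exponential population decline per year above age 62.5")

    @field_validator("cause_shares")
    @classmethod
    def _known_causes(cls, v):
        unknown = set(v) - set(CAUSES)
        if unknown:
            raise ValueError(f"unknown causes in cause_shares: {sorted(unknown)}")
        total = sum(v.values())
        if total <= 0:
            raise ValueError("cause shares must sum to a positive value")
        return {k: s / total for k, s in v.items()}

    @model_validator(mode="after")
    def _ranges(self):
        for name in ("target_range_mg", "excess_range", "generic_density_range_mg"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if self.within_model == "additive" and self.within_sd_mg is None:
            raise ValueError("within_sd_mg required when within_model='additive'")
        return self

    def all_strata(self) -> list[StratumConfig]:
        out = list(self.strata)
        if self.include_children:
            # descriptive-only child strata; never enter the impact model
            out += [
                StratumConfig(sex="male", age_group=CHILD_AGE_GROUP,
                              weight=3282, mean_mg=2500, sd_mg=1100),
                StratumConfig(sex="female", age_group=CHILD_AGE_GROUP,
                              weight=3282, mean_mg=2300, sd_mg=1000),
            ]
        return out


# --------------------------------------------------------------------------
# Food supply
# --------------------------------------------------------------------------

def generate_food_supply(
    config: SyntheticConfig, rng: np.random.Generator | None = None
):
    """Branded products, category targets, profile match map, generic profiles.

    Per category a benchmark target is drawn uniformly from
    ``target_range_mg``; each categorized product lands above its target
    with probability ``fraction_above_target`` (uniformly within
    ``excess_range`` times the target) and below it otherwise.  One
    matched profile is built per category; ``n_generic_profiles`` extra
    profiles have no branded match and keep generic densities.

    Returns (products, targets, match_map, generic_profiles).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.target_range_mg
    cats = [f"C{i:03d}" for i in range(config.n_categories)]
    targets = pd.DataFrame({
        "category_id": cats,
        "target_mg_per_100g": rng.uniform(lo, hi, size=config.n_categories),
    })

    n = config.n_products
    cat_idx = rng.integers(0, config.n_categories, size=n)
    uncategorized = rng.random(n) < config.fraction_uncategorized
    above = rng.random(n) < config.fraction_above_target
    t = targets["target_mg_per_100g"].to_numpy()[cat_idx]
    elo, ehi = config.excess_range
    density = np.where(above, t * rng.uniform(elo, ehi, size=n),
                       t * rng.uniform(0.3, 0.95, size=n))
    density = np.where(uncategorized, rng.uniform(50.0, 800.0, size=n), density)
    products = pd.DataFrame({
        "product_id": [f"B{i:05d}" for i in range(n)],
        "category_id": np.where(uncategorized, None, np.asarray(cats)[cat_idx]),
        "sodium_mg_per_100g": density,
    })

    match_map = {
        f"FP{c}": products.loc[
            (products["category_id"] == c), "product_id"
        ].tolist()
        for c in cats
    }
    match_map = {k: v for k, v in match_map.items() if v}

    glo, ghi = config.generic_density_range_mg
    generic = pd.DataFrame({
        "profile_id": [f"GP{i:03d}" for i in range(config.n_generic_profiles)],
        "sodium_mg_per_100g": rng.uniform(glo, ghi, size=config.n_generic_profiles),
    })
    return products, targets, match_map, generic


# --------------------------------------------------------------------------
# Recall microdata
# --------------------------------------------------------------------------

def generate_recalls(
    config: SyntheticConfig,
    profiles: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Respondent roster and 24-h recall items.

    Person usual intakes are drawn from a lognormal moment-matched to each
    stratum's configured mean/SD (positive and right-skewed, as observed
    intake distributions are); day intakes multiply (or add, in the additive model)
    within-person noise with expectation preserved.  Each respondent-day's
    sodium total is split across ``items_per_day`` food items by Dirichlet
    shares and converted to gram amounts against the profile densities, so
    summing amount x density/100 over items returns the day total exactly.

    Returns (respondents, items, day_truth) where ``day_truth`` holds the
    intended per-day sodium totals (mg) used to construct the items.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    strata = config.all_strata()
    w = np.array([s.weight for s in strata], dtype=float)
    w /= w.sum()
    assign = rng.choice(len(strata), size=config.n_respondents, p=w)

    means = np.array([s.mean_mg for s in strata])[assign]
    sds = np.array([s.sd_mg for s in strata])[assign]
    # lognormal usual intakes moment-matched to the configured mean/SD:
    # positive by construction and right-skewed like real intake data
    sigma2 = np.log1p((sds / means) ** 2)
    usual = rng.lognormal(np.log(means) - sigma2 / 2.0, np.sqrt(sigma2))

    respondents = pd.DataFrame({
        "respondent_id": [f"R{i:05d}" for i in range(config.n_respondents)],
        "sex": [strata[i].sex for i in assign],
        "age_group": [strata[i].age_group for i in assign],
        "weight": 1.0,
        "usual_mg_true": usual,
    })

    has_day2 = rng.random(config.n_respondents) < config.day2_fraction
    rows = []
    for day in (1, 2):
        idx = np.arange(config.n_respondents) if day == 1 else np.where(has_day2)[0]
        if len(idx) == 0:
            continue
        u = usual[idx]
        if config.within_model == "lognormal":
            s2 = math.log1p(config.within_cv**2)
            noise = rng.lognormal(-s2 / 2.0, math.sqrt(s2), size=len(idx))
            intake = u * noise
        else:
            intake = u + rng.normal(0.0, config.within_sd_mg, size=len(idx))
            intake = np.clip(intake, 1.0, None)
        rows.append(pd.DataFrame({
            "respondent_id": respondents["respondent_id"].to_numpy()[idx],
            "day_index": day,
            "target_sodium_mg": intake,
        }))
    day_truth = pd.concat(rows, ignore_index=True)

    profile_ids = profiles["profile_id"].to_numpy()
    density = profiles["sodium_mg_per_100g"].to_numpy(float)
    if (density <= 0).any():
        raise ValueError("profile densities must be positive to price items")

    k = config.items_per_day
    n_days = len(day_truth)
    chosen = rng.integers(0, len(profile_ids), size=(n_days, k))
    shares = rng.dirichlet(np.ones(k), size=n_days)
    amounts = shares * day_truth["target_sodium_mg"].to_numpy()[:, None] / (
        density[chosen] / 100.0
    )
    items = pd.DataFrame({
        "respondent_id": np.repeat(day_truth["respondent_id"].to_numpy(), k),
        "day_index": np.repeat(day_truth["day_index"].to_numpy(), k),
        "profile_id": profile_ids[chosen].ravel(),
        "amount_g": amounts.ravel(),
    })
    return respondents, items, day_truth


# --------------------------------------------------------------------------
# Demography and mortality
# --------------------------------------------------------------------------

def _largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Integer-round non-negative values so they sum exactly to ``total``."""
    floors = np.floor(values).astype(int)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(values - floors))
        floors[order[:short]] += 1
    return floors


def generate_demography(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Deaths and population by sex x 5-year band (20-24 ... 85+) x cause.

    The deaths share across bands is proportional to
    exp(gradient x (band midpoint - 22.5)) — a gradient of zero spreads
    deaths uniformly — then split across causes by ``cause_shares`` and
    integer-rounded so each sex hits its configured total exactly.
    Population counts follow a plateau-then-decline pyramid.
    """
    totals = {"male": config.mortality_total_male,
              "female": config.mortality_total_female}
    if sum(totals.values()) <= 0:
        raise ValueError("mortality totals must be positive; empty table rejected")

    bands = list(MORTALITY_AGE_BANDS)
    mids = np.array([age_band_midpoint(b) for b in bands])
    band_w = np.exp(config.mortality_age_gradient * (mids - mids[0]))
    band_w /= band_w.sum()
    causes = list(config.cause_shares)
    cause_w = np.array([config.cause_shares[c] for c in causes])

    pop = config.population_base * np.exp(
        -config.population_decline * np.clip(mids - 62.5, 0.0, None)
    )

    frames = []
    for sex in SEXES:
        raw = totals[sex] * np.outer(band_w, cause_w)          # bands x causes
        deaths = _largest_remainder_round(raw.ravel(), int(round(totals[sex])))
        frames.append(pd.DataFrame({
            "sex": sex,
            "age_band": np.repeat(bands, len(causes)),
            "cause": causes * len(bands),
            "deaths": deaths,
            "population": np.repeat(np.round(pop).astype(int), len(causes)),
        }))
    return pd.concat(frames, ignore_index=True)
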
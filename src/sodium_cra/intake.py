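"""Usual-intake distributions for baseline and counterfactual scenarios.

Two distinct counterfactual mechanisms feed the risk-assessment engine:

* the reformulation scenario re-runs the recall arithmetic on a capped
  food supply and re-estimates usual-intake distributions from the
  modified respondent-day intakes;
* population-target scenarios scale every stratum's mean by the single
  ratio r = target / population baseline mean, carrying the standard
  deviation along so the coefficient of variation of each stratum is
  preserved.

Usual-intake estimation here is a moment-based stand-in for full
measurement-error modelling of repeat 24-h recalls: the stratum usual mean
is the survey-weighted mean of person means, and the between-person
(usual) variance is the variance of person means minus the within-person
variance attenuated by the average number of recall days.  It does not
model covariates (recall sequence, weekday, misreporting status) the way
the National Cancer Institute method does; see docs/methods.md.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Energy-misreporting boundaries as fractions of estimated energy
#: requirement: reported/EER <= 0.70 is under-reporting ("at or less than
#: 70%"), > 1.42 is over-reporting ("more than 142%").
UNDER_REPORT_MAX = 0.70
OVER_REPORT_MIN = 1.42


# --------------------------------------------------------------------------
# Misreporting
# --------------------------------------------------------------------------

def classify_misreporting(reported_kcal, eer_kcal):
    """Classify energy misreporting from reported intake vs requirement.

    Returns ``"under"`` when reported/EER <= 0.70 (the boundary itself is
    under-reporting), ``"over"`` when the ratio exceeds 1.42, else
    ``"plausible"``.  Vectorized: array inputs give an object array.
    """
    rep = np.asarray(reported_kcal, dtype=float)
    eer = np.asarray(eer_kcal, dtype=float)
    if np.any(eer <= 0):
        raise ValueError("EER must be positive")
    if np.any(rep <= 0):
        raise ValueError("reported energy must be positive")
    ratio = rep / eer
    out = np.where(ratio <= UNDER_REPORT_MAX, "under",
                   np.where(ratio > OVER_REPORT_MIN, "over", "plausible"))
    if np.isscalar(reported_kcal) and np.isscalar(eer_kcal):
        return str(out)
    return out


# --------------------------------------------------------------------------
# Usual-intake estimation (moment-based stand-in)
# --------------------------------------------------------------------------

def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _weighted_var(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted variance with a frequency-weight small-sample correction."""
    m = _weighted_mean(x, w)
    sw = np.sum(w)
    n = len(x)
    if n < 2:
        return 0.0
    return float(np.sum(w * (x - m) ** 2) / sw * n / (n - 1))


def estimate_usual_distribution(
    day_intakes: pd.DataFrame,
    respondents: pd.DataFrame,
    var_floor: float = 1.0,
) -> pd.DataFrame:
    """Estimate per-stratum usual-intake mean and SD from repeat recalls.

    Parameters
    ----------
    day_intakes : frame with respondent_id, day_index, sodium_mg.
    respondents : frame with respondent_id, sex, age_group and optionally
        weight (survey weight, default 1).
    var_floor : lower bound (mg^2) applied to the between-person variance
        after decomposition, so the returned SD is always positive even
        when the within-person variance swamps the observed variance of
        person means.

    Returns
    -------
    frame with sex, age_group, n, mean_mg, sd_mg, within_sd_mg, mean_days.

    Notes
    -----
    Between-person variance is estimated as
    ``max(var(person means) - within_var / mean_days, var_floor)`` where
    ``within_var`` pools the day-to-day variance of respondents with two
    recalls.  Strata with no repeat recalls fall back to the total
    variance of person means, with a logged warning (the usual SD is then
    overstated by the within-person component).
    """
    req = {"respondent_id", "day_index", "sodium_mg"}
    if not req <= set(day_intakes.columns):
        raise ValueError(f"day_intakes needs columns {sorted(req)}")
    req = {"respondent_id", "sex", "age_group"}
    if not req <= set(respondents.columns):
        raise ValueError(f"respondents needs columns {sorted(req)}")

    resp = respondents.copy()
    if "weight" not in resp.columns:
        resp["weight"] = 1.0

    person = (
        day_intakes.groupby("respondent_id")["sodium_mg"]
        .agg(person_mean="mean", n_days="count", day_var=lambda s: s.var(ddof=1))
        .reset_index()
    )
    merged = person.merge(resp, on="respondent_id", how="inner")
    if len(merged) < len(person):
        raise ValueError("day intakes include respondents missing from the roster")

    rows = []
    for (sex, group), sub in merged.groupby(["sex", "age_group"], sort=True):
        if len(sub) < 2:
            raise ValueError(f"degenerate stratum ({sex}, {group}): fewer than 2 persons")
        w = sub["weight"].to_numpy(float)
        pm = sub["person_mean"].to_numpy(float)
        mean = _weighted_mean(pm, w)
        total_var = _weighted_var(pm, w)
        repeat = sub[sub["n_days"] >= 2]
        mean_days = _weighted_mean(sub["n_days"].to_numpy(float), w)
        if len(repeat) >= 2:
            wv = repeat["weight"].to_numpy(float)
            within_var = _weighted_mean(repeat["day_var"].to_numpy(float), wv)
            # person means average n_days draws, so they carry within/d noise
            between_var = total_var - within_var / mean_days
        else:
            logger.warning(
                "stratum (%s, %s) has no repeat recalls; usual SD falls back "
                "to the total SD of person means", sex, group,
            )
            within_var = 0.0
            between_var = total_var
        between_var = max(between_var, var_floor)
        rows.append(
            (sex, group, len(sub), mean, float(np.sqrt(between_var)),
             float(np.sqrt(within_var)), mean_days)
        )
    return pd.DataFrame(
        rows,
        columns=["sex", "age_group", "n", "mean_mg", "sd_mg",
                 "within_sd_mg", "mean_days"],
    )


def sd_from_se(se: float, effective_n: float) -> float:
    """Recover a distributional SD from a reported standard error of the
    mean and an effective sample size: SD = SE * sqrt(n_eff)."""
    if se < 0 or effective_n <= 0:
        raise ValueError("se must be >= 0 and effective_n positive")
    return se * float(np.sqrt(effective_n))


# --------------------------------------------------------------------------
# Scenario builders
# --------------------------------------------------------------------------

def build_proportional_scenario(
    baseline: pd.DataFrame,
    population_target_mg: float,
    population_weights: pd.Series | np.ndarray | None = None,
    population_baseline_mean: float | None = None,
    clamp: bool = True,
) -> pd.DataFrame:
    """Scale every stratum toward a population-level sodium target.

    The reduction ratio r = target / population baseline mean is applied
    uniformly: mean' = r * mean and SD' = r * SD, so each stratum's
    coefficient of variation is preserved and the weighted population mean
    lands exactly on the target.

    Parameters
    ----------
    baseline : frame with sex, age_group, mean_mg, sd_mg (extra columns
        pass through untouched).
    population_weights : per-row weights for the population mean; defaults
        to a ``weight`` or ``n`` column of ``baseline``, else equal weights.
    population_baseline_mean : externally supplied population mean (e.g.
        the published all-ages mean when the stratum table is adults-only);
        computed from the weighted stratum means when omitted.
    clamp : when the target is at or above the baseline population mean,
        warn and clamp r to 1 (no increase) instead of scaling intakes up.
    """
    req = {"sex", "age_group", "mean_mg", "sd_mg"}
    if not req <= set(baseline.columns):
        raise ValueError(f"baseline table needs columns {sorted(req)}")
    if population_target_mg <= 0:
        raise ValueError("population_target_mg must be positive")

    if population_weights is None:
        if "weight" in baseline.columns:
            population_weights = baseline["weight"]
        elif "n" in baseline.columns:
            population_weights = baseline["n"]
        else:
            population_weights = np.ones(len(baseline))
    w = np.asarray(population_weights, dtype=float)
    if len(w) != len(baseline):
        raise ValueError("population_weights length mismatch")

    if population_baseline_mean is None:
        population_baseline_mean = _weighted_mean(
            baseline["mean_mg"].to_numpy(float), w
        )
    r = population_target_mg / population_baseline_mean
    if r >= 1.0 and clamp:
        if r > 1.0:
            logger.warning(
                "target %.0f mg/d is above the baseline population mean %.0f "
                "mg/d; nothing to reduce (r clamped to 1)",
                population_target_mg, population_baseline_mean,
            )
        r = min(r, 1.0)

    out = baseline.copy()
    out["mean_mg"] = baseline["mean_mg"] * r
    out["sd_mg"] = baseline["sd_mg"] * r
    out["scaling_ratio"] = r
    return out


def build_reformulation_scenario(
    items: pd.DataFrame,
    capped_profiles: pd.DataFrame,
    respondents: pd.DataFrame,
    var_floor: float = 1.0,
) -> pd.DataFrame:
    """Usual-intake table under the reformulated (capped) food supply.

    Re-runs the recall arithmetic with the capped profile densities and
    re-estimates the per-stratum usual distributions.
    """
    from .reformulation import daily_sodium

    days = daily_sodium(items, capped_profiles)
    return estimate_usual_distribution(days, respondents, var_floor=var_floor)


def assemble_scenario_table(
    baseline: pd.DataFrame, scenarios: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Stack baseline and scenario intake tables into one long frame.

    Returns columns scenario, sex, age_group, mean_mg, sd_mg; scenario
    "baseline" first, then the given scenarios in insertion order.
    """
    keep = ["sex", "age_group", "mean_mg", "sd_mg"]
    parts = [baseline[keep].assign(scenario="baseline")]
    for name, tab in scenarios.items():
        parts.append(tab[keep].assign(scenario=name))
    out = pd.concat(parts, ignore_index=True)
    return out[["scenario"] + keep]
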
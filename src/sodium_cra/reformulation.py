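"""Food-supply reformulation: capping product sodium at category targets.

The reformulation counterfactual asks what dietary sodium intakes would
have been had every packaged product complied with its food category's
benchmark sodium target.  The transformation is:

1. ``cap_to_targets`` — any product whose sodium density (mg/100 g)
   exceeds its category target is set to the target ("reformulated");
   products below target, or in categories without a target, are untouched.
2. ``aggregate_profiles`` — recall food profiles matched to branded
   products take the arithmetic mean density of their matched products;
   unmatched profiles keep their generic database value.
3. ``daily_sodium`` — per respondent-day sodium is the sum over recall
   items of amount_g x density / 100.

``dri_cutpoint_stats`` computes the survey-weighted share of each stratum
at or below the Adequate Intake (1500 mg/d) and above the Chronic Disease
Risk Reduction level (2300 mg/d), the DRI cut-point method applied to
per-person usual means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AI_MG, CDRR_MG

logger = logging.getLogger(__name__)

PRODUCT_COLUMNS = ["product_id", "category_id", "sodium_mg_per_100g"]
TARGET_COLUMNS = ["category_id", "target_mg_per_100g"]
PROFILE_COLUMNS = ["profile_id", "sodium_mg_per_100g", "source"]
RECALL_COLUMNS = ["respondent_id", "day_index", "profile_id", "amount_g"]


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns {missing}")


def cap_to_targets(products: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Cap each product's sodium density at its category benchmark target.

    Returns a copy of ``products`` with ``sodium_mg_per_100g`` replaced by
    ``min(density, target)`` where a target exists, plus a boolean
    ``capped`` column marking exactly the products that were above target.
    Uncategorized products (null ``category_id``) and products in
    categories without a target pass through unchanged.
    """
    _require_columns(products, PRODUCT_COLUMNS, "products")
    _require_columns(targets, TARGET_COLUMNS, "targets")
    if targets["category_id"].duplicated().any():
        dups = targets.loc[targets["category_id"].duplicated(), "category_id"].tolist()
        raise ValueError(f"duplicate sodium target for categories {dups}")
    if (products["sodium_mg_per_100g"] < 0).any():
        raise ValueError("sodium densities must be non-negative")
    if (targets["target_mg_per_100g"] <= 0).any():
        raise ValueError("targets must be positive")

    out = products.copy()
    target_map = targets.set_index("category_id")["target_mg_per_100g"]
    t = out["category_id"].map(target_map)
    out["capped"] = t.notna() & (out["sodium_mg_per_100g"] > t)
    out.loc[out["capped"], "sodium_mg_per_100g"] = t[out["capped"]]
    n_capped = int(out["capped"].sum())
    logger.info("capped %d of %d products to category targets", n_capped, len(out))
    return out


def aggregate_profiles(
    products: pd.DataFrame,
    match_map: dict[str, list],
    generic: pd.DataFrame,
) -> pd.DataFrame:
    """Rebuild aggregate food profiles from a (possibly capped) supply.

    ``match_map`` sends a recall food profile id to the branded products it
    was matched with; matched profiles get the unweighted mean density of
    those products.  Profiles absent from the map (or mapped to an empty
    list) fall back to their generic density from ``generic``; a profile
    with neither is an error.
    """
    _require_columns(products, PRODUCT_COLUMNS, "products")
    _require_columns(generic, ["profile_id", "sodium_mg_per_100g"], "generic profiles")

    density = products.set_index("product_id")["sodium_mg_per_100g"]
    generic_density = generic.set_index("profile_id")["sodium_mg_per_100g"]

    rows = []
    profile_ids = list(dict.fromkeys(list(generic["profile_id"]) + list(match_map)))
    for pid in profile_ids:
        matched = match_map.get(pid, [])
        unknown = [m for m in matched if m not in density.index]
        if unknown:
            raise ValueError(f"profile {pid!r} matched to unknown products {unknown}")
        if matched:
            rows.append((pid, float(density.loc[matched].mean()), "matched_aggregate"))
        elif pid in generic_density.index:
            rows.append((pid, float(generic_density.loc[pid]), "unmatched_generic"))
        else:
            raise ValueError(
                f"profile {pid!r} has no matched products and no generic value"
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def daily_sodium(items: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per respondent-day sodium intake (mg) from recall items.

    Each item contributes amount_g x profile density / 100.  Returns a
    frame with columns respondent_id, day_index, sodium_mg covering every
    (respondent, day) present in ``items``.
    """
    _require_columns(items, RECALL_COLUMNS, "recall items")
    _require_columns(profiles, ["profile_id", "sodium_mg_per_100g"], "profiles")
    if (items["amount_g"] <= 0).any():
        raise ValueError("item amounts must be positive")

    density = profiles.set_index("profile_id")["sodium_mg_per_100g"]
    d = items["profile_id"].map(density)
    if d.isna().any():
        bad = sorted(items.loc[d.isna(), "profile_id"].unique().tolist())
        raise ValueError(f"recall items reference unknown profiles {bad}")
    contrib = items.assign(sodium_mg=items["amount_g"] * d / 100.0)
    out = (
        contrib.groupby(["respondent_id", "day_index"], as_index=False)["sodium_mg"]
        .sum()
    )
    return out


def dri_cutpoint_stats(
    person_means: pd.DataFrame,
    ai_mg: float = AI_MG,
    cdrr_mg: float = CDRR_MG,
) -> pd.DataFrame:
    """Survey-weighted DRI cut-point proportions per stratum.

    ``person_means`` needs columns sex, age_group, usual_mg and optionally
    weight (default 1).  "Below AI" counts intakes at or below ``ai_mg``
    (the AI itself counts); "above CDRR" is strictly greater than
    ``cdrr_mg``.  Returns per-stratum rows with columns sex, age_group, n,
    pct_below_ai, pct_above_cdrr.
    """
    _require_columns(person_means, ["sex", "age_group", "usual_mg"], "person means")
    df = person_means.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if (df["weight"] < 0).any():
        raise ValueError("weights must be non-negative")

    rows = []
    for (sex, group), sub in df.groupby(["sex", "age_group"], sort=True):
        w = sub["weight"].to_numpy(float)
        if len(sub) == 0 or w.sum() == 0:
            raise ValueError(f"empty stratum ({sex}, {group})")
        x = sub["usual_mg"].to_numpy(float)
        below = float(w[x <= ai_mg].sum() / w.sum() * 100.0)
        above = float(w[x > cdrr_mg].sum() / w.sum() * 100.0)
        rows.append((sex, group, len(sub), below, above))
    return pd.DataFrame(
        rows, columns=["sex", "age_group", "n", "pct_below_ai", "pct_above_cdrr"]
    )
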
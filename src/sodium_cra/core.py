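"""Shared data model for the sodium comparative-risk-assessment pipeline.

This module holds the vocabulary every stage speaks: sex and age strata,
ICD-10 cardiovascular cause groups, the sodium-to-salt unit conversion, and
the epidemiological parameter set (salt -> systolic blood pressure slopes
and relative risks per 20 mmHg of usual SBP) read from a versioned
parameter file.

Conventions
-----------
* Sodium is carried in mg/day at the I/O boundary; all risk computation
  downstream is in grams of salt (NaCl) per day.
* Age strata come in two resolutions: broad adult DRI groups (19-30,
  31-50, 51-70, 71+) used for intake distributions, and 5-year mortality
  bands (20-24 ... 85+).  A 5-year band maps to the broad group / RR age
  range containing its midpoint.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

SEXES = ("male", "female")

#: Adult Dietary Reference Intake age groups, ordered, with closed bounds.
ADULT_AGE_GROUPS: dict[str, tuple[int, int]] = {
    "19-30": (19, 30),
    "31-50": (31, 50),
    "51-70": (51, 70),
    "71+": (71, 150),
}

#: Child/adolescent group used only for descriptive outputs, never for the
#: impact model.
CHILD_AGE_GROUP = "1-18"

#: ICD-10 cardiovascular cause groups in scope.
CAUSES: dict[str, str] = {
    "I20-25": "Ischaemic heart diseases",
    "I60-69": "Cerebrovascular diseases (stroke)",
    "I50": "Heart failure",
    "I71": "Aortic aneurysm",
    "I26": "Pulmonary embolism",
    "I05-09": "Rheumatic heart disease",
    "I10-15": "Hypertensive disease",
}

#: 5-year mortality age bands, 20-24 through 85+.
MORTALITY_AGE_BANDS = tuple(
    [f"{lo}-{lo + 4}" for lo in range(20, 85, 5)] + ["85+"]
)

#: Sodium Adequate Intake and Chronic Disease Risk Reduction cut points for
#: adults (mg/day).
AI_MG = 1500.0
CDRR_MG = 2300.0

_Z975 = 1.959963984540054


# --------------------------------------------------------------------------
# Unit conversion
# --------------------------------------------------------------------------

def sodium_to_salt(sodium_mg):
    """Convert sodium (mg/day) to salt (g/day): salt = sodium * 2.5 / 1000.

    Accepts scalars or array-likes; rejects negative input.
    """
    arr = np.asarray(sodium_mg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("sodium_mg must be non-negative")
    out = arr * 2.5 / 1000.0
    return float(out) if np.isscalar(sodium_mg) else out


def salt_to_sodium(salt_g):
    """Inverse of :func:`sodium_to_salt` (g salt -> mg sodium)."""
    arr = np.asarray(salt_g, dtype=float)
    if np.any(arr < 0):
        raise ValueError("salt_g must be non-negative")
    out = arr * 1000.0 / 2.5
    return float(out) if np.isscalar(salt_g) else out


# --------------------------------------------------------------------------
# Age handling
# --------------------------------------------------------------------------

_BAND_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_OPEN_BAND_RE = re.compile(r"^(\d+)\+$")


def age_band_midpoint(band: str) -> float:
    """Midpoint of an age band label such as ``"30-34"`` or ``"85+"``.

    Closed bands use the arithmetic midpoint of their integer endpoints
    (30-34 -> 32.0).  Open bands ``"N+"`` use N + 2.5, the midpoint of the
    implied 5-year span.
    """
    m = _BAND_RE.match(band.strip())
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"invalid age band {band!r}")
        return (lo + hi) / 2.0
    m = _OPEN_BAND_RE.match(band.strip())
    if m:
        return int(m.group(1)) + 2.5
    raise ValueError(f"unparseable age band {band!r}")


def age_group_for(age: float, include_children: bool = False) -> str:
    """Map an exact age (years) to its DRI age group."""
    for label, (lo, hi) in ADULT_AGE_GROUPS.items():
        if lo <= age <= hi:
            return label
    if include_children and 1 <= age < 19:
        return CHILD_AGE_GROUP
    raise ValueError(f"age {age} outside the adult DRI groups")


def age_group_for_band(band: str) -> str:
    """Map a 5-year mortality band to the DRI group holding its midpoint."""
    mid = age_band_midpoint(band)
    # 19-30 also absorbs the 20-24 band whose midpoint (22) it contains.
    return age_group_for(mid)


def band_is_under_75(band: str) -> bool:
    return age_band_midpoint(band) < 75.0


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    """A sex x DRI age-group population cell."""

    sex: str
    age_group: str
    population_weight: float = 1.0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in ADULT_AGE_GROUPS and self.age_group != CHILD_AGE_GROUP:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.population_weight < 0:
            raise ValueError("population_weight must be non-negative")


@dataclass(frozen=True)
class IntakeDistribution:
    """Parametric usual-intake distribution for one stratum and scenario.

    ``mean_mg``/``sd_mg`` are sodium mg/day; the CRA engine converts to
    salt g/day internally.  ``form`` selects the distribution family;
    ``truncated_at_zero`` renormalizes the density on [0, inf).
    """

    stratum: Stratum
    mean_mg: float
    sd_mg: float
    form: Literal["normal", "lognormal"] = "normal"
    truncated_at_zero: bool = True

    def __post_init__(self):
        if not self.mean_mg > 0:
            raise ValueError("mean_mg must be positive")
        if not self.sd_mg > 0:
            raise ValueError("sd_mg must be positive")
        if self.form not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution form {self.form!r}")

    @property
    def mean_salt_g(self) -> float:
        return sodium_to_salt(self.mean_mg)

    @property
    def sd_salt_g(self) -> float:
        # Linear rescale: SD transforms like the mean under a unit change.
        return self.sd_mg * 2.5 / 1000.0


# --------------------------------------------------------------------------
# Epidemiological parameters
# --------------------------------------------------------------------------

class BetaEntry(BaseModel):
    """Systolic-BP response to salt: slope in mmHg per g/day of salt."""

    age_min: int = Field(ge=0)
    age_max: int = Field(le=200)
    slope: float = Field(ge=0.0, description="mmHg SBP per g/day salt")
    se: float = Field(ge=0.0)
    source: str

    @model_validator(mode="after")
    def _ordered(self):
        if self.age_max < self.age_min:
            raise ValueError("age_max < age_min in beta entry")
        return self

    def contains(self, age: float) -> bool:
        return self.age_min <= age <= self.age_max

    def distance(self, age: float) -> float:
        if self.contains(age):
            return 0.0
        return min(abs(age - self.age_min), abs(age - self.age_max))


class RR20Entry(BaseModel):
    """Relative risk of cause-specific CVD death per 20 mmHg higher usual SBP."""

    cause: str
    age_min: int = Field(ge=0)
    age_max: int = Field(le=200)
    rr: float
    ci_low: float
    ci_high: float
    source: str

    @field_validator("cause")
    @classmethod
    def _known_cause(cls, v):
        if v not in CAUSES:
            raise ValueError(f"unknown cause {v!r}; expected one of {sorted(CAUSES)}")
        return v

    @model_validator(mode="after")
    def _valid(self):
        if self.age_max < self.age_min:
            raise ValueError("age_max < age_min in rr20 entry")
        if self.rr < 1.0:
            raise ValueError(
                f"rr20 must be >= 1 for CVD causes, got {self.rr} for {self.cause}"
            )
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValueError(
                f"rr20 CI ({self.ci_low}, {self.ci_high}) must bracket rr={self.rr}"
            )
        return self

    @property
    def log_se(self) -> float:
        """SE of ln(RR) recovered from the 95% CI."""
        if self.ci_high == self.ci_low:
            return 0.0
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * _Z975)

    def contains(self, age: float) -> bool:
        return self.age_min <= age <= self.age_max

    def distance(self, age: float) -> float:
        if self.contains(age):
            return 0.0
        return min(abs(age - self.age_min), abs(age - self.age_max))


class RRParameterSet(BaseModel):
    """Versioned dose-response parameter set driving the CRA engine."""

    version: int = 1
    beta: list[BetaEntry]
    rr20: list[RR20Entry]

    @model_validator(mode="after")
    def _non_empty(self):
        if not self.beta or not self.rr20:
            raise ValueError("parameter set must contain beta and rr20 entries")
        return self

    # -- resolution (nearest-band fallback) --------------------------------

    def beta_for(self, age: float) -> BetaEntry:
        """The slope entry for an exact age, with nearest-range fallback."""
        inside = [e for e in self.beta if e.contains(age)]
        if len(inside) > 1:
            raise ValueError(f"overlapping beta entries at age {age}")
        if inside:
            return inside[0]
        return min(self.beta, key=lambda e: (e.distance(age), e.age_min))

    def rr20_for(self, cause: str, age: float) -> RR20Entry:
        """The RR-per-20-mmHg entry for (cause, age), nearest-range fallback."""
        entries = [e for e in self.rr20 if e.cause == cause]
        if not entries:
            raise ValueError(f"no rr20 entries for cause {cause!r}")
        inside = [e for e in entries if e.contains(age)]
        if len(inside) > 1:
            raise ValueError(f"overlapping rr20 entries for {cause} at age {age}")
        if inside:
            return inside[0]
        return min(entries, key=lambda e: (e.distance(age), e.age_min))

    def causes(self) -> list[str]:
        return sorted({e.cause for e in self.rr20})


def default_parameter_path() -> Path:
    return Path(__file__).parent / "data" / "parameters.yaml"


def load_parameters(path: str | Path | None = None) -> RRParameterSet:
    """Read an RRParameterSet from a YAML or JSON parameter file.

    With no argument, loads the bundled default transcribed from the
    published salt->SBP and SBP->CVD meta-analyses (see each entry's
    ``source`` string).
    """
    p = Path(path) if path is not None else default_parameter_path()
    if not p.exists():
        raise FileNotFoundError(p)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not raw:
        raise ValueError(f"parameter file {p} is empty: no parameters")
    return RRParameterSet.model_validate(raw)


def save_parameters(params: RRParameterSet, path: str | Path) -> None:
    """Write a parameter set back out (YAML or JSON by suffix)."""
    p = Path(path)
    data = params.model_dump()
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# --------------------------------------------------------------------------
# Mortality table I/O
# --------------------------------------------------------------------------

MORTALITY_COLUMNS = ["sex", "age_band", "cause", "deaths", "population"]


def validate_mortality(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a deaths-by-sex/age-band/cause table and return a clean copy."""
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mortality table missing columns {missing}")
    out = df[MORTALITY_COLUMNS].copy()
    bad_sex = set(out["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)}")
    bad_cause = set(out["cause"]) - set(CAUSES)
    if bad_cause:
        raise ValueError(f"unknown causes {sorted(bad_cause)}")
    for band in out["age_band"].unique():
        age_band_midpoint(band)  # raises on malformed labels
    if (out["deaths"] < 0).any():
        raise ValueError("deaths must be non-negative")
    if (out["population"] < 0).any():
        raise ValueError("population must be non-negative")
    dup = out.duplicated(subset=["sex", "age_band", "cause"])
    if dup.any():
        raise ValueError("duplicate (sex, age_band, cause) rows in mortality table")
    return out


def load_mortality(path: str | Path) -> pd.DataFrame:
    return validate_mortality(pd.read_csv(path))


# --------------------------------------------------------------------------
# Scenario definitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioDefinition:
    """A counterfactual: either supply reformulation or proportional scaling
    of every stratum mean toward a population-level sodium target (mg/day)."""

    name: str
    mechanism: Literal["reformulation", "proportional_scaling"]
    population_target_mg: float

    def __post_init__(self):
        if not self.population_target_mg > 0:
            raise ValueError("population_target_mg must be positive")
        if self.mechanism not in ("reformulation", "proportional_scaling"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


#: The three study scenarios: reformulated food supply aimed at a 2300 mg/d
#: population mean, and proportional reductions to the WHO (2000 mg/d) and
#: Adequate Intake (1500 mg/d) levels.
STUDY_SCENARIOS = (
    ScenarioDefinition("A", "reformulation", 2300.0),
    ScenarioDefinition("B", "proportional_scaling", 2000.0),
    ScenarioDefinition("C", "proportional_scaling", 1500.0),
)


def default_intake_table_path() -> Path:
    return Path(__file__).parent / "data" / "canadian_adult_sodium_2015.csv"


def load_intake_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a baseline (+ optional reformulation-scenario) intake table.

    Columns: sex, age_group, n, baseline_mean_mg, baseline_sd_mg and
    optionally scenarioA_mean_mg, scenarioA_sd_mg.  A row with
    sex == "total" carries the all-ages population mean used as the
    denominator for proportional scenarios.
    """
    p = Path(path) if path is not None else default_intake_table_path()
    df = pd.read_csv(p)
    required = {"sex", "age_group", "n", "baseline_mean_mg", "baseline_sd_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intake table missing columns {sorted(missing)}")
    return df
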
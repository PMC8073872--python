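"""EQ-5D utility scoring and health-state utility estimation.

EQ-5D instruments describe health on five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at 3 or 5
levels.  A *value set* (tariff) maps every profile of levels to a utility on
a scale anchored at 1 for full health and 0 for death, with a floor below
zero for states worse than death.  This module scores profiles under
pluggable value sets — either a full lookup table or an additive
coefficient scheme — estimates the utility increment associated with a good
treatment response as the difference in mean change-from-baseline between
responders and non-responders, and applies multiplicative age-related
utility decrements.

Published tariffs (crosswalks, national value sets) are consumed as data
files; the value sets constructed here are synthetic and exist so the rest
of the pipeline can be exercised and tested without any external table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DIMENSIONS = ("mobility", "self_care", "usual_activities",
              "pain_discomfort", "anxiety_depression")

#: short column codes used in participant tables, in DIMENSIONS order
DIM_CODES = ("mo", "sc", "ua", "pd", "ad")


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D health state: a level per dimension, 1 = no problems."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (self.mobility, self.self_care, self.usual_activities,
                self.pain_discomfort, self.anxiety_depression)

    def validate(self, n_levels: int) -> None:
        for dim, lev in zip(DIMENSIONS, self.levels):
            if not (1 <= lev <= n_levels):
                raise ValueError(
                    f"{dim} level {lev} outside 1..{n_levels}")


class InstrumentMismatchError(ValueError):
    """Profile instrument does not match the value set instrument."""


@dataclass(frozen=True)
class ValueSet:
    """A tariff mapping EQ-5D profiles to utilities.

    Exactly one of ``lookup`` and ``coefficients`` is set.  The coefficient
    scheme is the conventional additive form: a constant decrement applied
    whenever any dimension is above level 1, per-dimension per-level
    decrements (level 1 contributes 0), and an optional extra decrement when
    any dimension is at the worst level.
    """

    name: str
    instrument: str                       # "3L" or "5L"
    floor: float
    lookup: Mapping[tuple[int, ...], float] | None = None
    coefficients: Mapping | None = None

    @property
    def n_levels(self) -> int:
        return 3 if self.instrument == "3L" else 5

    def __post_init__(self):
        if self.instrument not in ("3L", "5L"):
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if (self.lookup is None) == (self.coefficients is None):
            raise ValueError("provide exactly one of lookup/coefficients")
        full = tuple([1] * 5)
        if self.lookup is not None:
            n_states = self.n_levels ** 5
            if len(self.lookup) != n_states:
                raise ValueError(
                    f"lookup covers {len(self.lookup)} states, "
                    f"expected {n_states}")
            if not math.isclose(self.lookup[full], 1.0, abs_tol=1e-12):
                raise ValueError("full-health state must score exactly 1")
            lo = min(self.lookup.values())
            if lo < self.floor - 1e-9:
                raise ValueError("lookup scores fall below the floor")


def score_profile(profile: EQ5DProfile | Sequence[int],
                  valueset: ValueSet) -> float:
    """Score a single profile under a value set.

    The full-health profile scores exactly 1 under any anchored value set;
    every score lies in ``[floor, 1]``.
    """
    if isinstance(profile, EQ5DProfile):
        levels = profile.levels
    else:
        levels = tuple(int(v) for v in profile)
    if len(levels) != 5:
        raise ValueError("a profile has five dimension levels")
    n = valueset.n_levels
    for lev in levels:
        if not 1 <= lev <= n:
            raise InstrumentMismatchError(
                f"level {lev} invalid for a {valueset.instrument} "
                f"value set")
    if valueset.lookup is not None:
        try:
            return float(valueset.lookup[levels])
        except KeyError:
            raise KeyError(f"state {levels} missing from lookup table")
    return _score_coefficients(levels, valueset)


def _score_coefficients(levels: tuple[int, ...], valueset: ValueSet) -> float:
    c = valueset.coefficients
    if all(l == 1 for l in levels):
        return 1.0
    u = 1.0 - float(c.get("any_problem", 0.0))
    worst = valueset.n_levels
    for dim, lev in zip(DIMENSIONS, levels):
        if lev > 1:
            u -= float(c["decrements"][dim][lev])
    if any(l == worst for l in levels) and "worst_level_any" in c:
        u -= float(c["worst_level_any"])
    return u


def expand_lookup(valueset: ValueSet) -> dict[tuple[int, ...], float]:
    """Enumerate every health state and its score as a full lookup table."""
    n = valueset.n_levels
    return {state: score_profile(state, valueset)
            for state in itertools.product(range(1, n + 1), repeat=5)}


def score_frame(df: pd.DataFrame, valueset: ValueSet,
                timepoints: Iterable[int] = (0, 6, 9, 12),
                prefix: str = "", out_prefix: str = "u") -> pd.DataFrame:
    """Score profile columns ``{prefix}{code}_{t}`` into ``{out_prefix}_{t}``.

    Rows with any missing dimension level at a time point get NaN utility.
    Returns a copy of ``df`` with the utility columns appended.
    """
    table = expand_lookup(valueset)
    keys = np.array(sorted(table))
    vals = np.array([table[tuple(k)] for k in keys])
    n = valueset.n_levels
    # radix encoding of profiles for a vectorised lookup
    radix = n ** np.arange(4, -1, -1)
    code_of = {int(np.dot(k - 1, radix)): v for k, v in zip(keys, vals)}
    out = df.copy()
    for t in timepoints:
        cols = [f"{prefix}{c}_{t}" for c in DIM_CODES]
        levels = df[cols].to_numpy(dtype=float)
        ok = ~np.isnan(levels).any(axis=1)
        u = np.full(len(df), np.nan)
        if ok.any():
            codes = ((levels[ok] - 1) @ radix).astype(int)
            u[ok] = [code_of[c] for c in codes]
        out[f"{out_prefix}_{t}"] = u
    return out


# ---------------------------------------------------------------------------
# Synthetic value sets (test tariffs; not any published national value set)

def synthetic_3l_valueset() -> ValueSet:
    """A synthetic 3L-style additive tariff with floor −0.594.

    The structure mirrors conventional 3L tariffs (constant any-problem
    term, per-dimension decrements, extra decrement when any dimension is
    at the worst level); the coefficient values are this package's own and
    are chosen so the worst state (3,3,3,3,3) scores exactly −0.594.
    """
    dec3 = dict(zip(DIMENSIONS, (0.350, 0.250, 0.150, 0.300, 0.194)))
    dec2 = dict(zip(DIMENSIONS, (0.100, 0.080, 0.050, 0.090, 0.070)))
    coeffs = {
        "any_problem": 0.081,
        "worst_level_any": 0.269,
        "decrements": {d: {2: dec2[d], 3: dec3[d]} for d in DIMENSIONS},
    }
    return ValueSet(name="synthetic-3L", instrument="3L",
                    floor=-0.594, coefficients=coeffs)


def synthetic_5l_valueset() -> ValueSet:
    """A synthetic 5L additive tariff with a dense spread of scores.

    Per-dimension weights are deliberately incommensurate so that the 3125
    states map to many distinct utilities, which makes profile generation
    by nearest-utility quantisation well behaved.
    """
    weights = dict(zip(DIMENSIONS, (0.331, 0.253, 0.217, 0.307, 0.271)))
    grades = {2: 0.115, 3: 0.271, 4: 0.553, 5: 1.0}
    coeffs = {
        "any_problem": 0.042,
        "decrements": {
            d: {lv: round(weights[d] * g, 6) for lv, g in grades.items()}
            for d in DIMENSIONS
        },
    }
    floor = 1.0 - 0.042 - sum(weights.values())
    return ValueSet(name="synthetic-5L", instrument="5L",
                    floor=round(floor, 6), coefficients=coeffs)


def valueset_from_csv(path, name: str, instrument: str,
                      floor: float | None = None) -> ValueSet:
    """Load a full lookup value set from CSV (5 level columns + utility)."""
    df = pd.read_csv(path)
    cols = list(df.columns[:5])
    lookup = {tuple(int(v) for v in row[cols]): float(row[df.columns[5]])
              for _, row in df.iterrows()}
    if floor is None:
        floor = min(lookup.values())
    return ValueSet(name=name, instrument=instrument, floor=floor,
                    lookup=lookup)


def valueset_to_csv(valueset: ValueSet, path) -> None:
    table = expand_lookup(valueset)
    rows = [list(state) + [u] for state, u in sorted(table.items())]
    pd.DataFrame(rows, columns=list(DIM_CODES) + ["utility"]).to_csv(
        path, index=False)


def valueset_from_yaml(path) -> ValueSet:
    """Load a coefficient-scheme value set from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ValueSet(name=raw["name"], instrument=raw["instrument"],
                    floor=float(raw["floor"]),
                    coefficients=raw["coefficients"])


# ---------------------------------------------------------------------------
# Ageing decrement

@dataclass(frozen=True)
class AgeingIndex:
    """Multiplicative per-age utility adjustment factors in (0, 1].

    The index must be non-increasing with age; utilities are multiplied by
    ``factor(age)`` so an ageing cohort's utility never increases through
    the adjustment alone.
    """

    ages: tuple[int, ...]
    factors: tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) != len(self.factors):
            raise ValueError("ages and factors differ in length")
        if any(f <= 0 or f > 1 for f in self.factors):
            raise ValueError("factors must lie in (0, 1]")
        diffs = np.diff(self.factors)
        if (diffs > 1e-12).any():
            raise ValueError("ageing index must be non-increasing with age")

    def factor(self, age: float) -> float:
        a = int(math.floor(age))
        if a < self.ages[0] or a > self.ages[-1]:
            raise ValueError(f"age {a} outside index range "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return self.factors[a - self.ages[0]]


def flat_ageing_index(start_age: int = 18, end_age: int = 105) -> AgeingIndex:
    """An identity index (factor 1 at every age)."""
    ages = tuple(range(start_age, end_age + 1))
    return AgeingIndex(ages=ages, factors=(1.0,) * len(ages))


def linear_ageing_index(start_age: int = 18, end_age: int = 105,
                        annual_decrement: float = 0.002) -> AgeingIndex:
    """An index declining by a constant fraction per year of age."""
    ages = tuple(range(start_age, end_age + 1))
    factors = tuple(max(1e-6, 1.0 - annual_decrement * i)
                    for i in range(len(ages)))
    return AgeingIndex(ages=ages, factors=factors)


def apply_age_decrement(utility: float, age: float,
                        ageing_index: AgeingIndex) -> float:
    """Age-adjust a utility; never increases it."""
    return utility * ageing_index.factor(age)


# ---------------------------------------------------------------------------
# Health-state utility estimation

@dataclass(frozen=True)
class UtilityEstimate:
    """Utility increment for good response at one assessment."""

    delta: float          # mean change (responders) − mean change (others)
    se: float
    n_responders: int
    n_nonresponders: int


@dataclass
class UtilityInputs:
    """All utility inputs the cohort model needs for one analysis."""

    u_aphasia: float
    deltas: dict[int, UtilityEstimate] = field(default_factory=dict)
    ageing_index: AgeingIndex = field(default_factory=flat_ageing_index)

    @property
    def extrapolated_delta(self) -> float:
        """The 12-month increment, carried forward beyond 12 months."""
        return self.deltas[12].delta


def estimate_state_utilities(df: pd.DataFrame, timepoint: int,
                             responder_col: str | None = None,
                             utility_prefix: str = "u") -> tuple[UtilityEstimate, float]:
    """Estimate the good-response utility increment at one assessment.

    The increment is the difference in mean utility change from baseline
    between responders and non-responders at ``timepoint``; its standard
    error is the usual two-sample SE of a difference in means.  Also
    returns the pooled baseline mean utility (the Aphasia-state utility).

    Requires utility columns ``u_0`` and ``u_{timepoint}`` and a boolean
    responder column (default ``resp_obs_{timepoint}``).
    """
    if responder_col is None:
        responder_col = f"resp_obs_{timepoint}"
    u0 = df[f"{utility_prefix}_0"].to_numpy(dtype=float)
    ut = df[f"{utility_prefix}_{timepoint}"].to_numpy(dtype=float)
    resp = df[responder_col].to_numpy(dtype=bool)
    ok = ~(np.isnan(u0) | np.isnan(ut))
    change = ut[ok] - u0[ok]
    resp = resp[ok]
    n1, n0 = int(resp.sum()), int((~resp).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"need at least 2 observations per response group at "
            f"{timepoint} months (got {n1} responders, {n0} others)")
    c1, c0 = change[resp], change[~resp]
    delta = float(c1.mean() - c0.mean())
    se = float(math.sqrt(c1.var(ddof=1) / n1 + c0.var(ddof=1) / n0))
    u_aphasia = float(u0[ok].mean())
    return UtilityEstimate(delta=delta, se=se, n_responders=n1,
                           n_nonresponders=n0), u_aphasia
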
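"""Good-response classification and transition-probability estimation.

A good response is a clinically meaningful improvement from baseline on
either co-primary outcome: an increase of 10%+ in words found correctly on
a 100-word personalised naming test, and/or an increase of 0.5+ points on
the Therapy Outcome Measures (TOM) activity scale.  Per-arm transition
probabilities for the cohort model are maximum-likelihood proportions from
the classified trial data, with the underlying event counts retained so
PSA can place beta distributions over them.  Relapse observed between the
9- and 12-month assessments is carried forward unchanged as the per-cycle
relapse probability for the remainder of the lifetime horizon; no new
responses occur after 12 months.

Mortality is common to every state and arm: an annual death probability
from a life table is combined with a post-stroke hazard multiplier and
converted to a 3-month cycle probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .synthdata import ASSESSMENTS, LifeTable


@dataclass(frozen=True)
class ResponseDefinition:
    """Thresholds of the good-response OR rule."""

    naming_threshold: float = 10.0    # words (of 100), i.e. 10%
    tom_threshold: float = 0.5        # TOM activity-scale points

    def __post_init__(self):
        if self.naming_threshold <= 0 or self.tom_threshold <= 0:
            raise ValueError("thresholds must be positive")


def classify_response(naming_baseline, naming_followup,
                      tom_baseline, tom_followup,
                      definition: ResponseDefinition = ResponseDefinition()):
    """Responder flag(s): naming gain >= threshold OR TOM gain >= threshold.

    Accepts scalars or arrays; raises if any required score is missing.
    """
    n0 = np.asarray(naming_baseline, dtype=float)
    n1 = np.asarray(naming_followup, dtype=float)
    t0 = np.asarray(tom_baseline, dtype=float)
    t1 = np.asarray(tom_followup, dtype=float)
    if any(np.isnan(x).any() for x in (n0, n1, t0, t1)):
        raise ValueError("missing scores: classify after imputation")
    flag = ((n1 - n0 >= definition.naming_threshold)
            | (t1 - t0 >= definition.tom_threshold))
    return bool(flag) if flag.ndim == 0 else flag


def classify_frame(df: pd.DataFrame,
                   definition: ResponseDefinition = ResponseDefinition()
                   ) -> pd.DataFrame:
    """Add observed-response columns ``resp_obs_{6,9,12}`` to a copy."""
    out = df.copy()
    for t in ASSESSMENTS:
        out[f"resp_obs_{t}"] = classify_response(
            df["naming_0"], df[f"naming_{t}"],
            df["tom_0"], df[f"tom_{t}"], definition)
    return out


@dataclass(frozen=True)
class ArmTransitions:
    """Event counts and ML probabilities for one arm.

    ``r6/n6``: responders / assessed at 6 months.  ``new9/d9`` and
    ``new12/d12``: new responders / prior non-responders at 9 and 12
    months.  ``rel69/d69`` and ``rel912/d912``: relapses / prior
    responders across the 6→9 and 9→12 month intervals.
    """

    arm: str
    r6: int
    n6: int
    new9: int
    d9: int
    new12: int
    d12: int
    rel69: int
    d69: int
    rel912: int
    d912: int

    def __post_init__(self):
        for r, n in ((self.r6, self.n6), (self.new9, self.d9),
                     (self.new12, self.d12), (self.rel69, self.d69),
                     (self.rel912, self.d912)):
            if not 0 <= r <= n:
                raise ValueError(f"invalid counts {r}/{n}")

    @staticmethod
    def _p(r: int, n: int) -> float:
        if n == 0:
            raise ZeroDivisionError(
                "zero denominator: no participants at risk")
        return r / n

    @property
    def p_response6(self) -> float:
        return self._p(self.r6, self.n6)

    @property
    def p_new_response9(self) -> float:
        return self._p(self.new9, self.d9)

    @property
    def p_new_response12(self) -> float:
        return self._p(self.new12, self.d12)

    @property
    def p_relapse_6_9(self) -> float:
        return self._p(self.rel69, self.d69)

    @property
    def p_relapse_9_12(self) -> float:
        return self._p(self.rel912, self.d912)


@dataclass
class TransitionSet:
    """Per-arm transition inputs plus the post-12-month relapse rate."""

    arms: dict[str, ArmTransitions] = field(default_factory=dict)

    def to_json(self, path) -> None:
        raw = {arm: asdict(at) for arm, at in self.arms.items()}
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransitionSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(arms={a: ArmTransitions(**d) for a, d in raw.items()})


def estimate_transitions(df: pd.DataFrame,
                         definition: ResponseDefinition = ResponseDefinition(),
                         response_cols: str = "resp_obs") -> TransitionSet:
    """Count response/relapse events per arm from classified data.

    If the response columns are absent they are derived with
    ``classify_frame`` first.  Counts (not just proportions) are retained
    because PSA parameterises beta distributions directly from events and
    non-events.
    """
    if f"{response_cols}_6" not in df.columns:
        df = classify_frame(df, definition)
    out = TransitionSet()
    for arm, g in df.groupby("arm", sort=False):
        r6 = g[f"{response_cols}_6"].to_numpy(dtype=bool)
        r9 = g[f"{response_cols}_9"].to_numpy(dtype=bool)
        r12 = g[f"{response_cols}_12"].to_numpy(dtype=bool)
        out.arms[arm] = ArmTransitions(
            arm=arm,
            r6=int(r6.sum()), n6=len(g),
            new9=int((~r6 & r9).sum()), d9=int((~r6).sum()),
            new12=int((~r9 & r12).sum()), d12=int((~r9).sum()),
            rel69=int((r6 & ~r9).sum()), d69=int(r6.sum()),
            rel912=int((r9 & ~r12).sum()), d912=int(r9.sum()),
        )
    return out


def extrapolate_relapse(arm: ArmTransitions) -> float:
    """Per-cycle relapse probability beyond 12 months.

    The relapse probability observed across the 9→12 month interval (one
    model cycle) is assumed constant for the remainder of the horizon.
    """
    return arm.p_relapse_9_12


def cycle_mortality(life_table: LifeTable, age: float,
                    multiplier: float = 1.0) -> float:
    """3-month death probability at ``age`` under a post-stroke multiplier.

    The multiplier acts on the hazard scale — ``h = -ln(1-q)``,
    ``q* = 1 - exp(-m h)`` — which keeps the adjusted annual probability
    valid for any multiplier > 0, and the cycle probability is
    ``1 - (1-q*)^(1/4)``.  Mortality is identical across health states and
    arms: the interventions are assumed not to affect life expectancy.
    """
    if multiplier <= 0:
        raise ValueError("mortality multiplier must be positive")
    q = life_table.q(age)
    if q >= 1.0:
        return 1.0
    h = -math.log1p(-q)
    q_star = 1.0 - math.exp(-multiplier * h)
    return 1.0 - (1.0 - q_star) ** 0.25
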
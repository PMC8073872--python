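"""Lifetime Markov cohort model with tunnel states.

Five states: Aphasia; Good response at 6 months (tunnel); Good response at
9 months (tunnel); Good response at 12 months and beyond; Dead.  The
cohort starts fully in Aphasia and moves in 3-month cycles.  Response
transitions happen only at the assessment-aligned cycles (months 6, 9 and
12, i.e. when trial outcome data exist); death can occur every cycle, at a
rate common to all states and arms.  After month 12 no new responses
occur: Good-response occupancy decays through the constant per-cycle
relapse probability and mortality, and Aphasia occupancy only dies.

QALYs accrue per cycle as occupancy x state utility x 1/4 year, with an
annual-step ageing decrement and 3.5%/year discounting applied at cycle
end.  Intervention costs are one-off in year 1 and undiscounted.

The engine is written over numpy arrays so a probabilistic-sensitivity
run with thousands of parameter draws is a single vectorised pass; a
deterministic run is the one-draw special case.  An individual-level
microsimulation of the same transition rules is provided as an
independent cross-check of the cohort arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import LifeTable
from .transitions import ArmTransitions, cycle_mortality, extrapolate_relapse
from .utility import UtilityInputs

STATES = ("aphasia", "gr6", "gr9", "gr12", "dead")
A, G6, G9, G12, D = range(5)

#: cycle index (1-based month/3) at which each assessment lands
_ASSESS_CYCLE = {6: 2, 9: 3, 12: 4}


@dataclass(frozen=True)
class ModelSpec:
    """Structural settings of the cohort model."""

    start_age: float = 65.0
    terminal_age: int = 100
    discount_rate_qalys: float = 0.035
    discount_rate_costs: float = 0.0      # all costs accrue in year 1
    cycle_length_years: float = 0.25
    half_cycle_correction: bool = False
    mortality_multiplier: float = 1.7     # post-stroke hazard multiplier
    living_tolerance: float = 1e-8

    def __post_init__(self):
        if self.discount_rate_qalys < 0 or self.discount_rate_costs < 0:
            raise ValueError("discount rates must be >= 0")
        if self.terminal_age <= self.start_age:
            raise ValueError("terminal_age must exceed start_age")

    @property
    def n_cycles(self) -> int:
        # one extra year of cycles so the cohort crosses the terminal age,
        # where the life table forces q = 1 and absorbs everyone
        return int(math.ceil((self.terminal_age - self.start_age)
                             / self.cycle_length_years)) + 4


@dataclass(frozen=True)
class ArmProbs:
    """Transition probabilities for one arm (scalars or draw vectors)."""

    p_response6: float | np.ndarray
    p_new_response9: float | np.ndarray
    p_new_response12: float | np.ndarray
    p_relapse_6_9: float | np.ndarray
    p_relapse_9_12: float | np.ndarray
    p_relapse_post12: float | np.ndarray

    @classmethod
    def from_transitions(cls, at: ArmTransitions) -> "ArmProbs":
        return cls(p_response6=at.p_response6,
                   p_new_response9=at.p_new_response9,
                   p_new_response12=at.p_new_response12,
                   p_relapse_6_9=at.p_relapse_6_9,
                   p_relapse_9_12=at.p_relapse_9_12,
                   p_relapse_post12=extrapolate_relapse(at))


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -t``."""
    if t_years < 0:
        raise ValueError("time must be >= 0")
    return (1.0 + rate) ** (-t_years)


def cycle_death_probs(spec: ModelSpec, life_table: LifeTable) -> np.ndarray:
    """Per-cycle death probability for every cycle of the horizon."""
    ages = spec.start_age + spec.cycle_length_years * np.arange(spec.n_cycles)
    return np.array([cycle_mortality(life_table, a, spec.mortality_multiplier)
                     for a in ages])


def _step(occ: np.ndarray, d, cycle_next: int, p: ArmProbs) -> np.ndarray:
    """One cycle update; ``occ`` has shape (..., 5), ``d`` broadcasts."""
    surv = 1.0 - d
    a, g6, g9, g12, dead = (occ[..., i] for i in range(5))
    dead_new = dead + d * (a + g6 + g9 + g12)
    a, g6, g9, g12 = a * surv, g6 * surv, g9 * surv, g12 * surv
    if cycle_next == _ASSESS_CYCLE[6]:
        a, g6 = a * (1 - p.p_response6), a * p.p_response6 + 0 * g6
    elif cycle_next == _ASSESS_CYCLE[9]:
        relapsed = g6 * p.p_relapse_6_9
        g9 = g6 * (1 - p.p_relapse_6_9) + a * p.p_new_response9
        a = a * (1 - p.p_new_response9) + relapsed
        g6 = np.zeros_like(g9) if isinstance(g9, np.ndarray) else 0.0
    elif cycle_next == _ASSESS_CYCLE[12]:
        relapsed = g9 * p.p_relapse_9_12
        g12 = g9 * (1 - p.p_relapse_9_12) + a * p.p_new_response12
        a = a * (1 - p.p_new_response12) + relapsed
        g9 = np.zeros_like(g12) if isinstance(g12, np.ndarray) else 0.0
    elif cycle_next > _ASSESS_CYCLE[12]:
        relapsed = g12 * p.p_relapse_post12
        g12 = g12 * (1 - p.p_relapse_post12)
        a = a + relapsed
    # cycle_next == 1: no response dynamics before the first assessment
    return np.stack(np.broadcast_arrays(a, g6, g9, g12, dead_new), axis=-1)


@dataclass
class MarkovTrace:
    """Cycle-by-state occupancy for one arm (deterministic run)."""

    spec: ModelSpec
    occupancy: np.ndarray               # (n_cycles + 1, 5); row t = start of cycle t
    ages: np.ndarray
    qaly_increments: np.ndarray | None = None   # filled by accrue_qalys

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATES)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        if self.qaly_increments is not None:
            inc = np.append(self.qaly_increments, np.nan)
            df["discounted_qaly_increment"] = inc
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def life_years(self) -> float:
        """Undiscounted life-years (living occupancy x cycle length)."""
        living = 1.0 - self.occupancy[:-1, D]
        return float(living.sum() * self.spec.cycle_length_years)


def run_cohort(spec: ModelSpec, probs: ArmProbs,
               life_table: LifeTable) -> MarkovTrace:
    """Run the cohort once and return the full occupancy trace.

    Starts 100% in Aphasia; stops early once living occupancy falls below
    the configured tolerance (the life table forces q -> 1 at the terminal age,
    so the cohort is always fully absorbed).
    """
    d = cycle_death_probs(spec, life_table)
    occ = np.zeros(5)
    occ[A] = 1.0
    rows = [occ.copy()]
    for t in range(spec.n_cycles):
        occ = _step(occ, d[t], t + 1, probs)
        total = occ.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise RuntimeError(f"non-stochastic update at cycle {t}: "
                               f"row sum {total}")
        rows.append(occ.copy())
        if 1.0 - occ[D] < spec.living_tolerance:
            break
    occupancy = np.array(rows)
    ages = spec.start_age + spec.cycle_length_years * np.arange(len(rows))
    return MarkovTrace(spec=spec, occupancy=occupancy, ages=ages)


def _state_utilities(spec: ModelSpec, utilities: UtilityInputs,
                     age: float, deltas=None):
    """Utility of each living state at one cycle (increment then ageing)."""
    idx = utilities.ageing_index.factor(age)
    ua = utilities.u_aphasia
    if deltas is None:
        d6 = utilities.deltas[6].delta
        d9 = utilities.deltas[9].delta
        d12 = utilities.deltas[12].delta
    else:
        d6, d9, d12 = deltas
    return (ua * idx, (ua + d6) * idx, (ua + d9) * idx, (ua + d12) * idx)


def accrue_qalys(trace: MarkovTrace, utilities: UtilityInputs,
                 spec: ModelSpec | None = None) -> float:
    """Total discounted QALYs for a trace; stores per-cycle increments.

    Each cycle contributes occupancy x state utility x 1/4 year (e.g. three
    months at utility 0.8 yields 0.2 QALYs), discounted at cycle end.
    """
    spec = spec or trace.spec
    occ = trace.occupancy[:-1]          # occupancy during each cycle
    n = len(occ)
    inc = np.zeros(n)
    total = 0.0                         # sequential sum, matching the
    for t in range(n):                  # vectorised engine exactly
        age = spec.start_age + spec.cycle_length_years * t
        us = _state_utilities(spec, utilities, age)
        if any(u > 1.0 + 1e-9 for u in us):
            raise ValueError("state utility above 1")
        u_cycle = (occ[t, A] * us[0] + occ[t, G6] * us[1]
                   + occ[t, G9] * us[2] + occ[t, G12] * us[3])
        t_end = (t + 1) * spec.cycle_length_years
        inc[t] = (u_cycle * spec.cycle_length_years
                  * discount_factor(t_end, spec.discount_rate_qalys))
        total += inc[t]
    trace.qaly_increments = inc
    return float(total)


def arm_outcomes(trace: MarkovTrace, utilities: UtilityInputs,
                 arm_cost: float, spec: ModelSpec | None = None
                 ) -> tuple[float, float]:
    """(total cost, total discounted QALYs) for one arm.

    The cost is the one-off year-1 per-patient intervention cost,
    undiscounted; QALYs come from the cohort trace.
    """
    return float(arm_cost), accrue_qalys(trace, utilities, spec)


# ---------------------------------------------------------------------------
# Vectorised engine for PSA

def cohort_qalys_vector(spec: ModelSpec, probs: ArmProbs,
                        life_table: LifeTable, utilities: UtilityInputs,
                        deltas: tuple[np.ndarray, np.ndarray, np.ndarray]
                        ) -> np.ndarray:
    """Discounted QALYs for many parameter draws in one pass.

    ``probs`` fields and the three delta vectors are arrays of a common
    draw length m; returns a length-m QALY vector.  The occupancy history
    is not stored, so memory stays O(m).
    """
    m = np.broadcast(probs.p_response6, deltas[0]).size
    d = cycle_death_probs(spec, life_table)
    occ = np.zeros((m, 5))
    occ[:, A] = 1.0
    qalys = np.zeros(m)
    d6, d9, d12 = deltas
    ua = utilities.u_aphasia
    for t in range(spec.n_cycles):
        age = spec.start_age + spec.cycle_length_years * t
        idx = utilities.ageing_index.factor(age)
        u_cycle = idx * (occ[:, A] * ua + occ[:, G6] * (ua + d6)
                         + occ[:, G9] * (ua + d9)
                         + occ[:, G12] * (ua + d12))
        t_end = (t + 1) * spec.cycle_length_years
        qalys += (u_cycle * spec.cycle_length_years
                  * discount_factor(t_end, spec.discount_rate_qalys))
        occ = _step(occ, d[t], t + 1, probs)
        if (1.0 - occ[:, D]).max() < spec.living_tolerance:
            break
    return qalys


# ---------------------------------------------------------------------------
# Individual-level microsimulation (independent oracle)

def microsimulate(spec: ModelSpec, probs: ArmProbs, life_table: LifeTable,
                  utilities: UtilityInputs, n: int = 100_000,
                  seed: int = 0) -> dict:
    """Simulate individuals through the same transition rules.

    Returns mean discounted QALYs with a Monte-Carlo standard error, and
    mean undiscounted life-years.  This is a sampling-based implementation
    kept deliberately independent of the cohort matrix arithmetic so the
    two can be compared.
    """
    rng = np.random.default_rng(seed)
    d = cycle_death_probs(spec, life_table)
    state = np.full(n, A, dtype=np.int8)
    qalys = np.zeros(n)
    life_years = np.zeros(n)
    ua = utilities.u_aphasia
    deltas = {A: 0.0, G6: utilities.deltas[6].delta,
              G9: utilities.deltas[9].delta, G12: utilities.deltas[12].delta}
    for t in range(spec.n_cycles):
        alive = state != D
        if not alive.any():
            break
        age = spec.start_age + spec.cycle_length_years * t
        idx = utilities.ageing_index.factor(age)
        for s in (A, G6, G9, G12):
            in_s = state == s
            qalys[in_s] += ((ua + deltas[s]) * idx
                            * spec.cycle_length_years
                            * discount_factor((t + 1) * spec.cycle_length_years,
                                              spec.discount_rate_qalys))
        life_years[alive] += spec.cycle_length_years
        dies = alive & (rng.random(n) < d[t])
        state[dies] = D
        alive = state != D
        cyc = t + 1
        u = rng.random(n)
        if cyc == _ASSESS_CYCLE[6]:
            respond = alive & (state == A) & (u < probs.p_response6)
            state[respond] = G6
        elif cyc == _ASSESS_CYCLE[9]:
            in_g6 = alive & (state == G6)
            state[in_g6 & (u < probs.p_relapse_6_9)] = A
            state[in_g6 & (u >= probs.p_relapse_6_9)] = G9
            new = alive & (state == A) & ~in_g6 & (u < probs.p_new_response9)
            state[new] = G9
        elif cyc == _ASSESS_CYCLE[12]:
            in_g9 = alive & (state == G9)
            state[in_g9 & (u < probs.p_relapse_9_12)] = A
            state[in_g9 & (u >= probs.p_relapse_9_12)] = G12
            new = alive & (state == A) & ~in_g9 & (u < probs.p_new_response12)
            state[new] = G12
        elif cyc > _ASSESS_CYCLE[12]:
            in_g12 = alive & (state == G12)
            state[in_g12 & (u < probs.p_relapse_post12)] = A
    return {
        "mean_qalys": float(qalys.mean()),
        "se_qalys": float(qalys.std(ddof=1) / math.sqrt(n)),
        "mean_life_years": float(life_years.mean()),
        "se_life_years": float(life_years.std(ddof=1) / math.sqrt(n)),
    }
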
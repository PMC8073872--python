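"""Micro-costing of intervention delivery from activity logs.

Each participant's intervention cost is built bottom-up from logged
therapist and assistant minutes, travel miles, and equipment/licence
components, valued at national unit costs (2016/17 cost year by default).
Usual care is provided in every arm, so usual-care costs cancel out of the
incremental comparison and the usual-care-alone arm costs exactly zero by
construction.  All intervention costs are one-off, accrued in year 1 and
never discounted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs (GBP) for every costed item.

    Defaults are the 2016/17 national unit costs used in the trial-based
    evaluation: e.g. laptop/tablet loan £69 (a £690 purchase amortised over
    10 users across its shelf life), SLT band 6 £0.75/minute, therapy
    assistant (SLTA) band 3 £0.41/minute, travel £0.45/mile.
    """

    laptop_loan_6m: float = 69.0
    software_licence_individual: float = 250.0
    software_licence_clinician: float = 550.0
    software_licence_bundle5: float = 2200.0
    headset: float = 14.50
    puzzle_book: float = 2.50
    slt_band7_per_min: float = 0.90     # therapy-delivery training
    slt_band6_per_min: float = 0.75     # computerised-therapy delivery
    slt_band5_per_min: float = 0.57     # attention-control calls
    slta_band3_per_min: float = 0.41
    travel_per_mile: float = 0.45
    cost_year: str = "2016/17"

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "cost_year":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"unit cost {f.name} must be >= 0")

    def licence_price(self, scheme: str) -> float:
        prices = {"individual": self.software_licence_individual,
                  "clinician": self.software_licence_clinician,
                  "bundle5": self.software_licence_bundle5,
                  "none": 0.0}
        if scheme not in prices:
            raise ValueError(f"unknown licence scheme {scheme!r}")
        return prices[scheme]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class CostScenario:
    """Multiplier on all SLT/SLTA per-minute rates (0.5 = halved-staff)."""

    slt_slta_multiplier: float = 1.0

    def __post_init__(self):
        if self.slt_slta_multiplier <= 0:
            raise ValueError("multiplier must be positive")


BASE_SCENARIO = CostScenario(1.0)
HALVED_STAFF_SCENARIO = CostScenario(0.5)

_LOG_COLUMNS = ("slt_training_min", "slt_delivery_min", "slta_min",
                "control_call_min", "travel_miles", "laptop_loaned",
                "headset_issued", "licence_scheme", "licence_users",
                "puzzle_books")


def laptop_unit_cost(purchase_cost: float, users_over_shelf_life: int) -> float:
    """Per-loan laptop cost: purchase price split across its users."""
    if users_over_shelf_life < 1:
        raise ValueError("users_over_shelf_life must be >= 1")
    return purchase_cost / users_over_shelf_life


def staff_time_cost(log, costs: UnitCostTable):
    """Undiscounted staff-time component (SLT + SLTA minutes) of a log."""
    return (log["slt_training_min"] * costs.slt_band7_per_min
            + log["slt_delivery_min"] * costs.slt_band6_per_min
            + log["control_call_min"] * costs.slt_band5_per_min
            + log["slta_min"] * costs.slta_band3_per_min)


def cost_participant(log, costs: UnitCostTable,
                     scenario: CostScenario = BASE_SCENARIO) -> float:
    """Total one-off intervention cost for one participant.

    ``log`` is any mapping with the activity-log fields (a DataFrame row
    works).  The scenario multiplier scales staff-time components only;
    travel, equipment, licences and consumables are unaffected.
    """
    for col in ("slt_training_min", "slt_delivery_min", "slta_min",
                "control_call_min", "travel_miles", "puzzle_books"):
        if log[col] < 0:
            raise ValueError(f"negative quantity in activity log: {col}")
    staff = staff_time_cost(log, costs) * scenario.slt_slta_multiplier
    travel = log["travel_miles"] * costs.travel_per_mile
    equipment = (bool(log["laptop_loaned"]) * costs.laptop_loan_6m
                 + bool(log["headset_issued"]) * costs.headset
                 + log["puzzle_books"] * costs.puzzle_book)
    scheme = log["licence_scheme"]
    if scheme != "none":
        users = int(log["licence_users"])
        if users < 1:
            raise ValueError("licence_users must be >= 1 when licensed")
        equipment += costs.licence_price(scheme) / users
    return float(staff + travel + equipment)


def cost_participants(df: pd.DataFrame, costs: UnitCostTable,
                      scenario: CostScenario = BASE_SCENARIO,
                      out_col: str = "cost") -> pd.DataFrame:
    """Vectorised per-participant costing; appends ``out_col``."""
    q = df[["slt_training_min", "slt_delivery_min", "slta_min",
            "control_call_min", "travel_miles"]].to_numpy(dtype=float)
    if (q < 0).any() or (df["puzzle_books"].to_numpy() < 0).any():
        raise ValueError("negative quantity in activity log")
    mult = scenario.slt_slta_multiplier
    rates = np.array([costs.slt_band7_per_min, costs.slt_band6_per_min,
                      costs.slta_band3_per_min, costs.slt_band5_per_min,
                      costs.travel_per_mile])
    staff = q[:, :4] @ (rates[:4] * mult)
    travel = q[:, 4] * rates[4]
    licence = np.array([
        costs.licence_price(s) / max(int(u), 1) if s != "none" else 0.0
        for s, u in zip(df["licence_scheme"], df["licence_users"])])
    equip = (df["laptop_loaned"].to_numpy(dtype=float) * costs.laptop_loan_6m
             + df["headset_issued"].to_numpy(dtype=float) * costs.headset
             + df["puzzle_books"].to_numpy(dtype=float) * costs.puzzle_book)
    out = df.copy()
    out[out_col] = staff + travel + licence + equip
    return out


@dataclass(frozen=True)
class ArmCost:
    """Mean per-patient intervention cost for one arm, with its SE."""

    arm: str
    mean: float
    se: float
    n: int


def mean_arm_cost(df: pd.DataFrame, costs: UnitCostTable,
                  scenario: CostScenario = BASE_SCENARIO
                  ) -> dict[str, ArmCost]:
    """Per-arm mean cost and standard error of the mean."""
    costed = cost_participants(df, costs, scenario)
    out = {}
    for arm, grp in costed.groupby("arm", sort=False):
        n = len(grp)
        if n == 0:
            raise ValueError(f"no costed participants in arm {arm}")
        c = grp["cost"].to_numpy()
        se = float(c.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[arm] = ArmCost(arm=arm, mean=float(c.mean()), se=se, n=n)
    return out
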
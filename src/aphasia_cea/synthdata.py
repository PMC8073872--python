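"""Synthetic trial and life-table generation.

No participant-level data is deposited with the trial this analysis
emulates, so the generator here produces trials with the statistical
structure the downstream pipeline assumes: three arms (computerised
word-finding therapy + usual care, attention control + usual care, usual
care alone), arm-specific good-response and relapse dynamics at the 6/9/12
month assessments, EQ-5D profiles whose scored utilities carry a
response-linked increment, gamma-distributed therapist/assistant resource
use recorded in activity logs, and missing-at-random missingness whose
probability depends on arm and baseline utility.

Latent response states are retained on every record so that recovery tests
can verify the whole estimation chain against known truth.  For a fixed
seed all generation is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .utility import (DIM_CODES, ValueSet, expand_lookup, score_frame,
                      synthetic_5l_valueset)

ARMS = ("ct_uc", "ac_uc", "uc")
ARM_LABELS = {
    "ct_uc": "computerised therapy + usual care",
    "ac_uc": "attention control + usual care",
    "uc": "usual care alone",
}
TIMEPOINTS = (0, 6, 9, 12)
ASSESSMENTS = (6, 9, 12)

# Severity bands on the baseline CAT Naming Objects score (range 5-43 of
# 48).  The trial's own mild/moderate/severe cut-offs are not public; these
# tertile-style bands are a synthetic convention of this package.
SEVERITY_BANDS = {"severe": (5, 17), "moderate": (18, 30), "mild": (31, 43)}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class ResourceModel:
    """Mean/SD of activity-log quantities (gamma-distributed where sd>0)."""

    slt_training_min: tuple[float, float] = (60.0, 40.0)
    slt_delivery_min: tuple[float, float] = (427.8, 350.0)  # 7.13 h mean
    slta_min: tuple[float, float] = (45.0, 35.0)
    travel_miles: tuple[float, float] = (93.0, 80.0)
    laptop_loan_prob: float = 0.5
    headset_prob: float = 0.9
    control_call_min: tuple[float, float] = (58.0, 35.0)
    puzzle_books: int = 2


@dataclass
class UtilityModel:
    """Latent utility process: baseline level plus response increments."""

    baseline_mean: float = 0.58
    baseline_sd: float = 0.20
    #: mean utility-change difference for responders at 6/9/12 months
    response_increment: Mapping[int, float] = field(
        default_factory=lambda: {6: -0.04, 9: -0.02, 12: 0.02})
    residual_sd: float = 0.07


def _default_response_prob() -> dict:
    # per arm x assessment probability of being a NEW responder; synthetic
    # conventions (the trial's per-arm response proportions are not in the
    # public record), with the therapy arm responding most.
    return {
        "ct_uc": {6: 0.45, 9: 0.15, 12: 0.10},
        "ac_uc": {6: 0.20, 9: 0.10, 12: 0.08},
        "uc": {6: 0.20, 9: 0.10, 12: 0.08},
    }


def _default_relapse_prob() -> dict:
    # low per-interval relapse: responses are largely sustained, which is
    # what makes a lifetime per-patient QALY gain of the order 0.02
    # attainable at a 12-month utility increment of 0.02
    return {
        "ct_uc": {"6_9": 0.06, "9_12": 0.04},
        "ac_uc": {"6_9": 0.11, "9_12": 0.07},
        "uc": {"6_9": 0.11, "9_12": 0.07},
    }


def _default_missing_prob() -> dict:
    # EQ-5D missingness rising from 1% at baseline to 18% at 12 months, as
    # observed in the trial; outcome scores follow the same pattern.
    return {
        "eq5d": {0: 0.01, 6: 0.10, 9: 0.14, 12: 0.18},
        "naming": {0: 0.0, 6: 0.08, 9: 0.12, 12: 0.15},
        "tom": {0: 0.0, 6: 0.08, 9: 0.12, 12: 0.15},
    }


@dataclass
class TrialConfig:
    """Full configuration of one synthetic trial."""

    n_per_arm: int = 93
    arms: tuple[str, ...] = ARMS
    response_prob: Mapping = field(default_factory=_default_response_prob)
    relapse_prob: Mapping = field(default_factory=_default_relapse_prob)
    severity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 0.34, "moderate": 0.33,
                                 "severe": 0.33})
    baseline_age_mean_sd: tuple[float, float] = (65.0, 10.0)
    utility_model: UtilityModel = field(default_factory=UtilityModel)
    resource_model: ResourceModel = field(default_factory=ResourceModel)
    missing_prob: Mapping = field(default_factory=_default_missing_prob)
    #: systematic worsening of proxy-reported EQ-5D levels
    proxy_level_shift: int = 1
    proxy_shift_prob: float = 0.35
    #: MAR mechanism: log-odds slope on standardised baseline utility
    mar_slope: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        for arm in self.arms:
            for t in ASSESSMENTS:
                p = self.response_prob[arm][t]
                if not 0 <= p <= 1:
                    raise ConfigError(
                        f"response_prob[{arm}][{t}]={p} outside [0,1]")
            for k in ("6_9", "9_12"):
                p = self.relapse_prob[arm][k]
                if not 0 <= p <= 1:
                    raise ConfigError(
                        f"relapse_prob[{arm}][{k}]={p} outside [0,1]")
        tot = sum(self.severity_mix.values())
        if abs(tot - 1.0) > 1e-12:
            raise ConfigError(f"severity_mix sums to {tot}, not 1")
        for var, by_t in self.missing_prob.items():
            for t, p in by_t.items():
                if not 0 <= p <= 1:
                    raise ConfigError(
                        f"missing_prob[{var}][{t}]={p} outside [0,1]")

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["utility_model"] = UtilityModel(**raw["utility_model"])
        raw["resource_model"] = ResourceModel(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in raw["resource_model"].items()})
        for key in ("arms", "baseline_age_mean_sd"):
            if key in raw:
                raw[key] = tuple(raw[key])
        # YAML round-trips mapping keys as they were written; assessment
        # keys must be ints
        raw["response_prob"] = {a: {int(t): p for t, p in d.items()}
                                for a, d in raw["response_prob"].items()}
        raw["missing_prob"] = {v: {int(t): p for t, p in d.items()}
                               for v, d in raw["missing_prob"].items()}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Life table

@dataclass(frozen=True)
class LifeTable:
    """Annual death probability q(age) for every integer age in range."""

    ages: tuple[int, ...]
    q_annual: tuple[float, ...]

    def __post_init__(self):
        if list(self.ages) != list(range(self.ages[0], self.ages[-1] + 1)):
            raise ValueError("ages must be consecutive integers")
        if any(not 0 <= q <= 1 for q in self.q_annual):
            raise ValueError("q_annual outside [0,1]")

    def q(self, age: float) -> float:
        a = int(math.floor(age))
        if a < self.ages[0]:
            raise ValueError(f"age {age} below table start {self.ages[0]}")
        if a >= self.ages[-1]:
            return 1.0          # absorbed at the terminal age
        return self.q_annual[a - self.ages[0]]

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(ages=tuple(int(a) for a in df["age"]),
                   q_annual=tuple(float(q) for q in df["q_annual"]))


def generate_life_table(start_age: int = 55, terminal_age: int = 100,
                        base_rate: float = 0.032,
                        growth: float = 0.09,
                        reference_age: int = 65) -> LifeTable:
    """Build a life table from a two-parameter exponential-growth hazard.

    ``q(age) = min(1, base_rate * exp(growth * (age - reference_age)))``,
    forced to 1 at ``terminal_age`` so the cohort is fully absorbed.
    ``growth = 0`` gives a constant annual probability ``base_rate`` (a
    constant hazard h corresponds to ``base_rate = 1 - exp(-h)``).
    """
    if start_age >= terminal_age:
        raise ValueError("start_age must be below terminal_age")
    if not 0 <= base_rate <= 1:
        raise ValueError("base_rate outside [0,1]")
    ages = tuple(range(start_age, terminal_age + 1))
    q = [min(1.0, base_rate * math.exp(growth * (a - reference_age)))
         for a in ages]
    q[-1] = 1.0
    return LifeTable(ages=ages, q_annual=tuple(q))


# ---------------------------------------------------------------------------
# Trial generation

def _gamma_draw(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    if sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size=size)


class _ProfileQuantiser:
    """Maps a target utility to the EQ-5D profile scoring nearest to it."""

    def __init__(self, valueset: ValueSet):
        table = expand_lookup(valueset)
        items = sorted(table.items(), key=lambda kv: (kv[1], kv[0]))
        self.scores = np.array([u for _, u in items])
        self.states = np.array([s for s, _ in items])

    def quantise(self, targets: np.ndarray) -> np.ndarray:
        """Return the (n, 5) level array of nearest-scoring profiles."""
        idx = np.searchsorted(self.scores, targets)
        idx = np.clip(idx, 1, len(self.scores) - 1)
        left = self.scores[idx - 1]
        right = self.scores[idx]
        pick = np.where(np.abs(targets - left) <= np.abs(right - targets),
                        idx - 1, idx)
        return self.states[pick]


def _latent_response_paths(rng, cfg: TrialConfig, arm: str,
                           n: int) -> dict[int, np.ndarray]:
    """Draw responder/non-responder state at each assessment.

    New responses can occur at 6, 9 and 12 months; an existing responder
    relapses between consecutive assessments with the configured interval
    probability.
    """
    p = cfg.response_prob[arm]
    rel = cfg.relapse_prob[arm]
    r6 = rng.random(n) < p[6]
    keep_69 = rng.random(n) >= rel["6_9"]
    new9 = rng.random(n) < p[9]
    r9 = np.where(r6, keep_69, new9)
    keep_912 = rng.random(n) >= rel["9_12"]
    new12 = rng.random(n) < p[12]
    r12 = np.where(r9, keep_912, new12)
    return {6: r6, 9: r9, 12: r12}


def _scores_consistent_with_state(rng, n: int, resp: np.ndarray,
                                  naming0: np.ndarray, tom0: np.ndarray,
                                  naming_thr: int = 10,
                                  tom_thr: float = 0.5):
    """Draw follow-up naming/TOM scores matching the latent state.

    Responders clear at least one of the good-response thresholds (10+
    words on the 100-word naming test OR +0.5 on the TOM activity scale);
    non-responders clear neither.  Scores stay inside their instrument
    ranges by construction so clipping can never flip a classification.
    """
    naming_fire = rng.random(n) < 0.75
    tom_fire = rng.random(n) < 0.55
    neither = ~(naming_fire | tom_fire)
    naming_fire = naming_fire | neither      # force the OR for responders

    gain_hit = naming_thr + rng.integers(0, 16, size=n)
    gain_miss = rng.integers(-5, naming_thr, size=n)      # <= thr-1
    naming_gain = np.where(resp & naming_fire, gain_hit,
                           np.where(resp, gain_miss,
                                    rng.integers(-8, naming_thr, size=n)))
    tom_hit = tom_thr * rng.integers(1, 4, size=n)        # +0.5..+1.5
    tom_flat = 0.5 * rng.integers(-1, 1, size=n)          # -0.5 or 0
    tom_gain = np.where(resp & tom_fire, tom_hit,
                        np.where(resp, tom_flat, tom_flat))
    naming = np.clip(naming0 + naming_gain, 0, 100)
    tom = np.clip(tom0 + tom_gain, 0.0, 5.0)
    return naming.astype(int), tom


def generate_trial(config: TrialConfig,
                   valueset: ValueSet | None = None) -> pd.DataFrame:
    """Generate one synthetic trial as a wide participant table.

    One row per participant; longitudinal columns are suffixed with the
    month (0/6/9/12).  Latent responder states (``resp_t``) and the scored
    latent utilities are retained alongside the observable columns so that
    estimator-recovery tests have access to the truth.  EQ-5D profiles are
    chosen as the nearest-scoring state to a latent target utility, so the
    expected scored utility equals the configured baseline mean plus the
    response increment for responders.
    """
    config.validate()
    if valueset is None:
        valueset = synthetic_5l_valueset()
    rng = np.random.default_rng(config.seed)
    quantiser = _ProfileQuantiser(valueset)
    um = config.utility_model
    rm = config.resource_model
    frames = []
    pid0 = 0
    for arm in config.arms:
        n = config.n_per_arm
        df = pd.DataFrame({"pid": np.arange(pid0, pid0 + n), "arm": arm})
        pid0 += n
        mu, sd = config.baseline_age_mean_sd
        df["age0"] = np.clip(rng.normal(mu, sd, n), 35.0, 90.0).round(1)
        sev_labels = list(config.severity_mix)
        sev = rng.choice(len(sev_labels), size=n,
                         p=[config.severity_mix[s] for s in sev_labels])
        df["severity"] = [sev_labels[i] for i in sev]
        lo_hi = np.array([SEVERITY_BANDS[s] for s in df["severity"]])
        df["cat_naming0"] = rng.integers(lo_hi[:, 0], lo_hi[:, 1] + 1)

        # baseline outcome scores; bounded away from the edges so that
        # follow-up gains never clip across a response threshold
        naming0 = np.clip(
            np.round(df["cat_naming0"] / 43 * 55 + rng.normal(0, 5, n)),
            10, 75).astype(int)
        tom0 = 0.5 * rng.integers(2, 8, size=n)           # 1.0 .. 3.5
        df["naming_0"] = naming0
        df["tom_0"] = tom0

        resp = _latent_response_paths(rng, config, arm, n)
        for t in ASSESSMENTS:
            df[f"resp_{t}"] = resp[t]
            naming_t, tom_t = _scores_consistent_with_state(
                rng, n, resp[t], naming0, tom0)
            df[f"naming_{t}"] = naming_t
            df[f"tom_{t}"] = tom_t

        # latent utility process and EQ-5D profile quantisation
        lo = valueset.floor + 0.02
        u_base = np.clip(rng.normal(um.baseline_mean, um.baseline_sd, n),
                         lo, 0.95)
        df["u_latent_0"] = u_base
        for t in TIMEPOINTS:
            inc = 0.0 if t == 0 else um.response_increment[t] * resp[t]
            target = np.clip(u_base + inc + rng.normal(0, um.residual_sd, n),
                             valueset.floor, 1.0)
            levels = quantiser.quantise(target)
            for j, code in enumerate(DIM_CODES):
                df[f"{code}_{t}"] = levels[:, j]
            # proxy report: systematically worse levels
            shift = (rng.random((n, 5)) < config.proxy_shift_prob)
            plevels = np.clip(levels + shift * config.proxy_level_shift,
                              1, valueset.n_levels)
            for j, code in enumerate(DIM_CODES):
                df[f"p{code}_{t}"] = plevels[:, j]

        # activity logs
        zero = np.zeros(n)
        if arm == "ct_uc":
            df["slt_training_min"] = _gamma_draw(rng, *rm.slt_training_min, n)
            df["slt_delivery_min"] = _gamma_draw(rng, *rm.slt_delivery_min, n)
            df["slta_min"] = _gamma_draw(rng, *rm.slta_min, n)
            df["travel_miles"] = _gamma_draw(rng, *rm.travel_miles, n)
            df["laptop_loaned"] = rng.random(n) < rm.laptop_loan_prob
            df["headset_issued"] = rng.random(n) < rm.headset_prob
            df["licence_scheme"] = "individual"
            df["licence_users"] = 1
            df["control_call_min"] = zero
            df["puzzle_books"] = 0
        elif arm == "ac_uc":
            for c in ("slt_training_min", "slt_delivery_min", "slta_min",
                      "travel_miles"):
                df[c] = zero
            df["laptop_loaned"] = False
            df["headset_issued"] = False
            df["licence_scheme"] = "none"
            df["licence_users"] = 0
            df["control_call_min"] = _gamma_draw(rng, *rm.control_call_min, n)
            df["puzzle_books"] = rm.puzzle_books
        else:
            for c in ("slt_training_min", "slt_delivery_min", "slta_min",
                      "travel_miles", "control_call_min"):
                df[c] = zero
            df["laptop_loaned"] = False
            df["headset_issued"] = False
            df["licence_scheme"] = "none"
            df["licence_users"] = 0
            df["puzzle_books"] = 0
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = score_frame(out, valueset)                       # u_t columns
    out = score_frame(out, valueset, prefix="p", out_prefix="pu")
    return out


# ---------------------------------------------------------------------------
# Missingness (MAR)

_MASKABLE = {
    "eq5d": lambda t: [f"{c}_{t}" for c in DIM_CODES] + [f"u_{t}"],
    "naming": lambda t: [f"naming_{t}"],
    "tom": lambda t: [f"tom_{t}"],
}


def _calibrated_mar_prob(target: float, z: np.ndarray,
                         slope: float) -> np.ndarray:
    """Per-record missingness probabilities with the configured marginal.

    Log-odds depend linearly on the standardised covariate ``z`` (MAR);
    the intercept is solved so the mean probability equals ``target``.
    """
    if target <= 0:
        return np.zeros_like(z)
    if target >= 1:
        return np.ones_like(z)
    if slope == 0 or np.allclose(z, z[0]):
        return np.full_like(z, target)

    def gap(a):
        return expit(a + slope * z).mean() - target

    lo, hi = logit(target) - 6 * abs(slope), logit(target) + 6 * abs(slope)
    a = brentq(gap, lo, hi, xtol=1e-12)
    return expit(a + slope * z)


def apply_missingness(df: pd.DataFrame, config: TrialConfig,
                      seed: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask values missing-at-random; return (masked table, mask).

    Missingness probability for each variable/time point has the
    configured marginal rate, with log-odds depending on arm and on the
    observed baseline utility (never on the masked value itself).  Masked
    cells are NaN in the returned table; the input table (which retains
    the originals) is not modified.  The mask frame has one boolean column
    per maskable variable/time point, named ``miss_{var}_{t}``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    masked = df.copy()
    u0 = df["u_0"].to_numpy(dtype=float)
    z = (u0 - np.nanmean(u0)) / (np.nanstd(u0) + 1e-12)
    z = np.nan_to_num(z)                     # mean-covariate fallback
    arm_offset = df["arm"].map({"ct_uc": 0.0, "ac_uc": 0.15,
                                "uc": -0.15}).fillna(0.0).to_numpy()
    mask_cols = {}
    for var, by_t in config.missing_prob.items():
        for t, p_target in sorted(by_t.items()):
            if var == "eq5d" and t == 0:
                # baseline utility is the MAR covariate; its own
                # missingness may depend only on arm, never on itself
                covar = arm_offset.copy()
            else:
                covar = z + arm_offset
            p = _calibrated_mar_prob(p_target, covar, config.mar_slope)
            miss = rng.random(len(df)) < p
            mask_cols[f"miss_{var}_{t}"] = miss
            if miss.any():
                for col in _MASKABLE[var](t):
                    if col in masked.columns:
                        vals = masked[col].astype(float).to_numpy()
                        vals[miss] = np.nan
                        masked[col] = vals
    mask = pd.DataFrame(mask_cols, index=df.index)
    return masked, mask
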
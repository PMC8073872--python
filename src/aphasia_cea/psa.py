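"""Probabilistic sensitivity analysis and cost-effectiveness outputs.

Every uncertain model input gets a probability distribution: normal for
utility-change parameters, beta (events / non-events from the trial
counts) for transition probabilities, and gamma (method of moments from
mean and SE) for resource-use/cost parameters.  The model is run for
thousands of parameter draws (10,000 in the base case); mean incremental
costs and QALYs over draws give the best-estimate ICER, percentile
intervals of the per-draw increments give 95% credible intervals, and the
draws also yield cost-effectiveness planes and acceptability curves
(CEACs) via net monetary benefit, lambda * QALYs - cost.

A zero-variance mode collapses every distribution to its mean so a
one-draw "PSA" reproduces the deterministic run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import ArmCost
from .markov import ArmProbs, ModelSpec, cohort_qalys_vector
from .synthdata import LifeTable
from .transitions import ArmTransitions, TransitionSet, extrapolate_relapse
from .utility import UtilityEstimate, UtilityInputs

#: willingness-to-pay grid: £0-£100,000 in £500 steps (includes £20k/£30k)
DEFAULT_THRESHOLDS = tuple(range(0, 100_001, 500))


def nmb(cost, qalys, threshold: float):
    """Net monetary benefit ``threshold * QALYs - cost``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * np.asarray(qalys) - np.asarray(cost)


def _beta_draw(rng, events: float, non_events: float, size: int,
               zero_variance: bool) -> np.ndarray:
    n = events + non_events
    if n <= 0:
        raise ValueError("beta distribution needs a positive denominator")
    mean = events / n
    if zero_variance or events == 0 or non_events == 0:
        # degenerate corner: the beta parameterisation requires both
        # counts positive, so boundary estimates collapse to a point mass
        return np.full(size, mean)
    return rng.beta(events, non_events, size=size)


def _gamma_draw(rng, mean: float, se: float, size: int,
                zero_variance: bool) -> np.ndarray:
    if mean < 0 or se < 0:
        raise ValueError("gamma mean and SE must be >= 0")
    if zero_variance or se == 0 or mean == 0:
        return np.full(size, mean)
    shape = (mean / se) ** 2
    scale = se ** 2 / mean
    return rng.gamma(shape, scale, size=size)


def _normal_draw(rng, mean: float, se: float, size: int,
                 zero_variance: bool) -> np.ndarray:
    if se < 0:
        raise ValueError("SE must be >= 0")
    if zero_variance or se == 0:
        return np.full(size, mean)
    return rng.normal(mean, se, size=size)


@dataclass
class ParameterDistributions:
    """All uncertain inputs for one analysis.

    ``transitions`` supplies beta counts per arm; ``utilities`` supplies
    normal means/SEs for the response increments; ``arm_costs`` supplies
    gamma mean/SE per arm.  ``zero_variance`` turns every distribution
    into a point mass at its mean.
    """

    transitions: TransitionSet
    utilities: UtilityInputs
    arm_costs: dict[str, ArmCost]
    zero_variance: bool = False


@dataclass
class ParameterDraw:
    """One (possibly vectorised) joint draw of all uncertain parameters."""

    arm_probs: dict[str, ArmProbs]
    deltas: tuple[np.ndarray, np.ndarray, np.ndarray]   # 6, 9, 12 months
    arm_costs: dict[str, np.ndarray]


def sample_parameters(dists: ParameterDistributions,
                      rng: np.random.Generator,
                      size: int = 1) -> ParameterDraw:
    """Draw all uncertain parameters jointly (independent components).

    Utility increments are shared across arms (the same draw enters every
    arm's Good-response states); transition probabilities and costs are
    arm-specific.  Deterministic for a fixed generator state.
    """
    zv = dists.zero_variance
    deltas = tuple(
        _normal_draw(rng, dists.utilities.deltas[t].delta,
                     dists.utilities.deltas[t].se, size, zv)
        for t in (6, 9, 12))
    arm_probs = {}
    for arm, at in dists.transitions.arms.items():
        # the post-12-month relapse is the 9->12 relapse carried forward:
        # it is the same parameter, so it shares the draw
        rel912 = _beta_draw(rng, at.rel912, at.d912 - at.rel912, size, zv)
        arm_probs[arm] = ArmProbs(
            p_response6=_beta_draw(rng, at.r6, at.n6 - at.r6, size, zv),
            p_new_response9=_beta_draw(rng, at.new9, at.d9 - at.new9,
                                       size, zv),
            p_new_response12=_beta_draw(rng, at.new12, at.d12 - at.new12,
                                        size, zv),
            p_relapse_6_9=_beta_draw(rng, at.rel69, at.d69 - at.rel69,
                                     size, zv),
            p_relapse_9_12=rel912,
            p_relapse_post12=rel912,
        )
    costs = {arm: _gamma_draw(rng, ac.mean, ac.se, size, zv)
             for arm, ac in dists.arm_costs.items()}
    return ParameterDraw(arm_probs=arm_probs, deltas=deltas,
                         arm_costs=costs)


@dataclass
class PSASample:
    """Per-iteration, per-arm costs and QALYs from a PSA."""

    data: pd.DataFrame        # columns: iteration, arm, cost, qalys

    @property
    def n_iter(self) -> int:
        return int(self.data["iteration"].nunique())

    @property
    def arms(self) -> list[str]:
        return list(self.data["arm"].unique())

    def arm_matrix(self, column: str) -> pd.DataFrame:
        """(n_iter x arm) pivot of cost or qalys."""
        return self.data.pivot(index="iteration", columns="arm",
                               values=column)

    def mean_outcomes(self) -> pd.DataFrame:
        return self.data.groupby("arm", sort=False)[
            ["cost", "qalys"]].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def run_psa(spec: ModelSpec, dists: ParameterDistributions,
            life_table: LifeTable, n_iter: int = 10_000,
            seed: int = 0) -> PSASample:
    """Run the cohort model for ``n_iter`` joint parameter draws.

    All arms share each iteration's draw of shared parameters (the utility
    increments), so between-arm comparisons difference out that noise.
    Fully reproducible from the seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draw = sample_parameters(dists, rng, size=n_iter)
    frames = []
    for arm, probs in draw.arm_probs.items():
        qalys = cohort_qalys_vector(spec, probs, life_table,
                                    dists.utilities, draw.deltas)
        frames.append(pd.DataFrame({
            "iteration": np.arange(n_iter), "arm": arm,
            "cost": draw.arm_costs[arm], "qalys": qalys}))
    return PSASample(data=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Incremental analysis

@dataclass(frozen=True)
class IncrementalResult:
    """Mean-based incremental comparison of one arm against a comparator."""

    arm: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    ci_cost: tuple[float, float]
    ci_qalys: tuple[float, float]
    icer: float | None
    label: str                      # "icer", "dominant", "dominated", ...

    def icer_text(self) -> str:
        if self.label == "icer":
            return f"{self.icer:,.0f}"
        return self.label.capitalize()


def incremental_analysis(sample: PSASample, arm: str,
                         comparator: str) -> IncrementalResult:
    """ICER (or dominance label) with 95% percentile credible intervals.

    Incremental costs and QALYs are means over iterations.  The ICER is
    reported when the new arm adds both cost and QALYs; an arm that costs
    more and yields fewer QALYs is dominated; cheaper and more effective
    is dominant; both-negative falls in the southwest quadrant where a
    ratio alone would mislead, so it is labelled rather than reported.
    """
    cost = sample.arm_matrix("cost")
    qalys = sample.arm_matrix("qalys")
    dc = (cost[arm] - cost[comparator]).to_numpy()
    dq = (qalys[arm] - qalys[comparator]).to_numpy()
    delta_cost, delta_q = float(dc.mean()), float(dq.mean())
    ci_cost = tuple(np.percentile(dc, [2.5, 97.5]))
    ci_q = tuple(np.percentile(dq, [2.5, 97.5]))
    icer = None
    if delta_q == 0:
        label = "undefined"
    elif delta_cost > 0 and delta_q > 0:
        label, icer = "icer", delta_cost / delta_q
    elif delta_cost > 0 and delta_q < 0:
        label = "dominated"
    elif delta_cost <= 0 and delta_q > 0:
        label = "dominant"          # includes a cost-free QALY gain
    else:
        label = "undefined (southwest quadrant)"
    return IncrementalResult(arm=arm, comparator=comparator,
                             delta_cost=delta_cost, delta_qalys=delta_q,
                             ci_cost=ci_cost, ci_qalys=ci_q,
                             icer=icer, label=label)


def incremental_pairs(sample: PSASample, arm: str,
                      comparator: str) -> pd.DataFrame:
    """Per-iteration (delta QALYs, delta cost) pairs: the CE plane cloud."""
    cost = sample.arm_matrix("cost")
    qalys = sample.arm_matrix("qalys")
    return pd.DataFrame({
        "delta_qalys": qalys[arm] - qalys[comparator],
        "delta_cost": cost[arm] - cost[comparator],
    }).reset_index()


def ceac(sample: PSASample,
         thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Probability each arm is most cost-effective at each threshold.

    At each willingness-to-pay the winner of an iteration is the arm with
    the highest net monetary benefit; ties split their iteration's
    probability mass evenly.  Columns sum to 1 across arms at every
    threshold.
    """
    cost = sample.arm_matrix("cost")
    qalys = sample.arm_matrix("qalys")
    if cost.empty:
        raise ValueError("empty PSA sample")
    arms = list(cost.columns)
    c = cost.to_numpy()
    q = qalys.to_numpy()
    n = c.shape[0]
    rows = []
    for lam in thresholds:
        net = lam * q - c
        best = net.max(axis=1, keepdims=True)
        winners = np.isclose(net, best, rtol=0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        rows.append([lam] + list(share.mean(axis=0)))
    return pd.DataFrame(rows, columns=["threshold"] + arms)


# ---------------------------------------------------------------------------
# Result container and plots

@dataclass
class CEResults:
    """All cost-effectiveness outputs for one analysis."""

    name: str
    arm_means: pd.DataFrame                 # per-arm mean cost / QALYs
    incrementals: list[IncrementalResult]
    ceac_table: pd.DataFrame
    sample: PSASample | None = None

    def ceac_at(self, threshold: float) -> dict[str, float]:
        t = self.ceac_table
        row = t.iloc[(t["threshold"] - threshold).abs().argmin()]
        return {a: float(row[a]) for a in t.columns if a != "threshold"}

    def summary(self) -> dict:
        return {
            "analysis": self.name,
            "arms": {a: {"cost": float(r["cost"]),
                         "qalys": float(r["qalys"])}
                     for a, r in self.arm_means.iterrows()},
            "incremental": [{
                "arm": inc.arm, "comparator": inc.comparator,
                "delta_cost": inc.delta_cost,
                "delta_cost_ci": list(inc.ci_cost),
                "delta_qalys": inc.delta_qalys,
                "delta_qalys_ci": list(inc.ci_qalys),
                "icer": inc.icer, "label": inc.label,
            } for inc in self.incrementals],
            "ceac_20000": self.ceac_at(20_000),
            "ceac_30000": self.ceac_at(30_000),
        }


def plot_ce_plane(pairs: pd.DataFrame, ax=None, threshold: float = 30_000):
    """Scatter the incremental cloud on the cost-effectiveness plane."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs["delta_qalys"], pairs["delta_cost"], s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    xs = np.array(ax.get_xlim())
    ax.plot(xs, threshold * xs, "r--", lw=0.8,
            label=f"lambda = {threshold:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.legend(fontsize=8)
    return ax


def plot_ceac(ceac_table: pd.DataFrame, ax=None):
    """Plot acceptability curves, one per arm."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for arm in ceac_table.columns[1:]:
        ax.plot(ceac_table["threshold"], ceac_table[arm], label=arm)
    ax.set_xlabel("Willingness to pay (GBP/QALY)")
    ax.set_ylabel("P(most cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
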
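"""Configuration-driven pipeline: data -> imputation -> estimation ->
cohort model -> PSA -> cost-effectiveness outputs.

``run_pipeline`` wires the full analysis: generate (or load) a trial,
apply and impute missingness, classify good response, estimate transition
probabilities, utility increments and arm costs per imputed dataset, run
the probabilistic cohort model, and assemble ICERs, credible intervals,
CEACs and report tables for the base case plus any cost scenarios and
subgroups.  Everything is deterministic given the configured seed.

With multiply-imputed data the default execution mode runs the
probabilistic analysis within each imputed dataset, splitting the
iteration budget evenly across imputations and concatenating the draws,
so imputation uncertainty propagates into the credible intervals.  A
pooled-parameter mode (average the per-imputation estimates first, widen
the utility-increment SEs by the between-imputation variance, then run a
single PSA) is also available.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .costing import (ArmCost, BASE_SCENARIO, CostScenario, UnitCostTable,
                      mean_arm_cost)
from .imputation import ImputationSpec, pmm_impute, pool_estimates
from .markov import ModelSpec
from .psa import (CEResults, IncrementalResult, ParameterDistributions,
                  PSASample, ceac, incremental_analysis, run_psa)
from .synthdata import (LifeTable, TrialConfig, apply_missingness,
                        generate_life_table, generate_trial)
from .transitions import (ResponseDefinition, TransitionSet, classify_frame,
                          estimate_transitions)
from .utility import (UtilityEstimate, UtilityInputs, ValueSet,
                      estimate_state_utilities, flat_ageing_index,
                      synthetic_5l_valueset)

INTERVENTION_ARM = "ct_uc"
COMPARATORS = ("uc", "ac_uc")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    trial: TrialConfig = field(default_factory=TrialConfig)
    response_definition: ResponseDefinition = field(
        default_factory=ResponseDefinition)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    unit_costs: UnitCostTable = field(default_factory=UnitCostTable)
    scenarios: dict[str, CostScenario] = field(
        default_factory=lambda: {"slt_costs_halved": CostScenario(0.5)})
    subgroup_var: str | None = "severity"
    n_iter: int = 10_000
    seed: int = 0
    #: score utilities from carer proxy EQ-5D reports instead of self-report
    use_proxy: bool = False
    #: "per_imputation" (default) or "pooled"
    execution_mode: str = "per_imputation"
    keep_samples: bool = False


def _estimate_inputs(df: pd.DataFrame, defn: ResponseDefinition,
                     utility_prefix: str = "u"
                     ) -> tuple[TransitionSet, UtilityInputs]:
    """Classify responses and estimate all model inputs on one dataset."""
    classified = classify_frame(df, defn)
    transitions = estimate_transitions(classified, defn)
    deltas = {}
    u_aphasia = None
    for t in (6, 9, 12):
        est, ua = estimate_state_utilities(classified, t,
                                           utility_prefix=utility_prefix)
        deltas[t] = est
        u_aphasia = ua          # pooled baseline mean; same at every t
    utilities = UtilityInputs(u_aphasia=u_aphasia, deltas=deltas,
                              ageing_index=flat_ageing_index())
    return transitions, utilities


def _pool_inputs(per_imp: list[tuple[TransitionSet, UtilityInputs]]
                 ) -> tuple[TransitionSet, UtilityInputs]:
    """Average estimates across imputations (pooled-parameter mode).

    Transition counts are averaged (beta parameters accept non-integer
    counts); utility increments pool with the multiple-imputation rules so
    their SEs carry between-imputation variance.
    """
    from .transitions import ArmTransitions
    m = len(per_imp)
    arms = per_imp[0][0].arms.keys()
    pooled_ts = TransitionSet()
    for arm in arms:
        fields = ("r6", "n6", "new9", "d9", "new12", "d12",
                  "rel69", "d69", "rel912", "d912")
        means = {f: float(np.mean([getattr(ts.arms[arm], f)
                                   for ts, _ in per_imp]))
                 for f in fields}
        pooled_ts.arms[arm] = ArmTransitions(arm=arm, **means)
    deltas = {}
    for t in (6, 9, 12):
        pooled = pool_estimates(
            [ui.deltas[t].delta for _, ui in per_imp],
            [ui.deltas[t].se ** 2 for _, ui in per_imp])
        deltas[t] = UtilityEstimate(
            delta=pooled.estimate, se=pooled.se,
            n_responders=per_imp[0][1].deltas[t].n_responders,
            n_nonresponders=per_imp[0][1].deltas[t].n_nonresponders)
    ua = float(np.mean([ui.u_aphasia for _, ui in per_imp]))
    return pooled_ts, UtilityInputs(u_aphasia=ua, deltas=deltas,
                                    ageing_index=per_imp[0][1].ageing_index)


def _analysis_results(name: str, completed: list[pd.DataFrame],
                      cfg: RunConfig, scenario: CostScenario,
                      life_table: LifeTable, seed: int,
                      utility_prefix: str) -> CEResults:
    """PSA + CE outputs for one analysis (one scenario/subgroup slice)."""
    m = len(completed)
    arm_costs = mean_arm_cost(completed[0], cfg.unit_costs, scenario)
    # usual-care-alone logs are all zero, so that arm costs exactly 0
    samples = []
    if cfg.execution_mode == "pooled":
        per_imp = [_estimate_inputs(d, cfg.response_definition,
                                    utility_prefix) for d in completed]
        transitions, utilities = _pool_inputs(per_imp)
        dists = ParameterDistributions(transitions=transitions,
                                       utilities=utilities,
                                       arm_costs=arm_costs)
        samples.append(run_psa(cfg.model, dists, life_table,
                               n_iter=cfg.n_iter, seed=seed))
    else:
        per_block = [cfg.n_iter // m + (1 if i < cfg.n_iter % m else 0)
                     for i in range(m)]
        offset = 0
        for i, d in enumerate(completed):
            if per_block[i] == 0:
                continue
            transitions, utilities = _estimate_inputs(
                d, cfg.response_definition, utility_prefix)
            dists = ParameterDistributions(transitions=transitions,
                                           utilities=utilities,
                                           arm_costs=arm_costs)
            s = run_psa(cfg.model, dists, life_table,
                        n_iter=per_block[i], seed=seed + i)
            s.data["iteration"] += offset
            offset += per_block[i]
            samples.append(s)
    sample = PSASample(data=pd.concat([s.data for s in samples],
                                      ignore_index=True))
    arm_means = sample.mean_outcomes()
    incs = [incremental_analysis(sample, INTERVENTION_ARM, comp)
            for comp in COMPARATORS if comp in arm_means.index]
    ceac_table = ceac(sample)
    return CEResults(name=name, arm_means=arm_means, incrementals=incs,
                     ceac_table=ceac_table,
                     sample=sample if cfg.keep_samples else None)


def run_pipeline(cfg: RunConfig,
                 records: pd.DataFrame | None = None,
                 life_table: LifeTable | None = None,
                 valueset: ValueSet | None = None,
                 output_dir=None) -> dict[str, CEResults]:
    """Run every configured analysis; returns {analysis name: CEResults}.

    Analyses: the base case, one per cost scenario, one per subgroup
    level.  If ``records`` is None a synthetic trial is generated from
    ``cfg.trial``.  With ``output_dir`` set, summary JSON, CEAC tables,
    the report table and a run manifest are written there.
    """
    t0 = time.time()
    timings = {}
    if valueset is None:
        valueset = synthetic_5l_valueset()
    if records is None:
        records = generate_trial(cfg.trial, valueset)
    if life_table is None:
        life_table = generate_life_table(
            start_age=int(min(55, cfg.model.start_age)),
            terminal_age=cfg.model.terminal_age)
    masked, _mask = apply_missingness(records, cfg.trial,
                                      seed=cfg.seed + 1)
    timings["data"] = time.time() - t0

    t1 = time.time()
    imp_spec = dataclasses.replace(cfg.imputation, seed=cfg.seed + 2)
    if cfg.use_proxy:
        targets = tuple(t.replace("u_", "pu_") for t in imp_spec.targets)
        imp_spec = dataclasses.replace(imp_spec, targets=targets)
    completed = pmm_impute(masked, imp_spec)
    timings["imputation"] = time.time() - t1

    utility_prefix = "pu" if cfg.use_proxy else "u"
    results: dict[str, CEResults] = {}
    t2 = time.time()
    results["base_case"] = _analysis_results(
        "base_case", completed, cfg, BASE_SCENARIO, life_table,
        seed=cfg.seed + 100, utility_prefix=utility_prefix)
    for sname, scenario in cfg.scenarios.items():
        results[sname] = _analysis_results(
            sname, completed, cfg, scenario, life_table,
            seed=cfg.seed + 100, utility_prefix=utility_prefix)
    if cfg.subgroup_var:
        levels = sorted(records[cfg.subgroup_var].unique())
        for li, level in enumerate(levels):
            subs = [d[d[cfg.subgroup_var] == level].reset_index(drop=True)
                    for d in completed]
            results[f"{cfg.subgroup_var}_{level}"] = _analysis_results(
                f"{cfg.subgroup_var}_{level}", subs, cfg, BASE_SCENARIO,
                life_table, seed=cfg.seed + 200 + li,
                utility_prefix=utility_prefix)
    timings["analysis"] = time.time() - t2

    if output_dir is not None:
        _write_outputs(Path(output_dir), cfg, results, timings)
    return results


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_outputs(outdir: Path, cfg: RunConfig,
                   results: dict[str, CEResults], timings: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {name: res.summary() for name, res in results.items()}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True,
                  default=_json_default)
    for name, res in results.items():
        res.ceac_table.to_csv(outdir / f"ceac_{name}.csv", index=False)
        if res.sample is not None:
            res.sample.to_csv(outdir / f"psa_{name}.csv")
    report_tables(results).to_csv(outdir / "report.csv", index=False)
    manifest = {"seed": cfg.seed, "n_iter": cfg.n_iter,
                "execution_mode": cfg.execution_mode,
                "analyses": list(results), "timings_sec": timings}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def report_tables(results: dict[str, CEResults]) -> pd.DataFrame:
    """Format results the way cost-effectiveness tables are published.

    One row per analysis x comparator: arm and comparator costs (2 dp),
    incremental cost with 95% credible interval, arm and comparator QALYs
    (4 dp), incremental QALYs with 95% CrI, and the ICER (nearest pound)
    or its dominance label.
    """
    rows = []
    for name, res in results.items():
        for inc in res.incrementals:
            arm_row = res.arm_means.loc[inc.arm]
            comp_row = res.arm_means.loc[inc.comparator]
            rows.append({
                "analysis": name,
                "arm": inc.arm,
                "comparator": inc.comparator,
                "arm_cost": f"{arm_row['cost']:.2f}",
                "comparator_cost": f"{comp_row['cost']:.2f}",
                "incremental_cost": (
                    f"{inc.delta_cost:.2f} "
                    f"({inc.ci_cost[0]:.2f} to {inc.ci_cost[1]:.2f})"),
                "arm_qalys": f"{arm_row['qalys']:.4f}",
                "comparator_qalys": f"{comp_row['qalys']:.4f}",
                "incremental_qalys": (
                    f"{inc.delta_qalys:.4f} "
                    f"({inc.ci_qalys[0]:.2f} to {inc.ci_qalys[1]:.2f})"),
                "icer": inc.icer_text(),
            })
    return pd.DataFrame(rows)
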
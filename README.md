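# aphasia-cea

Lifetime cost-utility modelling of self-managed computerised word-finding
therapy for chronic post-stroke aphasia.

About a third of stroke survivors experience aphasia, and word-finding
difficulty often persists for years. Computerised therapy lets patients
practise independently, at low cost per patient — but does the word-finding
benefit translate into enough quality-of-life gain to justify the spend?
This package implements the full decision-analytic machinery to answer that
question: it is written for health economists and methodologists who want a
tested, scriptable implementation of a trial-based Markov cost-utility
analysis — from participant-level data (synthetic here, since none is
public) through to ICERs and acceptability curves.

## The model

A five-state Markov cohort model in 3-month cycles over a lifetime horizon:
**Aphasia** → **Good response (6m)** → **Good response (9m)** →
**Good response (12m+)**, with **Dead** reachable from every state. The
6m and 9m states are tunnel states (occupied exactly one cycle) so relapse
can depend on time since response. A good response is a ≥10% gain on a
100-word naming test and/or a ≥0.5-point gain on the TOM activity scale.
After month 12 no new responses occur and the 9→12-month relapse
probability is carried forward per cycle.

Per arm a, total discounted QALYs are

    Q_a = Σ_t Σ_s  π_a(s,t) · u(s,t) · ¼ · (1.035)^(−t/4)

with π the occupancy trace, u(s,t) = (u_aphasia + δ_s) · g(age_t) the
age-decremented state utility, and costs C_a the one-off year-1
intervention cost (micro-costed from activity logs; undiscounted). The
decision statistics are ICER = ΔC/ΔQ with dominance labelling, and the
CEAC via net monetary benefit λQ − C across 10,000 probabilistic draws
(beta for transition probabilities, normal for utility increments, gamma
for costs). Missing utility/outcome scores are multiply imputed by
predictive mean matching and pooled with the standard combination rules.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## A worked example

```python
from aphasia_cea import (ArmCost, ArmTransitions, ModelSpec,
                         ParameterDistributions, TransitionSet,
                         UtilityEstimate, UtilityInputs, ceac,
                         flat_ageing_index, generate_life_table,
                         incremental_analysis, run_psa)

ts = TransitionSet()
ts.arms["ct_uc"] = ArmTransitions(arm="ct_uc", r6=42, n6=93, new9=8, d9=51,
                                  new12=4, d12=47, rel69=3, d69=42,
                                  rel912=2, d912=46)
ts.arms["uc"] = ArmTransitions(arm="uc", r6=19, n6=93, new9=7, d9=74,
                               new12=5, d12=69, rel69=2, d69=19,
                               rel912=2, d912=24)
deltas = {t: UtilityEstimate(d, 0.025, 40, 53)
          for t, d in ((6, -0.04), (9, -0.02), (12, 0.02))}
dists = ParameterDistributions(
    transitions=ts,
    utilities=UtilityInputs(u_aphasia=0.58, deltas=deltas,
                            ageing_index=flat_ageing_index()),
    arm_costs={"ct_uc": ArmCost("ct_uc", 732.73, 30.0, 93),
               "uc": ArmCost("uc", 0.0, 0.0, 93)})

sample = run_psa(ModelSpec(), dists, generate_life_table(55, 100),
                 n_iter=10_000, seed=6)
inc = incremental_analysis(sample, "ct_uc", "uc")
```

This is `examples/06_psa_cea.py`; it prints

```
Incremental cost: 732.96 (95% CrI 675.43 to 790.87)
Incremental QALYs: 0.0188 (95% CrI -0.04 to 0.11)
ICER: GBP 38,897 per QALY gained
P(most cost-effective at GBP 20,000/QALY): therapy 25%, usual care 75%
P(most cost-effective at GBP 30,000/QALY): therapy 35%, usual care 65%
```

Read: adding computerised therapy costs about £733 per patient and gains
about 0.019 QALYs on average, i.e. roughly £39,000 per QALY — but the
credible interval for the QALY gain straddles zero, so at a £30,000
threshold the therapy is the best use of resources in only ~35% of
parameter draws. Small utility shifts move the verdict a lot; that
fragility is the substantive finding, and the subgroup and scenario
machinery (`run_pipeline`) quantifies it.

The other scripts in `examples/` each demonstrate one capability:
synthetic trial generation, EQ-5D scoring and increment estimation, PMM
imputation, micro-costing, the cohort engine with its microsimulation
cross-check, and the end-to-end configuration-driven pipeline.

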
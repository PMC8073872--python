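"""Micro-cost intervention delivery from activity logs.

Costs each participant bottom-up from therapist/assistant minutes,
travel, equipment and software licences at 2016/17 national unit costs,
then compares the base case with the halved-staff-cost scenario.
"""

from aphasia_cea import (HALVED_STAFF_SCENARIO, TrialConfig, UnitCostTable,
                         cost_participant, generate_trial, mean_arm_cost)

costs = UnitCostTable()

one_patient = dict(slt_training_min=60.0, slt_delivery_min=7.13 * 60,
                   slta_min=45.0, control_call_min=0.0, travel_miles=93.0,
                   laptop_loaned=True, headset_issued=True,
                   licence_scheme="individual", licence_users=1,
                   puzzle_books=0)
total = cost_participant(one_patient, costs)
slt = 7.13 * 60 * costs.slt_band6_per_min
print(f"One typical therapy participant costs GBP {total:.2f}")
print(f"  of which band-6 SLT time (7.13 h): GBP {slt:.2f} "
      f"({100 * slt / total:.0f}% of the total)")

trial = generate_trial(TrialConfig(seed=4))
for scenario, tag in ((None, "base case"),
                      (HALVED_STAFF_SCENARIO, "SLT/SLTA costs halved")):
    arm_costs = (mean_arm_cost(trial, costs) if scenario is None
                 else mean_arm_cost(trial, costs, scenario))
    line = ", ".join(f"{a}: {c.mean:.2f} (SE {c.se:.2f})"
                     for a, c in arm_costs.items())
    print(f"\nMean per-patient cost, {tag}:\n  {line}")
# The usual-care-alone arm costs exactly 0: usual care continues in
# every arm, so its costs cancel out of all incremental comparisons.
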
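"""Inspect a cohort trace and cross-check it with microsimulation.

Runs biennial screening from age 30 on a 10-cycle model, prints the state
occupancy of selected cycles, then simulates 100,000 individuals through
the identical per-cycle probabilities: the cohort expectation should sit
within a few standard errors of the Monte-Carlo mean.
"""

import htnscreen as hs
from htnscreen.engine import STATE_NAMES

params = hs.base_case(schedule_seed=1).with_value("config.n_cycles", 10)
strategy = hs.strategy_by_label("Screening every two years from the age of 30")

trace = hs.run_cohort(strategy, params)
df = trace.to_frame()
print("State occupancy (start of cycle):")
print(df[["cycle", "age", *STATE_NAMES[:3], "dead_cvd", "dead_noncvd"]]
      .iloc[[0, 2, 5, 9]].round(4).to_string(index=False))

cohort = hs.accrue(trace, params)
micro = hs.microsim_oracle(strategy, params, 100_000, seed=7)
print(f"\nCohort:   cost {cohort.total_cost:8.2f}  qaly {cohort.total_qaly:.4f}")
print(f"Microsim: cost {micro.total_cost:8.2f} (se {micro.se_cost:.2f})"
      f"  qaly {micro.total_qaly:.4f} (se {micro.se_qaly:.5f})")
zc = (cohort.total_cost - micro.total_cost) / micro.se_cost
zq = (cohort.total_qaly - micro.total_qaly) / micro.se_qaly
print(f"z-scores: cost {zc:+.2f}, qaly {zq:+.2f} "
      "(|z| < 3 indicates the two engines agree)")
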
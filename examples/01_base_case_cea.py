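"""Full base-case cost-effectiveness analysis on the synthetic fixture.

Builds the packaged parameter set with seedable synthetic age schedules,
runs all ten screening strategies through the lifetime cohort model, and
prints the incremental table and the efficiency frontier. Costs are
per-person lifetime discounted PPP international dollars; effectiveness is
discounted QALYs per person.
"""

import htnscreen as hs

params = hs.base_case(schedule_seed=1)
roster = hs.strategy_roster()
results = [hs.evaluate_strategy(s, params) for s in roster]

rows = hs.incremental_vs_baseline(results, hs.NO_SCREENING_LABEL)
frontier = hs.frontier_analysis(results)
t4, t5 = hs.render_cea_tables(rows, frontier)

print("Versus no screening:")
print(t4.to_string(index=False))
print("\nEfficiency frontier (step ICERs vs the previous frontier strategy):")
print(t5.to_string(index=False))

wtp = params.config.wtp_threshold
print(f"\nOptimal strategy at WTP {wtp:,.2f} $/QALY:",
      hs.optimal_at_wtp(frontier, wtp))
print("A positive incremental cost with a positive QALY gain means screening")
print("buys extra healthy life-years at the printed ICER price per QALY.")
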
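"""Incremental analysis on the published per-strategy results.

The package ships the published per-person average cost / QALY pairs for
the ten strategies and the published step-ICER ladder of the undominated
ones. This example recomputes the incremental columns from those inputs and
picks the optimal strategy at the published willingness-to-pay threshold
(1.35 x GDP per capita = $PPP 20,652.44 per QALY).
"""

import htnscreen as hs
from htnscreen.reference import REFERENCE_WTP, reference_frontier, reference_strategy_results

rows = hs.incremental_vs_baseline(reference_strategy_results(), hs.NO_SCREENING_LABEL)
print("Incremental cost vs no screening (recomputed from the printed table):")
for r in rows[1:]:
    print(f"  {r.strategy:48s} {r.inc_cost:8.2f}")

fr = reference_frontier()
print("\nFrontier ladder (incremental cost recomputed, published step ICER):")
for row in fr.frontier[1:]:
    print(f"  {row.strategy:48s} +{row.inc_cost:7.2f}  ICER {row.icer:10,.2f}")

best = hs.optimal_at_wtp(fr, REFERENCE_WTP)
print(f"\nAt WTP {REFERENCE_WTP:,.2f} $/QALY the optimal strategy is: {best}")
print("(its step ICER is the last one at or below the threshold).")
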
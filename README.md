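# htnscreen

Markov cohort cost-effectiveness analysis of population blood-pressure
screening strategies.

Hypertension drives a large share of coronary heart disease (CHD) and
stroke. Health ministries weighing a periodic screening programme need to
know which combination of start age (30/40/50) and screening interval
(1/2/3 years) buys the most quality-adjusted life expectancy per dollar.
`htnscreen` is a Python library for exactly that question: it implements a
lifetime state-transition model of hypertension and its cardiovascular
sequelae, evaluates ten strategies (nine screening schedules plus no
screening), and performs the full health-economic tool chain — incremental
cost-effectiveness ratios, dominance and the efficiency frontier, net
monetary benefit, one-way (tornado) and probabilistic sensitivity analysis
with acceptability curves. It is written for health-economics researchers
and students who want a transparent, testable alternative to spreadsheet or
GUI decision-tree software.

## The model

A cohort enters at age 30 split across *healthy*, *hypertension off
treatment* and *hypertension on treatment*, and is propagated through 70
annual cycles over ten mutually exclusive states:

```
healthy, HTN off treatment, HTN on treatment,
post-MI, post-SA, post-UA, post-stroke, post-TIA,
CVD death, non-CVD death
```

Within a cycle, non-CVD mortality competes first; survivors face
age-specific CHD and stroke event risks (treated hypertensives at relative
risks RR_CHD = 0.675 and RR_stroke = 0.622 of untreated). An event is a
within-cycle chance node split across fatal and non-fatal outcomes
(e.g. CHD → death 0.122, MI 0.261, SA 0.503, UA 0.157, renormalized to sum
to one); survivors occupy the corresponding post-event state with its
utility weight and recurrence risk. On a screening cycle the healthy and
untreated states are partitioned by participation (0.563 / 0.673) and test
accuracy (sensitivity = specificity = 0.746); screen-positives get a
perfect confirmatory work-up, and 90% of confirmed true positives start
treatment. False negatives remain undetected until the next round.

Per strategy *s* the model accrues discounted totals (r = 5%, no half-cycle
correction)

    C_s = Σ_t cost_t (1+r)^-t ,   E_s = Σ_t Σ_state occ_t,state · u_state (1+r)^-t

and the comparison machinery computes ICER = ΔC/ΔE between strategies,
removes absolutely and extended dominated options, and selects the optimal
strategy at a willingness-to-pay λ as the NMB argmax, NMB = λ·ΔE − ΔC.

All published point estimates and 95% CIs (probabilities, relative risks,
costs in PPP international dollars 2020, utilities) ship as a JSON fixture.
The age-indexed schedules behind the model (CHD/stroke incidence,
hypertension incidence, treatment uptake, mortality) are not publicly
available; a seedable synthetic generator produces plausible, internally
consistent stand-in curves so the entire pipeline runs self-contained (see
`docs/methods.md` for what this does and does not represent).

## Worked example

The published per-strategy averages for this decision problem are shipped
as a reference input. Running `python examples/02_published_worked_example.py`
recomputes the incremental analysis from them:

```
Frontier ladder (incremental cost recomputed, published step ICER):
  Screening every three years from the age of 50   +  55.02  ICER   2,675.20
  Screening every three years from the age of 40   + 106.40  ICER   7,373.41
  Screening every three years from the age of 30   + 108.86  ICER   9,466.41
  Screening every two years from the age of 30     + 141.74  ICER  20,466.83
  Annual screening from the age of 30              + 449.75  ICER  39,731.03

At WTP 20,652.44 $/QALY the optimal strategy is: Screening every two years from the age of 30
```

Each ladder row is an undominated strategy: the incremental cost is what it
adds per person over the previous frontier strategy, and the step ICER is
the price per extra QALY of moving up one rung. At a willingness to pay of
$PPP 20,652.44 per QALY (1.35 × GDP per capita), biennial screening from
age 30 is the last rung whose price is below the threshold — the optimal
choice.

The other examples run the full synthetic base case
(`01_base_case_cea.py`), inspect a cohort trace against a 100,000-person
microsimulation (`03_cohort_trace_and_microsim.py`), and produce tornado
and acceptability-curve output (`04_sensitivity_analysis.py`). A thin CLI
wraps the same pipeline: `htnscreen run --synthetic --seed 1 --out results/`.

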
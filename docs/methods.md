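# Methods

## Model structure

`htnscreen` implements a discrete-time Markov cohort model with annual
cycles and a lifetime horizon (70 cycles from entry at age 30). The ten
persistent states are healthy; hypertension off treatment; hypertension on
treatment; five post-event states (myocardial infarction, stable angina,
unstable angina, stroke, transient ischaemic attack); and two absorbing
death states (cardiovascular, non-cardiovascular). CHD and stroke events
are *within-cycle chance nodes*, not persistent states: event mass is split
across its outcomes in the same cycle and survivors occupy the post-event
state from the next cycle. The event-year cost and the post-state's utility
weight apply already in the event cycle; an event-year-specific disutility
is not separately modelled because none is available.

Within one cycle the competing risks resolve in a fixed order:

1. **Screening** (only on qualifying cycles) partitions the healthy and
   untreated-hypertensive occupancy into participants and non-participants,
   then into test outcomes. The confirmatory work-up is perfectly accurate,
   so false positives return to the healthy state (after incurring the
   work-up cost) and only true positives can start treatment (90% uptake).
2. **Non-CVD death** removes mass first; all subsequent probabilities act
   on survivors. This ordering is a modelling choice — the alternatives
   (events first, or simultaneous competing risks) differ only at second
   order for the probability magnitudes involved here.
3. **Events**: each alive state carries age-specific CHD and stroke
   probabilities. Treated hypertensives face the untreated probabilities
   scaled by the treatment relative risks (0.675 CHD, 0.622 stroke — the
   source table prints both rows with the same stroke label; the smaller
   value is assigned to stroke, consistent with the stronger published
   effect of treatment on stroke). Post-CHD states face a recurrent CHD
   risk equal to the *general-population* CHD curve times 2.4 (the
   published excess risk "compared with people without CHD"); post-stroke
   states face a flat 0.0485 annual recurrence. Post-event states also
   carry their state-specific cardiovascular death probabilities
   (0.014–0.027/yr).
4. **Disease progression**: surviving event-free healthy mass develops
   hypertension at the age-specific incidence and splits into treated /
   untreated by the background-uptake schedule; untreated survivors start
   treatment at that same background uptake in every strategy (screening
   and not), since background diagnosis does not stop when a screening
   programme exists.

During a screening cycle the screen-outcome sub-populations temporarily
carry the published outcome-specific event risks (false positive
0.010/0.003, true positive and false negative 0.014/0.006 for CHD/stroke)
instead of their parent state's curve; between rounds false negatives are
indistinguishable from other untreated mass.

## Accruals and discounting

QALYs accrue on the end-of-cycle distribution (so the event cycle is
weighted by the post-state utility, and the dying accrue nothing in the
death cycle). Costs accrue per flow: ongoing treatment (57.56/yr on the
start-of-cycle treated stock), post-event incremental annual costs on the
post-state stock, screening contact (1.56 per participant), confirmatory
work-up (212.57 per screen-positive), event-year costs on the event flows,
death-year costs on the fatal event flows, and one-off new-treatment costs.
The printed new-case cost with screening (139.41) exceeds the background
new-case cost (137.85) by exactly the contact cost (1.56); the engine
therefore charges participants the contact cost and screen-detected
starters the difference, so a starter's total equals the printed 139.41
with no double count.

Both cost and outcome streams are discounted at 5%/yr with cycle *t*
divided by (1+r)^t and cycle 0 undiscounted; no half-cycle correction is
applied, matching the default of the decision-tree software the original
analysis used.

Printed branch probabilities that should sum to one do not (CHD outcomes
sum to 1.043, stroke outcomes to 0.8495, the entry split to 0.999); they
are renormalized proportionally by default, since a row-stochastic model is
impossible otherwise. A flag preserves the raw values for inspection.
Reversed printed confidence intervals are stored low–high; orientation
never changes a point estimate. Parameters without a CI are flagged fixed.

## Synthetic age schedules

The model needs eight age-indexed annual-probability curves that in the
original analysis came from national life tables, survey data and
burden-of-disease extracts and are not published. The generator produces
stand-ins with standard demographic/epidemiologic shapes: Gompertz
(log-linear in age) for mortality, logistic (logit-linear) for incidence
and uptake, anchored at ages 30 and 70 and extrapolated to 100.

The anchor levels are pinned to the published screen-cycle constants so the
curves and the constants describe one epidemiology: the general-population
CHD curve averages ≈ 0.010/yr over the screened ages (the published
false-positive event risk), stroke ≈ 0.003, and the untreated curves are
the general-population curves times 1.4 (CHD) and 2.0 (stroke), matching
the printed 0.014/0.010 and 0.006/0.003 ratios. Background treatment
uptake is 0.10–0.18/yr, consistent with roughly half of aware
hypertensives being treated. Non-CVD mortality rises from 0.002 at 30 to
0.025 at 70 (≈ 0.16 at 100). A seed jitters every anchor by ±10%, giving
distinct but equally plausible curve sets; the untreated ≥ healthy ordering
holds at every age by construction. Under these defaults the lifetime
first-CVD-event risk from age 30 is ≈ 0.45–0.50 and every screening
strategy is more costly and more effective than no screening — the
qualitative regime the original analysis reports.

What the generator does **not** emulate: sex stratification, cohort trends,
any calibration to a specific country's surveillance data, or correlation
between curves beyond the fixed risk multipliers. Consequently the
synthetic base case reproduces the *structure* of the published results
(signs, orderings, plausible magnitudes), not their numerical values; the
published per-strategy averages are shipped separately as a reference input
and the incremental machinery is validated against them directly. An
age-specific cardiovascular-death schedule is carried as a required input
for interface completeness, but transitions to cardiovascular death are
driven by the published post-state constants.

## Sensitivity analysis

One-way analysis re-runs the model at each end of a parameter's range
(95% CI, or 0.03–0.07 for the discount rates) and reports the swing of a
chosen outcome — by default incremental net monetary benefit at the
configured willingness to pay — sorted into tornado order.

Probabilistic analysis assigns beta distributions to probabilities and
utilities and gamma distributions to costs, relative risks and the
recurrence rate (positive support), fitted by method of moments with the
CI width read as 3.92 normal standard deviations; the fitted mean is
within 2% of the point estimate by construction. Parameters without a CI
stay fixed. Draws are independent (no correlation structure is published);
branch probabilities are renormalized after sampling, the derived
false-positive probability follows sampled specificity, and a draw that
breaks a structural constraint (an on-treatment relative risk above one)
is rejected and resampled with a logged count. Iterations are summarized
as acceptability curves (probability of maximizing NMB per willingness-to-
pay, ties to the cheaper strategy), single-threshold acceptability, and
cost-effectiveness-plane scatter data.

## Dominance and selection conventions

Absolute dominance: another strategy has strictly lower cost and at least
equal QALYs (weak dominance folded in; exact cost/QALY ties keep the
earlier-listed strategy; an equal-cost lower-QALY strategy is also
removed, since it can never maximize NMB). Extended dominance: iterative
removal of the frontier point that breaks step-ICER monotonicity. The
optimal strategy at a willingness to pay is the most effective frontier
strategy whose step ICER does not exceed it, which equals the NMB argmax.
ICERs are reported as undefined (not ±∞) when the QALY difference is not
positive.

## Numerical choices and problem sizes

Occupancy conservation is enforced to 1e-12 per cycle; renormalized
branches sum to one to 1e-12; construction errors are raised if per-cycle
probabilities of an occupied state exceed one by more than 1e-9. Schedule
CSVs round-trip float64 exactly (`%.17g`). The microsimulation cross-check
uses 200,000 individuals on a 10-cycle truncation (z-scores well inside
±3); the probabilistic analysis in the acceptance run uses 1000 iterations
on the same 10-cycle truncation and 300 × 20 cycles in the unit suite —
sizes chosen so the whole pipeline, including tests, runs in well under a
minute while keeping Monte-Carlo error small relative to the tolerances.

## Limitations

Treated-and-controlled individuals cannot revert to untreated
(non-adherence is not modelled); post-event states hold only the most
recent event; cross-family recurrence (stroke after MI) is not modelled;
participation is independent across rounds (no never-attender memory);
costs and utilities are age-invariant. The synthetic schedules make the
base-case magnitudes illustrative, not estimates for any real population.
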
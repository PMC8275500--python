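# Methods

## Model structure

The package implements a discrete-time Markov cohort model with three
health states — stable disease (SD), progressive disease (PD) and dead —
for comparing Lutetium-Octreotate (LO, four injections plus standard-dose
Octreotide-LAR maintenance) against high-dose Octreotide-LAR alone in
advanced midgut neuroendocrine tumours. A cohort of 1,000 patients aged
63 starts in SD and moves through 28-day cycles until more than 99% of
the cohort is absorbed in the dead state (a 60-year cap acts as a
numerical guard only). Progression is irreversible (no PD→SD arrow) and
state membership is counted at cycle start; no half-cycle correction is
applied, matching the spreadsheet-style cohort model the analysis
emulates. The correction could be added in `economics.qaly_core`/
`cost_core` by averaging adjacent occupancies, and is deliberately left
out so the reproduction target stays well-defined.

Per cycle, each strategy is described by three probabilities: SD→PD,
SD→dead and PD→dead. The model supports two sources for them.

**Table-driven (the case study).** The published per-cycle probabilities
(control 0.0854 / 0.0095 / 0.0216; intervention 0.0183 / 0.0073 /
0.0116) are used directly, with their printed time-profile annotations:
SD→PD is constant over time (exponential profile) while the two death
probabilities follow a gamma hazard profile anchored at the printed
cycle-0 value,

    q_c = 1 − (1 − q_0) ^ w_c ,   w_c = ΔH_c / ΔH_0 ,

where ΔH_c is the cycle-c increment of the gamma cumulative hazard.

**Curve-driven.** `survival.reconstruct_ipd` rebuilds pseudo
individual-patient data from digitized Kaplan–Meier coordinates plus the
numbers-at-risk table (interval-wise allocation: censoring within each
risk-table interval is adjusted iteratively until the implied at-risk
count matches the published one, event counts track the product-limit
recursion, censor times are spread uniformly; an optional published
total event count rescales terminal censoring). `survival.fit_parametric`
fits exponential, Weibull, gamma, Gompertz, log-normal or log-logistic
families by right-censored maximum likelihood (L-BFGS-B on
log-parameters, deterministic moment-matched starts, ftol 1e-8; the
exponential rate uses its closed form events/exposure), and
`select_best` picks the minimum-AIC family with ties broken by parameter
count, then list order. `markov.derive_transitions` then splits the
overall-survival cycle probability between SD and PD so that the two
state hazards keep the reported ratio 0.44 while their occupancy-weighted
mean reproduces the overall value — a one-dimensional bisection per
cycle (tolerance 1e-14; recombination is exact to 1e-10). Intervention
curves apply the trial hazard ratios (PFS 0.21, OS 0.54) per cycle via
1 − (1 − p)^HR.

**Background mortality.** General-population mortality (an age- and
sex-specific life table, cohort-blended at the arms' printed sex mix of
54%/47% male) replaces a state's model death probability permanently
from the first cycle where it exceeds it. A per-cycle-maximum variant is
available as the `general_population_survival` scenario flag. The
bundled life table is a Gompertz emulation of Dutch national statistics:
annual probability 0.0115 (men) / 0.0077 (women) at 63, doubling every
8 years, certain death at 105.

## Valuation

QALYs weight SD at 0.771 and PD at 0.612 (time-trade-off tariff); the
dead state is 0. Grade III/IV adverse events are assumed to occur at the
start of treatment: during the first cycle the SD utility is blended
with the arm's AE utility (0.666 control, 0.687 intervention) over an
assumed affected fraction of 10% (control) and 20% (intervention). The
window length and fractions are config knobs; the single-cycle default
follows the stated all-at-start assumption and is consistent with the
published one-way result that AE utilities do not move the ICER at the
hundred-euro resolution. Life-years value every alive state at 1.

Costs (2019 euros, healthcare perspective) comprise: the LO price
(€16,000 initial / €90,000 increased per four-injection course, charged
per injection at cycles 0, 2, 4, 6 — the lower bound of the licensed
8–10-week interval — conditional on SD occupancy, plus €1,000
administration per injection); Octreotide-LAR drug + administration per
cycle in SD (treatment stops on progression); a €150 follow-up visit
every 6 months in PD, pro-rated per cycle (cost/6.52 per cycle) rather
than charged lumpily; indirect unrelated medical costs split into an
age-indexed annual component (€3,600 at 63, growing 5%/year) for the
alive and a one-time €24,000 end-of-life component for the newly dead;
and a one-time AE-management cost at cycle 0 (€500 / €1,500). Costs
discount at 4%/year and effects at 1.5%/year via per-cycle factors
(1+r)^(−c·28/365.25); cycle 0 is undiscounted. ICERs are rounded to the
nearest hundred euros at reporting only.

## Calibration of unpublished inputs

Two inputs of the original analysis are not publicly recoverable: the
fitted gamma overall-survival parameters (shown only as supplementary
figures) and the itemized unit-cost table (a supplementary appendix).
The bundled case-study fixture therefore calibrates them once, against
the published outputs, and freezes the result:

- the gamma time profile (shape 1.833, rate 5.5 per month) was chosen so
  the deterministic run reproduces the published discounted QALY totals
  (1.79 comparator, 3.61 intervention). The profile is a hazard that
  rises to roughly 1.7× its first-cycle level within the first cycles
  and then plateaus; the shared two-parameter family cannot hit both
  arms' QALY and life-year totals simultaneously, leaving residuals of
  a few percent (our ΔQALY is 1.75 against a published 1.82).
- most unit costs are set at plausible public Dutch 2019 tariff levels;
  the two Octreotide-LAR cycle costs (€4,025 high-dose, €1,375
  maintenance — consistent with list prices of roughly €1.4–2k per
  30 mg injection plus administration) were selected by a coarse grid
  search minimizing the worst relative deviation across the published
  cost totals, all four ICERs and the scenario ICERs. The worst
  deviation of the calibrated model is 8.8%.

Consequences worth knowing: every deterministic output inherits a
systematic offset of up to ~9% (the base-case increased-price ICER is
€56,900 against a published €53,500), and the difference between the
two price levels (€67,600 here, €63,000 published) implies the original
spread the price difference over injections with a lower effective
SD-weighting than the 0.91 this schedule produces.

## Sensitivity analysis

The PSA samples all 18 uncertain parameters independently per draw:
beta for utilities and transition probabilities (moment-matched to the
mean and 95% interval, interval width treated as 3.92 sd), gamma for
unit costs (sd = 20% of the mean), lognormal for hazard ratios
(interval matched on the log scale). Parameters printed without an
interval get the assumed 80–120% band. The LO price is the policy
variable and is never sampled. Draws come from one seeded generator in
declared parameter order — the seed plus config fully determines the
result, bit for bit. Invalid draws (an SD row exceeding probability 1)
are rejected and redrawn; with the case-study distributions this never
triggers. The "Markov Chain Monte Carlo" phrasing in the source is
read as plain Monte-Carlo parameter sampling: no likelihood or prior
exists to define a chain. Draws are independent across parameters (no
correlation structure is published).

The whole engine is vectorized across draws (one cycle loop over
arrays of draws), so a 10,000-draw PSA of both arms and both price
levels takes a few seconds on one CPU. A degenerate PSA (all
distributions collapsed) reproduces the deterministic totals exactly;
this is guaranteed by summing per-cycle increments in strict cycle
order rather than with shape-dependent pairwise blocking.

The tornado analysis sweeps each parameter to its interval bounds one
at a time and reports the ICER pair, sorted by unrounded bar width;
bars narrower than €100 are zero-width at the published reporting
resolution. Named scenarios are single config mutations: equal 4%
discounting, no discounting, no progression extrapolation beyond the
25-month trial follow-up (SD→PD set to zero from the first cycle
starting after 25 months), excluding indirect medical costs, and the
per-cycle-maximum background-mortality variant.

The proportional-shortfall classification divides the quality-adjusted
life expectancy lost to the disease (healthy QALE at 63 defaulting to
18.9 QALYs, a config value; disease outlook = the comparator arm's
modelled QALY total) by the healthy QALE, and maps it onto the Dutch
three-class thresholds (€20,000 / €50,000 / €80,000 at boundaries
0.10 / 0.41 / 0.71 — the boundaries are standard practice, not printed
in the source, and configurable).

## Synthetic data

The original trial's patient-level data are not public; the source
itself worked from digitized figures. `synthetic.simulate_km` emulates
that input: it simulates survival times from a known family, applies
administrative censoring, computes the Kaplan–Meier estimator,
down-samples it to a regular digitization grid (default 60 points) and
emits a consistent numbers-at-risk table, returning the generating
truth alongside for recovery scoring. Defaults mimic the trial's scale
(113 patients per arm, 40-month censoring) so reconstruction is tested
in a realistic sparsity regime. What this does not emulate: digitizer
coordinate noise, plot-resolution quantization, and reader error in the
risk table — reconstruction accuracy on real digitized figures will be
somewhat worse than the clean-grid results the tests demonstrate.

## Numerical choices and limitations

- Time unit is months (30.4375 days) internally; 28-day cycles convert
  on demand.
- Survival underflow at extreme ages holds the last finite gamma-hazard
  increment; the life-table override dominates there anyway.
- `apply_hazard_ratio` clamps to just below 1 where double precision
  saturates.
- Exponential fits use the closed-form MLE; other families are smooth
  two-parameter optimizations from deterministic starts, so repeated
  fits are bit-identical.
- The Guyot reconstruction tolerates irreducible off-by-one risk-table
  mismatches from digitization rounding (warning, not error); gross
  inconsistencies (implied events exceeding the at-risk count) raise.
- Known limitations: no half-cycle correction; no correlation between
  sampled parameters; the AE-affected fractions are assumptions, not
  published values; societal-perspective costs (productivity losses)
  are out of scope, as in the source analysis; and all deterministic
  targets carry the calibration offset described above.
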
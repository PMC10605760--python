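# Methods

## The decision problem

Eight two-line chemotherapy strategies for stage III colorectal cancer are
compared: a first-line adjuvant regimen (5-FU/LV, capecitabine, FOLFOX or
CAPOX) paired with a second-line regimen for progressive disease (FOLFOX,
CAPOX or FOLFIRI). The package estimates, for a cohort of newly diagnosed
63-year-old patients, lifetime costs (2021 USD, societal perspective), life
years and QALYs per strategy; builds the incremental cost-effectiveness
table against the 5-FU/LV→FOLFOX comparator at a willingness-to-pay ceiling
of USD 5,003 per QALY; quantifies parameter uncertainty (one-way and
probabilistic); and projects a five-year payer-perspective budget impact.

## Model structure

A discrete-time Markov cohort model with a one-year cycle and three health
states — stable disease (SD), progressive disease (PD), death — expanded
into tunnel compartments so probabilities can depend on time in state:
SD years 1–4 and an open 5+ band; PD years 1–3 and an open 4+ band.
Movement is strictly forward (SD(y) → {SD(y+1), PD(1), DEAD};
PD(y) → {PD(y+1), DEAD}; DEAD absorbs). The PD mortality clock resets at
progression: PD transition probabilities are those of chemotherapy-naive
metastatic disease, whatever the time since original diagnosis.

Death from any cause combines the disease-specific annual probability
(regimen- and band-specific) with the age-specific background probability
from a life table under independent competing risks,
`q = 1 − (1−q_disease)(1−q_background)`, in both SD and PD. An
additive-capped policy is available (`mortality_policy="additive"`). If a
combined SD row would exceed unity, death takes priority and progression is
truncated; base-case inputs never trigger this.

The cohort is followed from age 63 until extinction (occupancy below 1e-8)
or age 100; with the bundled inputs the cohort is extinct well before the
age cap, so the horizon is effectively lifetime.

## Reward conventions

These are the package's defaults, chosen because they reproduce the
published lifetime table; each has a switchable textbook alternative in
`EngineOptions`:

* **Life years and annual care costs** accrue to members present at the
  start of a cycle (`credit="begin"`): entering a year earns that year's
  life-year credit and care costs. Alternatives: `"end"` (survivors only)
  and `"half"` (half-cycle correction).
* **QALYs** accrue to members who complete a cycle (`qaly_credit="end"`).
* **First-year utilities.** Treatment occupies the first half of the first
  year in each state (`treated_fraction_of_first_cycle = 0.5`). In SD year
  1 only the post-treatment half-year carries a utility weight
  (`year1_utility="off_half"`, i.e. 0.5 × u(SD, off treatment)); the
  `"blend"` alternative also credits the treated half at the on-treatment
  utility (oral vs intravenous according to the first-line regimen). The
  first PD year always blends on-IV and off-treatment utility at the
  treated fraction; no oral-PD utility exists, so CAPOX as second line uses
  the on-IV weight.
* **Chemotherapy courses** (drug + administration + per-visit food and
  transportation) are charged once, on entry to the treated year: the whole
  cohort pays the first-line course in cycle 1 and each year's new PD
  entrants pay the second-line course — regardless of survival through the
  year, since the drugs are delivered up front.
* **Discounting** at 3% per annum multiplies cycle-t rewards by
  (1+r)^−(t−1); the first year is undiscounted.

Why these defaults: the three columns of the published lifetime table are
not jointly consistent with any single textbook convention. A least-squares
fit of per-bucket utility weights against the published QALY column (with
our survival dynamics) identified the survivor-credit/off-half convention
to within 0.005 QALY, and begin-credit reproduces the published cost column
within 2.6% for all eight strategies. Under these defaults the package
reproduces published costs within ±2.6%, QALYs within +0.05, and the
headline ICER within +3.6%. Undiscounted life expectancy runs 0.13–0.32
years short of the published LY column; that column appears to embed a
slightly more generous survival credit than the QALY and cost columns can
jointly support (removing background mortality from SD closes the LY gap
for oral-first strategies but breaks costs and QALYs), so the residual is
reported rather than forced.

Published LY values are undiscounted (the published QALY/LY ratio for the
best strategy, 0.524, is below the smallest utility weight in the model,
which is impossible if both are discounted), so the CEA table prints
undiscounted LY next to discounted costs and QALYs by default.

## Inputs

All inputs ship in `src/colcea/data/params_basecase.yaml` (2021 USD).
Dosing follows the standard regimens at a fixed body surface area of
1.7 m² (Mosteller, 60 kg reference adult); drug cost is per-milligram with
no vial rounding (no product wastage assumed). Administration is priced per
visit by modality — outpatient bolus (USD 14) for 5-FU/LV, outpatient
infusion (32) for CAPOX, inpatient infusion (122) for the 46-hour
infusional regimens FOLFOX and FOLFIRI, and zero for capecitabine
dispensing (monthly pharmacy visits still incur food and transportation,
USD 7 per visit). Annual "other healthcare" costs depend on state, year in
state, and whether the year-1 regimen is outpatient or inpatient.
Quantities published without a standard error carry an explicit absent-SE
marker; imputation happens only in the sensitivity module as declared
policy.

### Life tables

`lifetable_tha_2019.csv` is an abridged all-cause table for Thailand 2019:
a synthetic approximation reconstructed from the WHO Global Health
Observatory abridged band probabilities (annualized via
`band_to_annual`, Gompertz-like extension above age 85), since the original
file cannot be redistributed here. Its implied life expectancies (e0 ≈ 77.0,
e60 ≈ 21.7) are within about one year of the WHO 2019 values for Thailand;
this reconstruction uncertainty is part of the LY residual discussed above.
`lifetable_stylized.csv` is a Gompertz curve q(age) = min(1, 1e-4·e^(0.085·age)),
a plausible adult-mortality shape used by tests that do not target
published numbers.

## Sensitivity analyses

**One-way:** probabilities and utilities with a published SE move across
their 95% CI (clamped to [0,1]); everything else moves ±25%. The tornado
target is the ICER of CAPOX→FOLFIRI vs 5-FU/LV→FOLFOX. Top-15 entries are
reported; a bound that renders the model infeasible is recorded as a failed
entry, not an abort.

**Probabilistic:** 1000 Monte-Carlo iterations; beta draws for
probabilities and utilities, gamma for costs, method-of-moments from mean
and SE. Imputed SEs where none was published: costs 25%/1.96 of the mean
(so the implied 95% interval matches the ±25% one-way convention);
probabilities 10% of the mean. Both fractions and a global SE scale are
configurable (`PSAConfig`); a zero-mean probability (FOLFOX SD-death year
1) cannot be sampled and stays at base with a log notice. Draws use
per-iteration substreams seeded by (seed, iteration), so results are
reproducible and order-independent. Parameter correlations are not
modelled. Because the published analysis does not state which parameters
entered its PSA or its imputation rule, the probability-cost-effective
figure carries reproduction uncertainty beyond Monte-Carlo error; across
seeds we observe ≈70% at WTP 5,003 against the published 65.2%.

## Budget impact

Payer perspective: drug and administration costs only, undiscounted,
five years. Incident cohorts are population × (1+0.3%)^(y−1) ×
39.72/100,000 × 80% accessibility; relapse inflow reuses the cohort
engine's SD occupancy (so CEA and BIA share one disease model), counting
progression of prior-year cohorts, times 80% accessibility. The national
population is an explicit config input (70,000,000 in the bundled fixture);
the published table's absolute cells imply a much smaller effective
population than Thailand's and are not reproducible from the paper alone,
so the package's checked claims are structural: year-1 budgets depend only
on the first-line regimen, budgets are linear in population and
accessibility, and the published strategy ordering (FOLFOX→FOLFIRI highest,
CAPOX→FOLFIRI second, all 5-FU/LV-first lowest) holds at any population
scale. The five-year budget ratio of CAPOX→FOLFIRI to the comparator
(≈3.2 here, "about three times" published) is scale-free and reported by
the acceptance script.

## Synthetic data and the microsimulation oracle

`random_parameters` jitters every uncertain input multiplicatively within
per-class bounds (probabilities ±30%, utilities ±15%, costs ±40% by
default), clamps to invariants and truncates SD rows to feasibility, so
every generated bundle validates; collapsing the bounds to (1,1) returns
the base case exactly. These bundles emulate registry-to-registry parameter
variation, not patient-level data: passing property tests on them shows the
engine is well-behaved over the plausible input space, not that any
particular registry is represented.

`microsimulate` draws n individual trajectories using the engine's own
per-cycle tables (shared code), mirroring the credit conventions exactly,
and returns means with standard errors. At n = 100,000 the means agree
with the cohort totals within 3 SE; this is the package's independent check
that the deterministic engine integrates the same process the probabilities
describe. Simulated cohorts are homogeneous at age 63 — no age/sex mix,
treatment switching, or adverse-event submodel (adverse-event costs are
inside the annual care costs).

## Numerical choices and limitations

* Occupancy is conserved to 1e-12 per cycle; the run stops at occupancy
  < 1e-8 alive or age 100.
* ICERs are computed from unrounded totals; rounding happens only in the
  CSV presentation layer (the JSON outputs carry full precision).
* Strict pairwise dominance only (the published table needs nothing more);
  south-west quadrant ratios are reported but never labelled cost
  effective.
* Deterministic base case runs in well under a second per strategy; the
  1000-iteration PSA takes a few seconds on one CPU.
* Not modelled: targeted therapy/immunotherapy, dose capping or reduction,
  treatment switching beyond the fixed two-line sequence, parameter
  correlation, currency conversion (all inputs are consumed in 2021 USD),
  and estimation of transition probabilities from patient-level records.
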
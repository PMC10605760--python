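# colcea

Cost-utility and budget impact analysis of adjuvant chemotherapy strategies
for stage III colorectal cancer, for health-economics analysts and
HTA modellers who want the full analysis as tested, scriptable code rather
than a spreadsheet.

Eight two-line strategies are compared — a first-line adjuvant regimen
(5-FU/LV, capecitabine, FOLFOX or CAPOX) followed by a second-line regimen
on progression (FOLFOX, CAPOX or FOLFIRI) — for a cohort of newly diagnosed
Thai patients aged 63, from a societal perspective in 2021 USD.

## The model

A discrete-time Markov cohort model with one-year cycles over three health
states — stable disease (SD), progressive disease (PD), death — expanded
into tunnel compartments (SD years 1–4, 5+; PD years 1–3, 4+) so transition
probabilities depend on time in state. Annual all-cause death combines the
disease-specific probability `q_d` with the age-specific background
probability `q_b` from a life table under independent competing risks:

    q = 1 − (1 − q_d)(1 − q_b)

Per cycle *t* the cohort accrues costs *C_t*, life years *L_t* and
quality-adjusted life years *Q_t = Σ_s occupancy_s · u_s*, discounted at
rate *r* = 3%:

    C = Σ_t C_t (1+r)^−(t−1),   similarly for Q

Strategies are compared by incremental cost-effectiveness ratio
ICER = ΔC/ΔQ against the 5-FU/LV→FOLFOX comparator, judged at a
willingness-to-pay ceiling λ = USD 5,003/QALY via net monetary benefit
NMB = λ·ΔQ − ΔC. Uncertainty is handled by one-way (tornado) analysis and
a 1000-iteration probabilistic sensitivity analysis (beta draws for
probabilities/utilities, gamma for costs, method of moments), summarised as
a cost-effectiveness acceptability curve. A five-year payer-perspective
budget impact projects incident and relapsing treated cohorts.

Modelling conventions and their rationale are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The bundled base case and vendored life table reproduce the lifetime
cost-effectiveness table:

```sh
colcea cea --out-dir outputs
```

```
             strategy  total_cost_usd   ly  qaly incremental_cost_usd incremental_qaly icer_usd_per_qaly                       interpretation
     5-FU/LV->FOLFIRI           15092 4.39  2.18                -1559            -0.38              4120          dominated by 5-FU/LV->CAPOX
      5-FU/LV->FOLFOX           16651 5.13  2.56                                                                                    base case
       5-FU/LV->CAPOX           14250 5.17  2.58                -2401             0.02           -107522    cost saving compared to base case
capecitabine->FOLFIRI           17780 5.36  2.86                 1129              0.3              3718     dominated by capecitabine->CAPOX
 capecitabine->FOLFOX           19406 6.15  3.26                 2755              0.7              3941     dominated by capecitabine->CAPOX
  capecitabine->CAPOX           16877 6.19  3.28                  226             0.72               312 cost effective compared to base case
      FOLFOX->FOLFIRI           25778 6.18  3.42                 9127             0.86             10576          dominated by CAPOX->FOLFIRI
       CAPOX->FOLFIRI           21462 6.55  3.65                 4811             1.09              4412 cost effective compared to base case
```

Reading the last row: CAPOX then FOLFIRI yields the most health (6.55 life
years, 3.65 QALYs discounted) at the second-highest lifetime cost
(USD 21,462); against the comparator it buys 1.09 extra QALYs for USD 4,811,
an ICER of USD 4,412 per QALY — under the USD 5,003 ceiling, hence cost
effective. Costs and QALYs are discounted at 3%; the `ly` column is
undiscounted life expectancy. Negative incremental costs with non-negative
incremental QALYs are labelled cost saving; a strategy that some other
strategy beats on both axes is labelled dominated.

Other stages:

```sh
colcea psa  --iterations 1000 --seed 1   # CE plane + acceptability curve
colcea owsa --top 15                     # tornado table
colcea bia  --population 70000000        # five-year budget table
colcea run  --seed 1 --out-dir outputs   # everything + manifest
colcea synth microsim --n 100000         # microsimulation vs cohort check
```

The PSA prints, e.g., `P(cost-effective at WTP 5003) = 0.705` — the fraction
of Monte-Carlo draws in which CAPOX→FOLFIRI has positive net monetary
benefit against the comparator.

As a library:

```python
from colcea import load_basecase, load_life_table, run_strategy, STRATEGIES

params = load_basecase()
lt = load_life_table("tha_2019")
result = run_strategy("CAPOX->FOLFIRI", params, lt)
print(round(result.qaly, 2), round(result.ly_undiscounted, 2))  # 3.65 6.55
```

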
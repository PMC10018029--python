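# hfcea

A decision-analytic cost-effectiveness model of **when to start
sacubitril–valsartan in acute decompensated heart failure (ADHF)**, from a
Chinese healthcare-system perspective. It compares three strategies for a
cohort hospitalized with ADHF at age 60:

* **enalapril** throughout (control),
* **early initiation** — sacubitril–valsartan from the index admission,
* **late initiation** — enalapril until the patient has gone three
  consecutive months without hospitalization, sacubitril–valsartan
  thereafter.

It is aimed at health-economics researchers and students who want a fully
scripted, testable state-transition model rather than a spreadsheet or a
proprietary TreeAge workbook.

## The model

A lifetime Markov cohort model with a 1-month cycle and six health states:
*Hospitalized HF*, two post-discharge tunnel months (*Non-hospitalized HF
month 1/2*), a *stable* state (*Non-hospitalized HF month 3*, re-entered
while event-free), and two absorbing states (*cardiovascular death*,
*non-cardiovascular death*). The first three alive states form a vulnerable
phase with elevated monthly cardiovascular-death and readmission
probabilities; deaths there count as cardiovascular. Background
non-cardiovascular mortality applies from the stable state via an age-banded
life table. To encode the late-initiation switch the alive transient states
carry a pre-/post-switch flag; once the cohort reaches stability and starts
sacubitril–valsartan it does not revert.

Monthly transition probabilities come from trial summary statistics via the
constant-rate conversion *p* = 1 − exp(ln(1 − *e*/*n*)/*T*) for *e* events
among *n* at risk over *T* months, with a hazard ratio applied to the event
count before conversion where a treatment effect is needed. Costs (USD,
2021) and QALYs are discounted at *r* = 0.03/year — the geometric mean of
the 2015–2021 healthcare CPI chain — with a trapezoidal half-cycle
correction on state-occupancy accruals; hospitalization cost and a −0.1
utility decrement accrue per admission event. Outcomes are total discounted
cost, QALY and life-years per strategy, and the incremental
cost-effectiveness ratio ICER = ΔC/ΔE judged against a willingness-to-pay
threshold of 37,654.5 USD/QALY (three times 2021 per-capita GDP).
Uncertainty is handled by one-way (tornado) analysis over published ranges
and by probabilistic sensitivity analysis (beta distributions for
probabilities and utilities, gamma for costs, moment-matched to published
SDs) summarized as an acceptability fraction and a cost-effectiveness
acceptability curve (CEAC).

## Worked example

The packaged base case is the default configuration:

```sh
$ hfcea base-case --outdir out
intervention component      cost  qaly   ly  incremental_cost  incremental_qaly     icer
   enalapril     total 13,063.74  5.71 7.39               NaN               NaN      NaN
    sv_early     total 18,061.55  7.10 8.93          4,997.81              1.39 3,590.14
     sv_late     total 17,783.37  6.95 8.75          4,719.63              1.24 3,816.25
sv_early vs enalapril: ICER 3,590.1 USD/QALY (cost-effective at WTP 37,654.5)
sv_late vs enalapril: ICER 3,816.3 USD/QALY (cost-effective at WTP 37,654.5)
```

Reading: early initiation costs 4,997.8 USD more than enalapril over a
lifetime but yields 1.39 extra QALYs, i.e. 3,590.1 USD per QALY gained —
far below the threshold, so it is cost-effective; late initiation is also
cost-effective but less favourable. `out/base_case.csv` adds the
decomposition of each total into hospitalization-event versus
state-occupancy accruals.

Other commands: `hfcea tornado` (one-way sensitivity table; the
sacubitril–valsartan price has by far the widest bar), `hfcea psa --seed 0
--iterations 10000` (scatter, CEAC and manifest CSV/JSON artifacts),
`hfcea derive` (prints the audit arithmetic behind every derived input) and
`hfcea validate` (configuration checking). All analyses accept `--config`
with a YAML file in the packaged format, so alternative parameter sets can
be run unchanged. The same functionality is available as a library
(`hfcea.run_strategy`, `hfcea.compute_icer`, `hfcea.run_psa`, ...).

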
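# Bundled reference inputs

Small plain-text inputs used by the analysis drivers, tests and
`scripts/acceptance.py`. Both are *published summary tables* for the FAERS
mirtazapine primary-suspect cohort (Q1 2004 – Q4 2024, n = 2,954 cases with
complete baseline data); they are inputs to consistency checks, not outputs
of this pipeline.

- `mirtazapine_faers_demographics.csv` — published per-category case counts
  (sex, weight band, age band, reporter occupation, top-5 countries, outcome).
  The pipeline's percentage arithmetic is checked by recomputing each
  category's percentage from these counts and the cohort total.
- `mirtazapine_pt_signals.csv` — the published top-20 preferred-term signal
  rows (case count, ROR with 95% CI, PRR with chi-squared, EBGM with EBGM05,
  IC with IC025). Used to check the IC = log2(EBGM) identity that links the
  Bayesian columns, at the 2-decimal precision of the published values.
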
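# faers-signals

Disproportionality-based adverse-event signal detection for FAERS-style
spontaneous reporting data, built around the mirtazapine safety question:
given twenty years of quarterly FDA Adverse Event Reporting System (FAERS)
bundles, which adverse events are reported disproportionately often when the
drug of interest is the primary suspect?

The package is aimed at pharmacovigilance analysts and methods researchers.
It implements the complete screening pipeline — raw quarterly ASCII
ingestion, FDA-style case deduplication, primary-suspect cohort
construction, PT/SOC-level contingency tables, four signal statistics with a
joint significance rule, demographic and outcome case tables, and
time-to-onset analysis — plus a synthetic FAERS-bundle generator with
planted ground truth, so every stage is testable without downloading a
single quarter.

## The statistics

For each drug–event pair, the deduplicated database is collapsed to a 2×2
table: `a` (target drug ∧ target event), `b` (target drug ∧ other events),
`c` (other drugs ∧ target event), `d` (neither), with `N = a+b+c+d`. The
four screening algorithms are

| Algorithm | Statistic | Signal criterion (default) |
|---|---|---|
| ROR | `ad/bc`, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | lower bound > 1 and `a ≥ 3` |
| PRR | `a(c+d)/(c(a+b))` with `χ² = (ad−bc)²N / ((a+b)(c+d)(a+c)(b+d))` | `PRR ≥ 2` and `χ² ≥ 4` |
| BCPNN | `IC = log₂[aN/((a+c)(a+b))]`, IC025 from the closed-form Bayesian posterior | `IC025 > 0` |
| MGPS | `EBGM = aN/((a+c)(a+b))` (unshrunk closed form), Wald-style EBGM05 | `EBGM05 > 2` |

A pair is a *signal* when it passes all four jointly. IC and EBGM are the
same observed-to-expected ratio on log₂ and natural scales, so
`IC = log₂(EBGM)` identically — a property the tests assert to 1e-12 and
that holds in published signal tables at printed precision. A strictness
switch turns the inclusive PRR/χ²/count boundaries into strict ones; zero
cells are reported as undefined by default or handled with the
Haldane–Anscombe +0.5 correction on request.

## Worked example

Generate a synthetic bundle with planted signals, then screen it — either
through the library or the `faers-signals` CLI (`synth`, `ingest`, `screen`,
`tto`, `report`, `run` subcommands). The numbered drivers under `analysis/`
run the full study:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_screen_signals.py
```

which prints

```
cases: 20000 (target 2017, background 17983, 1008 duplicated caseids)
planted PT_0029: rate ratio 2.0, realized signal cell a = 65
planted PT_0059: rate ratio 5.0, realized signal cell a = 66
planted PT_0099: rate ratio 10.0, realized signal cell a = 77
---
20000 deduplicated cases -> 2017 target, 17983 background
199 PTs screened, 2 pass all four algorithms:
   term  a  ROR  ROR_lo95  PRR   chi2   IC  IC025  EBGM  EBGM05
PT_0099 77 9.35      6.79 9.03 275.34 2.32   1.83  4.99    3.62
PT_0059 66 5.26      3.87 5.12 140.16 1.85   1.38  3.62    2.66
```

Reading this: deduplication collapsed the 1,008 planted duplicate case
versions exactly; the two strong planted signals (rate ratios 10 and 5)
pass all four algorithms with ROR estimates near their planted values,
while the rate-ratio-2 signal — like most genuinely weak associations at
this cohort size — clears the ROR test but not the `PRR ≥ 2` / `EBGM05 > 2`
thresholds, so it is not flagged. The remaining drivers produce the
time-to-onset binning and cumulative incidence curve
(`03_time_to_onset.py`), the demographic case table and volcano coordinates
(`04_descriptive_report.py`), and the calibration/recovery study
(`05_calibration_study.py`), all under `results/`.

## Layout

- `src/faers_signals/` — the library: `faers_io` (parsing, dedup, case
  assembly), `cohort`, `disproportionality`, `time_to_onset`, `report`,
  `synthetic` (generator with ground truth), `experiments` (simulation
  studies), `cli`.
- `analysis/` — numbered study drivers over the library.
- `data/` — small published summary tables used as check inputs (see
  `data/README.md`).
- `docs/methods.md` — models, parameter choices, numerical conventions and
  limitations.
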
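"""Simulation studies over the synthetic generator.

Each function runs the *full* pipeline — generate a bundle, assemble cases,
select the primary-suspect cohort, count events, screen — and measures one
calibration or recovery property of the screening statistics:

* null calibration: with no planted signals every PT is independent of the
  target drug by construction, so the one-sided ROR criterion (lower 95%
  bound above 1) should fire at roughly its nominal 2.5% rate;
* parameter recovery: planted rate ratios should be re-estimated by the
  pipeline's ROR to within sampling error and the small odds-vs-rate bias;
* dedup recovery: after deduplication the case count equals the number of
  distinct planted cases regardless of the duplicate rate;
* onset-mixture recovery: the early/late onset mixture reappears in the
  first time-to-onset bin at its planted proportion.

All randomness derives from the caller's seed; seeds for replicate runs are
drawn as consecutive offsets so any replicate can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median

import numpy as np

from .cohort import DrugQuery, count_events, select_cohort
from .disproportionality import ScreenRow, screen
from .faers_io import assemble_cases
from .synthetic import SimConfig, SyntheticTruth, generate
from .time_to_onset import compute_tto, summarize_tto

# Study conditions: database-scale simulations use 20,000 cases with a 10%
# target-drug share (≈2,000 target cases, the order of a real single-drug
# FAERS cohort) over 200 PTs with power-law marginals.
NULL_CONFIG = SimConfig(seed=0, n_cases=20000, n_pts=200, target_drug_share=0.1)

# Planted recovery signals: PTs chosen so the expected signal cell a is >= 50
# at every rate ratio (base inclusion probabilities ~0.015, 0.007, 0.004).
RECOVERY_SIGNALS = (("PT_0029", 2.0), ("PT_0059", 5.0), ("PT_0099", 10.0))


def run_pipeline(cfg: SimConfig) -> tuple[list[ScreenRow], SyntheticTruth]:
    """generate -> assemble -> cohort -> count -> screen, returning scored rows."""
    bundle, truth = generate(cfg)
    cases = assemble_cases([bundle])
    query = DrugQuery.from_names([cfg.target_drug])
    target, background = select_cohort(cases, query)
    counts = count_events(target, background)
    return screen(counts, level="PT", min_a=1), truth


@dataclass
class NullCalibration:
    n_terms: int
    n_exceed: int

    @property
    def rate(self) -> float:
        return self.n_exceed / self.n_terms if self.n_terms else float("nan")


def null_calibration(
    seed: int,
    n_seeds: int = 5,
    config: SimConfig = NULL_CONFIG,
    min_expected_a: float = 10.0,
) -> NullCalibration:
    """Fraction of null PTs whose ROR lower 95% bound exceeds 1.

    Only PTs whose expected target-event count is at least ``min_expected_a``
    enter the denominator: the Wald interval is an asymptotic construction
    and its nominal 2.5% one-sided exceedance is only meaningful where the
    normal approximation holds.
    """
    n_terms = n_exceed = 0
    for k in range(n_seeds):
        cfg = replace(config, seed=seed + k, planted_signals=())
        rows, truth = run_pipeline(cfg)
        eligible = {
            pt for pt, (ea, _, _, _) in truth.expected_tables.items()
            if ea >= min_expected_a
        }
        for r in rows:
            if r.term in eligible:
                n_terms += 1
                if r.estimate.ror_lo95 > 1.0:
                    n_exceed += 1
    return NullCalibration(n_terms, n_exceed)


def ror_recovery(
    seed: int,
    n_seeds: int = 20,
    config: SimConfig = NULL_CONFIG,
    signals: tuple[tuple[str, float], ...] = RECOVERY_SIGNALS,
) -> dict[float, dict]:
    """Median pipeline ROR per planted rate ratio across replicate bundles."""
    estimates: dict[str, list[float]] = {pt: [] for pt, _ in signals}
    for k in range(n_seeds):
        cfg = replace(config, seed=seed + k, planted_signals=signals)
        rows, truth = run_pipeline(cfg)
        by_term = {r.term: r for r in rows}
        for pt, _rho in signals:
            estimates[pt].append(by_term[pt].estimate.ror)
    out = {}
    for pt, rho in signals:
        med = median(estimates[pt])
        out[rho] = {
            "pt": pt,
            "median_ror": med,
            "relative_error": abs(med - rho) / rho,
            "n_seeds": n_seeds,
        }
    return out


def dedup_recovery(
    seed: int,
    duplicate_rates: tuple[float, ...] = (0.0, 0.1, 0.3),
    n_cases: int = 5000,
) -> dict[float, tuple[int, int]]:
    """(emitted DEMO rows, cases after dedup) per duplicate rate; the second
    element must equal ``n_cases`` for every rate."""
    out = {}
    for i, rate in enumerate(duplicate_rates):
        cfg = SimConfig(seed=seed + i, n_cases=n_cases, n_pts=50,
                        duplicate_rate=rate)
        bundle, _ = generate(cfg)
        cases = assemble_cases([bundle])
        out[rate] = (len(bundle.rows("DEMO")), len(cases))
    return out


def tto_first_bin_fraction(
    seed: int,
    n_cases: int = 1000,
    onset_mixture: tuple[float, float, float] = (0.8, 8.0, 120.0),
) -> dict:
    """First-bin ([0, 30) days) fraction of onset intervals for a cohort whose
    onset times follow the planted early/late mixture."""
    cfg = SimConfig(seed=seed, n_cases=n_cases, n_pts=50,
                    target_drug_share=1.0, partial_date_rate=0.0,
                    duplicate_rate=0.0, onset_mixture=onset_mixture)
    bundle, truth = generate(cfg)
    cases = assemble_cases([bundle])
    query = DrugQuery.from_names([cfg.target_drug])
    target, _ = select_cohort(cases, query)
    summary = summarize_tto(compute_tto(target, query))
    frac = summary.bin_counts[0] / summary.n_included
    return {
        "first_bin_fraction": frac,
        "n_included": summary.n_included,
        "n_excluded": summary.n_excluded,
        "bin_counts": summary.bin_counts,
    }
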
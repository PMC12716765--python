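"""Descriptive outputs: demographic/outcome summary tables and volcano
coordinates for the screened PT signals.

The demographic summary follows the usual pharmacovigilance case-table
layout: per-category counts with percentages of the cohort total, with
``missing`` always its own category so every block sums to the cohort size.
Percentages are rounded half-up to one decimal, matching how such tables are
printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .disproportionality import ScreenRow
from .faers_io import ReportCase

# Outcome severity priority used to pick one outcome per case.
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "CA": "Congenital anomaly",
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization",
    "LT": "Life-threatening",
    "OT": "Other",
    "RI": "Required intervention",
}

DEFAULT_AGE_BANDS = ((0.0, 18.0), (18.0, 65.0), (65.0, 85.0), (85.0, math.inf))
DEFAULT_AGE_LABELS = ("<18", "18-64.9", "65-85", ">85")
DEFAULT_WEIGHT_BANDS = ((0.0, 50.0), (50.0, 100.0), (100.0, math.inf))
DEFAULT_WEIGHT_LABELS = ("<50", "50-100", ">100")


def round_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (printed-table style)."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_block(counts: Mapping[str, int], total: int) -> list[tuple[str, int, float]]:
    """(category, count, percent-of-total) rows for one characteristic."""
    return [(k, v, round_percent(v, total)) for k, v in counts.items()]


def age_band(age: float | None, bands=DEFAULT_AGE_BANDS, labels=DEFAULT_AGE_LABELS) -> str:
    """Band an age in years. Bands are half-open [lo, hi) except that the
    upper edge of the penultimate band is inclusive, so an age of exactly 85
    falls in "65-85" and ">85" is strictly above it."""
    if age is None:
        return "missing"
    for i, ((lo, hi), label) in enumerate(zip(bands, labels)):
        last_finite = i == len(bands) - 2
        if lo <= age < hi or (last_finite and age == hi):
            return label
        if i == len(bands) - 1 and age > bands[i - 1][1]:
            return label
    return labels[-1]


def weight_band(wt: float | None) -> str:
    return age_band(wt, DEFAULT_WEIGHT_BANDS, DEFAULT_WEIGHT_LABELS)


def primary_outcome(outcomes: frozenset[str]) -> str:
    """One outcome per case: the most serious reported, else missing."""
    for code in OUTCOME_PRIORITY:
        if code in outcomes:
            return OUTCOME_LABELS[code]
    return "missing"


@dataclass
class DemographicSummary:
    total_cases: int
    sex: list[tuple[str, int, float]] = field(default_factory=list)
    weight: list[tuple[str, int, float]] = field(default_factory=list)
    age: list[tuple[str, int, float]] = field(default_factory=list)
    occupation: list[tuple[str, int, float]] = field(default_factory=list)
    countries: list[tuple[str, int, float]] = field(default_factory=list)
    outcome: list[tuple[str, int, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block_name, block in (
            ("sex", self.sex), ("weight_kg", self.weight), ("age_years", self.age),
            ("occupation", self.occupation), ("country", self.countries),
            ("outcome", self.outcome),
        ):
            for cat, n, pct in block:
                rows.append({"characteristic": block_name, "category": cat,
                             "count": n, "percent": pct})
        return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def summarize_demographics(
    cases: Sequence[ReportCase],
    top_k_countries: int = 5,
) -> DemographicSummary:
    """Case-table summary of the target cohort (counts and percents)."""
    total = len(cases)
    summary = DemographicSummary(total_cases=total)
    if total == 0:
        return summary

    def count_by(keyfn) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in cases:
            k = keyfn(c)
            out[k] = out.get(k, 0) + 1
        return out

    sex_counts = count_by(lambda c: {"female": "Female", "male": "Male"}.get(c.sex, "missing"))
    wt_counts = count_by(lambda c: weight_band(c.weight_kg))
    age_counts = count_by(lambda c: age_band(c.age_years))
    occ_counts = count_by(lambda c: c.reporter_occupation)
    out_counts = count_by(lambda c: primary_outcome(c.outcomes))

    country_counts = count_by(lambda c: c.country or "missing")
    missing_countries = country_counts.pop("missing", 0)
    ranked = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_k_countries]
    other = sum(n for _, n in ranked[top_k_countries:])
    country_block = dict(top)
    if other:
        country_block["Other"] = other
    if missing_countries:
        country_block["missing"] = missing_countries

    def ordered(counts: dict[str, int], order: Sequence[str]) -> dict[str, int]:
        out = {k: counts[k] for k in order if k in counts}
        for k in sorted(counts):
            out.setdefault(k, counts[k])
        return out

    summary.sex = percent_block(ordered(sex_counts, ("Female", "Male", "missing")), total)
    summary.weight = percent_block(
        ordered(wt_counts, DEFAULT_WEIGHT_LABELS + ("missing",)), total)
    summary.age = percent_block(ordered(age_counts, DEFAULT_AGE_LABELS + ("missing",)), total)
    summary.occupation = percent_block(
        ordered(occ_counts, ("consumer", "health_professional", "lawyer", "physician",
                             "pharmacist", "other_health_professional", "missing")), total)
    summary.countries = percent_block(country_block, total)
    summary.outcome = percent_block(
        ordered(out_counts, tuple(OUTCOME_LABELS[c] for c in
                                  ("CA", "DE", "DS", "HO", "LT", "OT", "RI")) + ("missing",)),
        total)
    return summary


@dataclass(frozen=True)
class VolcanoPoint:
    """One PT on the volcano plot: effect size vs evidence strength."""

    term: str
    x: float  # log2(ROR)
    y: float  # -log10 of the chi-squared (df=1) tail probability
    a: int


def volcano_coordinates(rows: Sequence[ScreenRow]) -> list[VolcanoPoint]:
    """Volcano coordinates for every screened term whose table has all cells
    positive (ROR and the chi-squared tail are defined), ordered by
    descending case count."""
    pts = []
    for r in rows:
        t = r.table
        if t.has_zero_cell or math.isnan(r.estimate.ror):
            continue
        pvalue = float(stats.chi2.sf(r.estimate.chi2, df=1))
        y = -math.log10(pvalue) if pvalue > 0 else math.inf
        pts.append(VolcanoPoint(r.term, math.log2(r.estimate.ror), y, t.a))
    pts.sort(key=lambda p: (-p.a, p.term))
    return pts


def volcano_frame(points: Sequence[VolcanoPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": p.term, "x": p.x, "y": p.y, "a": p.a} for p in points],
        columns=["term", "x", "y", "a"],
    )
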
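"""Time from therapy start to adverse event, binned, with a cumulative curve.

For each target-drug case the onset interval is the number of whole days from
the earliest target-drug therapy start date to the event date. Cases with a
missing start or event date, a negative interval, or (by default) a date of
less-than-day precision are excluded with an explicit reason — exclusions are
reported, never silent. Binning is half-open [lo, hi), so a same-day onset
(0 days) falls in the first bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .cohort import DrugQuery
from .faers_io import ReportCase

DEFAULT_BIN_EDGES = (0, 30, 60, 90, 180, 360, math.inf)

ExclusionReason = Literal["missing_start", "missing_event", "negative", "incomplete_precision"]
PartialDatePolicy = Literal["exclude", "impute_midpoint"]


@dataclass(frozen=True)
class OnsetRecord:
    caseid: int
    tto_days: int | None = None
    exclusion_reason: ExclusionReason | None = None
    imputed: bool = False

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


@dataclass
class OnsetSummary:
    bin_edges: tuple[float, ...]
    bin_counts: list[int]
    n_included: int
    n_excluded: int
    exclusion_breakdown: dict[str, int] = field(default_factory=dict)
    cumulative_curve: list[tuple[int, float]] = field(default_factory=list)

    def bin_labels(self) -> list[str]:
        labels = []
        for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:]):
            labels.append(f"[{int(lo)}, {'inf' if math.isinf(hi) else int(hi)})")
        return labels

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        bins = pd.DataFrame({"bin": self.bin_labels(), "count": self.bin_counts})
        curve = pd.DataFrame(self.cumulative_curve, columns=["day", "cumulative_fraction"])
        return bins, curve


def compute_tto(
    cases: Sequence[ReportCase],
    query: DrugQuery,
    partial_date_policy: PartialDatePolicy = "exclude",
) -> list[OnsetRecord]:
    """One :class:`OnsetRecord` per case, using the earliest start date among
    the case's target-drug rows (restricted to the query's role filter)."""
    records = []
    for case in cases:
        starts = [
            d.start_date
            for d in case.drugs
            if d.name in query.target_names and d.role in query.role_filter
            and d.start_date is not None
        ]
        if not starts:
            records.append(OnsetRecord(case.key.caseid, exclusion_reason="missing_start"))
            continue
        start = min(starts, key=lambda p: p.sort_key())
        event = case.event_date
        if event is None:
            records.append(OnsetRecord(case.key.caseid, exclusion_reason="missing_event"))
            continue
        imputed = False
        if start.precision != "day" or event.precision != "day":
            if partial_date_policy == "exclude":
                records.append(
                    OnsetRecord(case.key.caseid, exclusion_reason="incomplete_precision")
                )
                continue
            imputed = True
        start_d = start.midpoint() if imputed else start.to_date()
        event_d = event.midpoint() if imputed else event.to_date()
        tto = (event_d - start_d).days
        if tto < 0:
            records.append(OnsetRecord(case.key.caseid, exclusion_reason="negative"))
            continue
        records.append(OnsetRecord(case.key.caseid, tto_days=tto, imputed=imputed))
    return records


def summarize_tto(
    records: Sequence[OnsetRecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> OnsetSummary:
    """Half-open binning plus the empirical cumulative incidence curve,
    evaluated at every distinct observed onset time."""
    edges = tuple(float(e) for e in bin_edges)
    if any(hi <= lo for lo, hi in zip(edges[:-1], edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    included = sorted(r.tto_days for r in records if r.included)
    excluded = [r for r in records if not r.included]
    breakdown: dict[str, int] = {}
    for r in excluded:
        breakdown[r.exclusion_reason] = breakdown.get(r.exclusion_reason, 0) + 1

    counts = [0] * (len(edges) - 1)
    for t in included:
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if lo <= t < hi:
                counts[i] += 1
                break
    n = len(included)
    curve: list[tuple[int, float]] = []
    if n:
        # single pass over the sorted values: fraction with tto <= day
        i = 0
        while i < n:
            day = included[i]
            j = i
            while j < n and included[j] == day:
                j += 1
            curve.append((day, j / n))
            i = j
    return OnsetSummary(
        bin_edges=edges,
        bin_counts=counts,
        n_included=n,
        n_excluded=len(excluded),
        exclusion_breakdown=breakdown,
        cumulative_curve=curve,
    )
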
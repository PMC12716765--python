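#!/usr/bin/env python
"""Descriptive outputs: cohort case table and volcano coordinates.

Summarises the synthetic target cohort's demographics (sex, age and weight
bands, reporter occupation, countries, outcomes) the way published
pharmacovigilance case tables are laid out, and emits volcano-plot
coordinates (log2 ROR vs -log10 chi-squared tail probability) for the
screened PTs. Also recomputes the published mirtazapine case-table
percentages from the bundled published counts as an arithmetic check.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from faers_signals.cohort import DrugQuery, count_events, select_cohort
from faers_signals.disproportionality import screen
from faers_signals.faers_io import assemble_cases, read_bundle
from faers_signals.report import (
    round_percent,
    summarize_demographics,
    volcano_coordinates,
    volcano_frame,
)

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synth_bundle"
RESULTS = ROOT / "results"

if not BUNDLE.exists():
    subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")],
                   check=True)

bundle = read_bundle(sorted(BUNDLE.glob("*_synth.txt")))
cases = assemble_cases([bundle])
query = DrugQuery.from_names(["DRUG_TARGET"])
target, background = select_cohort(cases, query)

RESULTS.mkdir(exist_ok=True)
summary = summarize_demographics(target)
summary.to_frame().to_csv(RESULTS / "demographics.tsv", sep="\t", index=False)
print(f"target cohort: {summary.total_cases} cases")
print(summary.to_frame().head(12).to_string(index=False))

rows = screen(count_events(target, background), level="PT")
volcano = volcano_frame(volcano_coordinates(rows))
volcano.to_csv(RESULTS / "volcano.tsv", sep="\t", index=False)
print(f"\nvolcano coordinates for {len(volcano)} PTs "
      f"(top effect: {volcano.loc[volcano.x.idxmax(), 'term']})")

# arithmetic check against the published case table (n = 2,954)
table = pd.read_csv(ROOT / "data" / "mirtazapine_faers_demographics.csv")
total = int(table.loc[table.characteristic == "total", "count"].iloc[0])
rows_pub = table.dropna(subset=["published_percent"]).copy()
rows_pub["recomputed"] = [round_percent(int(n), total) for n in rows_pub["count"]]
rows_pub["match"] = rows_pub["recomputed"] == rows_pub["published_percent"]
rows_pub.to_csv(RESULTS / "published_demographics_check.tsv", sep="\t", index=False)
print(f"\npublished percentages recomputed: {int(rows_pub['match'].sum())}"
      f"/{len(rows_pub)} match exactly")
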
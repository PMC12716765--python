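#!/usr/bin/env python
"""Ingest the synthetic bundle and screen every PT with the four algorithms.

Reads the bundle written by 01_simulate_cohort.py (regenerating it if
absent), deduplicates, selects the primary-suspect cohort, builds the 2x2
table per PT and scores ROR, PRR+chi2, IC and EBGM with the joint
four-algorithm rule. Writes results/pt_screen.tsv and prints the signals.
"""

import subprocess
import sys
from pathlib import Path

from faers_signals.cohort import DrugQuery, count_events, select_cohort
from faers_signals.disproportionality import screen, screen_frame
from faers_signals.faers_io import assemble_cases, read_bundle

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synth_bundle"
RESULTS = ROOT / "results"

if not BUNDLE.exists():
    subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")],
                   check=True)

tables = sorted(BUNDLE.glob("*_synth.txt"))
bundle = read_bundle(tables)
cases = assemble_cases([bundle])
query = DrugQuery.from_names(["DRUG_TARGET"])
target, background = select_cohort(cases, query)
rows = screen(count_events(target, background), level="PT", min_a=1)

RESULTS.mkdir(exist_ok=True)
frame = screen_frame(rows)
frame.to_csv(RESULTS / "pt_screen.tsv", sep="\t", index=False)

signals = frame[frame.all_four]
print(f"{len(cases)} deduplicated cases -> {len(target)} target, "
      f"{len(background)} background")
print(f"{len(frame)} PTs screened, {len(signals)} pass all four algorithms:")
cols = ["term", "a", "ROR", "ROR_lo95", "PRR", "chi2", "IC", "IC025", "EBGM", "EBGM05"]
print(signals[cols].round(2).to_string(index=False))
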
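"""Collate the stage outputs into a single run summary.

Reads the tables produced by scripts 01-05 and writes
results/summary.json with the headline numbers of the run: per-family
linkage maxima, counts of called regions, variant-selection funnel counts,
segregation outcomes, Bonferroni threshold and association results.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"

summary: dict = {}

scan = RES / "linkage" / "scan_summary.json"
if scan.exists():
    summary["linkage_maxima"] = json.loads(scan.read_text())

regions = {}
for f in sorted((RES / "regions").glob("*.tsv")):
    n = max(0, len(f.read_text().splitlines()) - 1)
    if n:
        regions[f.stem] = n
summary["regions_called"] = regions

seg = RES / "variants" / "segregation.tsv"
if seg.exists():
    tab = pd.read_csv(seg, sep="\t")
    summary["segregation"] = {
        "n_tested": int(len(tab)),
        "n_segregating": int((tab.segregating == "Yes").sum()),
    }

cand = RES / "variants" / "candidates.tsv"
if cand.exists():
    summary["n_candidates_retained"] = max(
        0, len(cand.read_text().splitlines()) - 1)

thr = RES / "association" / "thresholds.json"
if thr.exists():
    summary["association_thresholds"] = json.loads(thr.read_text())

assoc = RES / "association" / "association.tsv"
if assoc.exists():
    tab = pd.read_csv(assoc, sep="\t")
    summary["association"] = tab.to_dict(orient="records")

out = RES / "summary.json"
out.write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print(f"\nwrote {out}")
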
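"""Case-control replication of the candidate variants.

Applies the 5-SD component-wise ancestry filter on PCs 1-4 (reference:
the control arm), then Firth-penalized logistic regression of case status
on carrier state per variant under a dominant model with sex + 10 PCs as
covariates - for all cases and for familial cases only - and the bespoke
Bonferroni threshold (0.05 / number of genes with at least one observed
mutated allele).  A per-gene rare-allele burden analysis runs on
synthetic qualifying-allele counts.

Writes results/association/: Table-4-shaped association.tsv, burden.tsv,
thresholds.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pedlink.association import (
    SkippedTest,
    ancestry_filter,
    association_table,
    bonferroni_threshold,
    burden_test,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "association"
OUT.mkdir(parents=True, exist_ok=True)

cohort = pd.read_csv(DATA / "cohort.tsv", sep="\t")
cohort["familial"] = cohort["familial"].astype(bool)
controls = cohort[cohort.status == 0]
pcs = ["PC1", "PC2", "PC3", "PC4"]
filtered = ancestry_filter(cohort, controls[pcs].mean().to_numpy(),
                           controls[pcs].std().to_numpy())
print(f"ancestry filter: {len(cohort)} -> {len(filtered)} retained")

carrier_cols = [c for c in filtered.columns if c.startswith("carrier_")]
tab = association_table(filtered, carrier_cols)
tab.to_csv(OUT / "association.tsv", sep="\t", index=False)
print(tab.to_string(index=False))

counts = {c.removeprefix("carrier_"): (
    int(filtered.loc[filtered.status == 1, c].sum()),
    int(filtered.loc[filtered.status == 0, c].sum()))
    for c in carrier_cols}
n_genes, alpha = bonferroni_threshold(counts)
print(f"\nBonferroni: {n_genes} genes with >=1 mutated allele -> "
      f"alpha = 0.05/{n_genes} = {alpha:.4g}")

# burden: synthetic per-gene qualifying rare-allele counts, one gene with
# 4x enrichment in cases, one null gene
rng = np.random.default_rng(9)
filtered = filtered.copy()
filtered["count_GENE_ENRICHED"] = rng.poisson(
    np.where(filtered.status == 1, 0.20, 0.05))
filtered["count_GENE_NULL"] = rng.poisson(0.05, size=len(filtered))
fits = burden_test(filtered, ["count_GENE_ENRICHED", "count_GENE_NULL"])
rows = []
for col, fit in fits.items():
    gene = col.removeprefix("count_")
    if isinstance(fit, SkippedTest):
        rows.append({"gene": gene, "OR": "-", "P": "-", "note": fit.reason})
    else:
        rows.append({"gene": gene, "OR": round(fit.odds_ratio, 3),
                     "P": round(fit.p_value, 5), "note": ""})
burden_tab = pd.DataFrame(rows)
burden_tab.to_csv(OUT / "burden.tsv", sep="\t", index=False)
print("\nburden:")
print(burden_tab.to_string(index=False))

(OUT / "thresholds.json").write_text(json.dumps(
    {"n_genes_with_carrier": n_genes, "alpha": alpha,
     "n_before_ancestry_filter": len(cohort),
     "n_after_ancestry_filter": len(filtered)}, indent=2))
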
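"""Variant prioritization: selection cascade, segregation, expression.

Builds an annotated rare-variant table over family 1's suggestive linkage
regions (planted so that each selection filter has known positive and
negative examples), runs the four-filter cascade (region membership, MAF
<= 1% in every reporting panel, damaging effect class, all sequenced
affecteds heterozygous), then the extended-family segregation test
(all affected genotyped members heterozygous), and finally the
expression-priority lookup (top-20% of non-zero-median genes) with a
differential-expression flag at FDR < 0.05.

Writes results/variants/: candidate table, Table-3-style segregation
report, expression priority table.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pedlink.npl import read_track_tsv
from pedlink.pedigree import read_ped
from pedlink.simulate import simulate_variant_table
from pedlink.variants import (
    RegionSet,
    de_flag,
    expression_priority,
    segregation_table,
    segregation_test,
    select_candidates,
    write_variant_tsv,
    write_variant_vcf,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
REGIONS = ROOT / "results" / "regions"
OUT = ROOT / "results" / "variants"
OUT.mkdir(parents=True, exist_ok=True)

ped, _, _ = read_ped(DATA / "fam1.ped", DATA / "fam1.map",
                     DATA / "fam1.ages.tsv")
affected = ped.affected()

bed = REGIONS / "fam1_NPL_robdom.suggestive.bed"
linkage_regions = RegionSet.from_bed(bed, build="GRCh38", provenance="linkage")
print(f"fam1 suggestive regions (Srobdom): {len(linkage_regions.regions)}")

variants, truth = simulate_variant_table(
    linkage_regions, ped, sequenced_affected=affected, seed=77)
write_variant_tsv(variants, OUT / "annotated_variants.tsv")
write_variant_vcf(variants, OUT / "annotated_variants.vcf")

kept = select_candidates(variants, linkage_regions, None, affected)
write_variant_tsv(kept, OUT / "candidates.tsv")
kept_labels = sorted(truth[v.key] for v in kept)
print(f"selection cascade: {len(variants)} variants -> {len(kept)} retained "
      f"({', '.join(kept_labels)})")

# extended genotyping (the wider-family confirmation step, here simulated
# directly in the planted genotype tables)
reports = [segregation_test(v, v.genotypes, ped) for v in variants
           if truth[v.key] in ("pass", "pass_not_reported", "fail_het")]
tab = segregation_table(reports)
tab.to_csv(OUT / "segregation.tsv", sep="\t", index=False)
print("segregation:")
print(tab.to_string(index=False))

# expression lookup on a synthetic gene x sample RPKM table: candidate genes
# planted at high and low expression ranks
rng = np.random.default_rng(5)
genes = [f"BG{k}" for k in range(40)] + ["GENE_PASS", "GENE_PASS_NOT_REPORTED"]
expr = pd.DataFrame(rng.lognormal(1.0, 1.5, size=(len(genes), 6)),
                    index=genes, columns=[f"s{j}" for j in range(6)])
expr.loc["GENE_PASS"] = expr.to_numpy().max() * 2      # clearly top-20%
expr.loc["GENE_PASS_NOT_REPORTED"] = 0.0               # not expressed
prio = expression_priority(expr, ["GENE_PASS", "GENE_PASS_NOT_REPORTED"])
de = pd.DataFrame({"fdr": [0.2, 0.9]},
                  index=["GENE_PASS", "GENE_PASS_NOT_REPORTED"])
prio["de_significant"] = [de_flag(de, g) for g in prio.index]
prio.to_csv(OUT / "expression_priority.tsv", sep="\t")
print("\nexpression priority:")
print(prio.to_string())
(OUT / "truth.json").write_text(json.dumps(truth, indent=2))
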
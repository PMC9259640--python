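"""Simulate the study inputs: three ascertained families and a cohort.

Three extended families are generated in the shape of the study design -
family 1 a large single-generation sibship with many affecteds, families 2
and 3 three-generation pedigrees with fewer affecteds - together with a
dense linked SNP panel per family carrying a dominant rare causal variant
(age-dependent penetrance, 3% phenocopy floor), and a case-control cohort
(937 cases / 1046 controls, 160 familial cases) with sex, 10 PCs and
carrier states for six candidate variants at rare frequencies.

Outputs under results/data/: per-family PED/MAP/ages, cohort.tsv,
per-family truth.json (causal position, causal genotypes, seed).
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pedlink.pedigree import write_ped
from pedlink.simulate import (
    CausalSpec,
    CohortSpec,
    CohortVariant,
    MarkerSpec,
    PedigreeSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_family_dataset,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

MARKERS = MarkerSpec(n_chromosomes=4, markers_per_chromosome=40,
                     spacing_cM=2.5, maf_range=(0.3, 0.5))

FAMILIES = {
    "fam1": SimulationConfig(
        seed=14,
        pedigree=PedigreeSpec(generations=2, children_per_couple=(8, 8),
                              founder_age_range=(85, 90),
                              n_affected_target=8),
        markers=MARKERS,
        causal=CausalSpec(chromosome="1", cM=50.0),
    ),
    "fam2": SimulationConfig(
        seed=22,
        pedigree=PedigreeSpec(generations=3, children_per_couple=(4, 4),
                              marry_fraction=1.0, max_marriages=1,
                              founder_age_range=(85, 90),
                              n_affected_target=5),
        markers=MARKERS,
        causal=CausalSpec(chromosome="2", cM=40.0),
    ),
    "fam3": SimulationConfig(
        seed=33,
        pedigree=PedigreeSpec(generations=3, children_per_couple=(3, 3),
                              marry_fraction=1.0, max_marriages=1,
                              founder_age_range=(85, 90),
                              n_affected_target=4),
        markers=MARKERS,
        causal=CausalSpec(chromosome="3", cM=60.0),
    ),
}

COHORT = SimulationConfig(
    seed=44,
    cohort=CohortSpec(
        n_cases=937, n_controls=1046, n_familial=160,
        variants=tuple(
            CohortVariant(name, freq, 1.0)
            for name, freq in [
                ("VAR1", 0.008), ("VAR2", 0.010), ("VAR3", 0.006),
                ("VAR4", 0.007), ("VAR5", 0.009), ("VAR6", 0.0)]
        ),
    ),
)

for name, cfg in FAMILIES.items():
    ds = simulate_family_dataset(cfg, name=name)
    write_ped(ds.pedigree, ds.panel, ds.genotypes,
              OUT / f"{name}.ped", OUT / f"{name}.map",
              OUT / f"{name}.ages.tsv")
    truth = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "causal_chromosome": cfg.causal.chromosome,
        "causal_cM": cfg.causal.cM,
        "causal_genotypes": ds.causal_genotypes,
        "n_members": len(ds.pedigree),
        "n_affected": len(ds.pedigree.affected()),
        "n_markers_post_qc": len(ds.panel),
        "n_drop_attempts": ds.n_drop_attempts,
    }
    (OUT / f"{name}.truth.json").write_text(json.dumps(truth, indent=2))
    print(f"{name}: {truth['n_members']} members, "
          f"{truth['n_affected']} affected, causal at "
          f"chr{cfg.causal.chromosome}:{cfg.causal.cM} cM, "
          f"{truth['n_markers_post_qc']} markers after QC")

cohort = simulate_cohort(COHORT)
cohort.assign(familial=cohort["familial"].astype(int)).to_csv(
    OUT / "cohort.tsv", sep="\t", index=False)
print(f"cohort: {int((cohort.status == 1).sum())} cases, "
      f"{int((cohort.status == 0).sum())} controls, "
      f"{int(cohort.familial.sum())} familial cases")
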
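"""Calibration and parameter-recovery experiments on synthetic data.

These are the study-level simulations the package is validated against:

* **Causal-region recovery** - replicate families are simulated with a
  dominant, high-penetrance causal variant ascertained to 8 affected
  members; a replicate scores as recovered when the statistic's maximum
  inside the causal region (+/- 20 cM around the causal position on its
  chromosome) is at least the maximum over all unlinked chromosomes.  Ties
  count as recovery because within one family the sharing statistic is
  discrete and its ceiling can be attained at an unlinked locus by chance.
* **Null locus rate** - the same families with marker data simulated
  independently of disease; the fraction of loci with NPL >= 3.90 measures
  calibration of the genome-wide-significant threshold.
* **Association calibration** - type-I error of the Firth dominant-model
  carrier test at alpha = 0.05 on null cohorts, and odds-ratio recovery at
  a simulated OR of 5.

Problem sizes (pedigree of 10 with 8 affected, 4 chromosomes x 40 markers
at 2.5 cM) are desk-scale stand-ins for an array-genotyped genome scan;
the experiment structure, not the scale, carries over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import variant_association
from .npl import ScoreTrack
from .pipeline import linkage_scan
from .penetrance import default_models
from .simulate import (
    CausalSpec,
    CohortSpec,
    CohortVariant,
    MarkerSpec,
    PedigreeSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_family_dataset,
)

#: +/- window in cM around the causal position counted as the causal region
#: (single-family linkage resolution is of this order).
CAUSAL_WINDOW_CM = 20.0

RECOVERY_MARKERS = MarkerSpec(
    n_chromosomes=4, markers_per_chromosome=40, spacing_cM=2.5,
    maf_range=(0.3, 0.5),
)

RECOVERY_PEDIGREE = PedigreeSpec(
    generations=2, children_per_couple=(8, 8),
    founder_age_range=(85.0, 90.0), n_affected_target=8,
)

RECOVERY_CAUSAL = CausalSpec(model="dominant-high", chromosome="1", cM=50.0)


def recovery_config(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed, pedigree=RECOVERY_PEDIGREE,
                            markers=RECOVERY_MARKERS, causal=RECOVERY_CAUSAL)


def peak_recovered(track: ScoreTrack, causal_chromosome: str,
                   causal_cM: float, window: float = CAUSAL_WINDOW_CM) -> bool:
    """Max inside the causal region >= max over the unlinked chromosomes."""
    inside = [v for c, cm, v in zip(track.chromosomes, track.cM, track.values)
              if c == causal_chromosome and abs(cm - causal_cM) <= window]
    off = [v for c, v in zip(track.chromosomes, track.values)
           if c != causal_chromosome]
    if not inside:
        return False
    return max(inside) >= max(off)


@dataclass
class RecoveryResult:
    n_replicates: int
    hit_rate: dict[str, float]  # statistic -> fraction recovered
    n_phenocopy_replicates: int


def run_recovery(n_replicates: int = 100, base_seed: int = 0) -> RecoveryResult:
    """Fraction of replicates whose linkage peak recovers the causal region."""
    stats = ("NPL_robdom", "NPL_pairs", "LOD_dominant-high")
    hits = {s: 0 for s in stats}
    n_pheno = 0
    models = {"dominant-high": default_models()["dominant-high"]}
    for r in range(n_replicates):
        cfg = recovery_config(base_seed + r)
        ds = simulate_family_dataset(cfg)
        if any(ds.causal_genotypes[i] == 0 for i in ds.pedigree.affected()):
            n_pheno += 1
        tracks = linkage_scan(ds.pedigree, ds.genotypes, ds.panel,
                              models=models)
        for s in stats:
            hits[s] += peak_recovered(tracks[s], cfg.causal.chromosome,
                                      cfg.causal.cM)
    return RecoveryResult(
        n_replicates=n_replicates,
        hit_rate={s: h / n_replicates for s, h in hits.items()},
        n_phenocopy_replicates=n_pheno,
    )


@dataclass
class NullRateResult:
    n_replicates: int
    n_loci: int
    rate: dict[str, float]  # statistic -> fraction of loci with NPL >= thr


def run_null_rate(n_replicates: int = 100, base_seed: int = 0,
                  threshold: float = 3.90) -> NullRateResult:
    """Fraction of unlinked loci reaching the significant NPL threshold."""
    stats = ("NPL_pairs", "NPL_robdom")
    counts = {s: 0 for s in stats}
    n_loci = 0
    for r in range(n_replicates):
        cfg = recovery_config(base_seed + r)
        ds = simulate_family_dataset(cfg, linked=False)
        tracks = linkage_scan(ds.pedigree, ds.genotypes, ds.panel, models={})
        n_loci += len(tracks["NPL_pairs"])
        for s in stats:
            counts[s] += int((tracks[s].values >= threshold).sum())
    return NullRateResult(
        n_replicates=n_replicates, n_loci=n_loci,
        rate={s: c / n_loci for s, c in counts.items()},
    )


def _calibration_cohort(seed: int, odds_ratio: float,
                        carrier_freq: float = 0.05,
                        n_cases: int = 1000, n_controls: int = 1000):
    cfg = SimulationConfig(seed=seed, cohort=CohortSpec(
        n_cases=n_cases, n_controls=n_controls, n_familial=160,
        variants=(CohortVariant("v", carrier_freq, odds_ratio),)))
    return simulate_cohort(cfg)


def run_type_one_error(n_replicates: int = 500, base_seed: int = 0,
                       alpha: float = 0.05) -> tuple[float, int]:
    """Rejection rate of the Firth carrier test on null cohorts."""
    n_rej = 0
    for r in range(n_replicates):
        coh = _calibration_cohort(base_seed + r, odds_ratio=1.0)
        fit = variant_association(coh, "carrier_v", compute_ci=False)
        n_rej += fit.p_value < alpha
    return n_rej / n_replicates, n_replicates


def run_or_recovery(n_replicates: int = 100, base_seed: int = 0,
                    odds_ratio: float = 5.0) -> tuple[float, int]:
    """Mean estimated odds ratio at a simulated carrier OR."""
    ors = []
    for r in range(n_replicates):
        coh = _calibration_cohort(base_seed + r, odds_ratio=odds_ratio)
        fit = variant_association(coh, "carrier_v", compute_ci=False)
        ors.append(fit.odds_ratio)
    return float(np.mean(ors)), n_replicates
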
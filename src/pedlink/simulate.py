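"""Synthetic pedigree, marker, variant and cohort generators.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes: extended pedigrees ascertained for many
affected members, a dominant rare causal variant with age-dependent
penetrance dropped through the family, linked SNP panels whose founder
haplotypes recombine by the Haldane map (so markers flanking the causal
locus cosegregate with disease), annotated rare-variant tables constructed
so that a known subset passes each selection filter, and a case-control
cohort with covariates and configurable carrier frequencies.

All generators are deterministic under a fixed seed; output writers embed
the seed and a config hash in a header line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .inheritance import PedigreeIndex, descent_labels, haldane_theta
from .penetrance import (
    LiabilityClassTable,
    PenetranceModel,
    build_liability_classes,
    default_models,
)
from .pedigree import (
    Genotype,
    Individual,
    Marker,
    MarkerGenotypes,
    MarkerPanel,
    Pedigree,
)
from .variants import AnnotatedVariant, RegionSet


@dataclass(frozen=True)
class PedigreeSpec:
    """Family structure: ascertained, heavily affected extended sibships.

    Founders are the oldest generation (ages 70-90 by default) and each
    later generation is 25-30 years younger, which makes the age-dependent
    penetrance consequential.  ``n_affected_target`` triggers rejection
    sampling of the causal gene drop until at least that many members are
    affected (the families emulated here were ascertained for exactly this).
    """

    generations: int = 2
    children_per_couple: tuple[int, int] = (8, 8)  # inclusive range
    marry_fraction: float = 0.5  # generation-2+ children who marry in a spouse
    max_marriages: int | None = None  # cap on married-in couples (bit budget)
    founder_age_range: tuple[float, float] = (85.0, 90.0)
    generation_age_gap: tuple[float, float] = (25.0, 30.0)
    n_affected_target: int | None = 8
    max_retries: int = 20_000


@dataclass(frozen=True)
class MarkerSpec:
    n_chromosomes: int = 22
    markers_per_chromosome: int = 200
    spacing_cM: float = 1.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.01
    bp_per_cM: int = 1_000_000
    build: str = "GRCh38"


@dataclass(frozen=True)
class CausalSpec:
    model: str = "dominant-high"
    chromosome: str = "1"
    cM: float = 50.0
    force_founder_carrier: bool = True


@dataclass(frozen=True)
class CohortVariant:
    name: str
    control_carrier_freq: float
    odds_ratio: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 937
    n_controls: int = 1046
    n_familial: int = 160
    female_fraction_cases: float = 0.708
    female_fraction_controls: float = 0.5
    n_pcs: int = 10
    minority_fraction: float = 0.0  # shifted ancestry cluster, for filter tests
    minority_shift: float = 8.0
    variants: tuple[CohortVariant, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    markers: MarkerSpec = field(default_factory=MarkerSpec)
    causal: CausalSpec = field(default_factory=CausalSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=raw.get("seed", 0),
            pedigree=_from_dict(PedigreeSpec, raw.get("pedigree", {})),
            markers=_from_dict(MarkerSpec, raw.get("markers", {})),
            causal=_from_dict(CausalSpec, raw.get("causal", {})),
            cohort=_from_dict(CohortSpec, raw.get("cohort", {})),
        )

    @property
    def penetrance_model(self) -> PenetranceModel:
        return default_models()[self.causal.model]


def _from_dict(cls, data: dict):
    if cls is CohortSpec and "variants" in data:
        data = dict(data)
        data["variants"] = tuple(
            CohortVariant(**v) if isinstance(v, dict) else CohortVariant(*v)
            for v in data["variants"]
        )
    fields = {f for f in cls.__dataclass_fields__}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Pedigree simulation


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator | None = None,
    name: str = "simfam",
) -> Pedigree:
    """Generate a loop-free pedigree with per-generation ages.

    Generation 1 is a founder couple; their children either remain leaves
    or (for 3+ generations) marry a founder spouse and have children of
    their own.  Reproducible under the config seed.
    """
    spec = config.pedigree
    rng = rng or np.random.default_rng(config.seed)
    inds: dict[str, Individual] = {}

    def age_for(gen: int, parent_age: float | None) -> float:
        if parent_age is None:
            return float(np.round(rng.uniform(*spec.founder_age_range)))
        return float(np.round(parent_age - rng.uniform(*spec.generation_age_gap)))

    father = Individual("g0_f", sex="male", age=age_for(0, None))
    mother = Individual("g0_m", sex="female", age=age_for(0, None))
    inds[father.id] = father
    inds[mother.id] = mother
    frontier = [(father, mother, 1)]
    counter = 0
    n_married = 0
    while frontier:
        fa, mo, gen = frontier.pop(0)
        n_kids = int(rng.integers(spec.children_per_couple[0],
                                  spec.children_per_couple[1] + 1))
        for _ in range(n_kids):
            counter += 1
            sex = "male" if rng.random() < 0.5 else "female"
            child = Individual(
                f"g{gen}_c{counter}", father=fa.id, mother=mo.id, sex=sex,
                age=max(0.0, age_for(gen, min(fa.age, mo.age))),
            )
            inds[child.id] = child
            if gen < spec.generations - 1 and rng.random() < spec.marry_fraction \
                    and (spec.max_marriages is None
                         or n_married < spec.max_marriages):
                n_married += 1
                counter += 1
                sp_sex = "female" if sex == "male" else "male"
                spouse = Individual(
                    f"g{gen}_s{counter}", sex=sp_sex,
                    age=max(0.0, float(np.round(
                        child.age + rng.uniform(-3, 3)))),
                )
                inds[spouse.id] = spouse
                couple = ((child, spouse) if sex == "male" else (spouse, child))
                frontier.append((couple[0], couple[1], gen + 1))
    return Pedigree(inds, name=name)


# ---------------------------------------------------------------------------
# Gene drop


def _draw_founder_risk_labels(
    idx: PedigreeIndex, q: float, force_carrier: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    risk = (rng.random(idx.n_labels) < q).astype(np.int64)
    if force_carrier and risk.sum() == 0:
        # condition on at least one copy entering through a top founder
        top = idx.founder_labels(idx.founders[0])
        risk[top[int(rng.integers(0, 2))]] = 1
    return risk


def gene_drop(
    ped: Pedigree,
    model: PenetranceModel,
    seed: int | np.random.Generator = 0,
    force_founder_carrier: bool = True,
    table: LiabilityClassTable | None = None,
) -> tuple[dict[str, int], dict[str, str], tuple[int, ...]]:
    """Drop a causal allele through the pedigree and sample affection.

    Founder founder-allele labels carry the risk allele independently with
    probability ``model.trait_allele_freq`` (HWE); Mendelian transmission is
    a uniform inheritance vector; each individual is affected with the
    liability-class penetrance for their age and genotype.  Returns
    (genotypes as risk-allele counts, affection statuses, inheritance
    vector at the causal locus).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tab = table or build_liability_classes(model)
    idx = PedigreeIndex(ped)
    risk = _draw_founder_risk_labels(idx, model.trait_allele_freq,
                                     force_founder_carrier, rng)
    vector = tuple(int(b) for b in rng.integers(0, 2, size=idx.n_bits))
    labels = descent_labels(ped, vector, idx)
    genos = {i: int(risk[l[0]] + risk[l[1]]) for i, l in labels.items()}
    affection = {}
    for i, g in genos.items():
        f = tab.penetrance(ped[i].age, g)
        affection[i] = "affected" if rng.random() < f else "unaffected"
    return genos, affection, vector


# ---------------------------------------------------------------------------
# Marker simulation


def make_marker_panel(spec: MarkerSpec, rng: np.random.Generator) -> MarkerPanel:
    markers = []
    for c in range(1, spec.n_chromosomes + 1):
        for k in range(spec.markers_per_chromosome):
            cm = k * spec.spacing_cM
            maf = float(rng.uniform(*spec.maf_range))
            markers.append(Marker(
                id=f"rs{c}_{k}",
                chromosome=str(c),
                bp=int((cm + spec.spacing_cM) * spec.bp_per_cM),
                cM=cm,
                allele_frequencies={"1": round(1.0 - maf, 6),
                                    "2": round(maf, 6)},
            ))
    return MarkerPanel(markers, build=spec.build)


def _meiosis_paths(
    n_meioses: int,
    thetas: Sequence[float],
    rng: np.random.Generator,
    anchor: tuple[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-meiosis transmitted-haplotype bit at each marker of a chromosome.

    Without an anchor the path starts uniform and evolves as a Markov chain
    with per-interval flip probability theta.  With ``anchor=(k, bits)`` the
    path is conditioned to equal ``bits`` at marker index k and simulated
    outward in both directions (valid because the chain is reversible).
    """
    n_mark = len(thetas) + 1
    bits = np.empty((n_meioses, n_mark), dtype=np.int8)
    if anchor is None:
        start = 0
        bits[:, 0] = rng.integers(0, 2, size=n_meioses)
    else:
        start, vals = anchor
        bits[:, start] = vals
    for k in range(start + 1, n_mark):
        flip = rng.random(n_meioses) < thetas[k - 1]
        bits[:, k] = bits[:, k - 1] ^ flip
    for k in range(start - 1, -1, -1):
        flip = rng.random(n_meioses) < thetas[k]
        bits[:, k] = bits[:, k + 1] ^ flip
    return bits


def simulate_markers(
    ped: Pedigree,
    panel: MarkerPanel,
    rng: np.random.Generator,
    causal_vector: Sequence[int] | None = None,
    causal_chromosome: str | None = None,
    causal_cM: float | None = None,
    paths_out: dict | None = None,
) -> MarkerGenotypes:
    """Drop founder haplotypes through the pedigree along each chromosome.

    Founder haplotypes are drawn from the panel allele frequencies;
    recombination between adjacent markers follows the Haldane map.  When a
    causal inheritance vector is given, the meiosis paths on the causal
    chromosome are conditioned through it at the causal map position, so
    flanking markers cosegregate with the causal allele.  Genotyping error
    (allele replaced by a random panel draw) and missingness are applied
    last; error/missing rates ride along in the MarkerSpec used to build
    the panel, applied by :func:`apply_genotyping_noise`.
    """
    idx = PedigreeIndex(ped)
    n_mei = idx.n_bits
    table: dict[str, list[Genotype]] = {i: [None] * len(panel)
                                        for i in ped.individuals}
    for chrom in panel.chromosomes:
        loci = panel.chromosome_indices(chrom)
        cms = [panel[l].cM for l in loci]
        thetas = [haldane_theta(b - a) for a, b in zip(cms[:-1], cms[1:])]
        anchor = None
        if causal_vector is not None and chrom == causal_chromosome:
            k = int(np.argmin(np.abs(np.asarray(cms) - causal_cM)))
            anchor = (k, np.asarray(causal_vector, dtype=np.int8))
        paths = _meiosis_paths(n_mei, thetas, rng, anchor=anchor)
        if paths_out is not None:
            paths_out[chrom] = (np.asarray(cms), paths.copy())
        # founder haplotypes: label -> allele per locus
        hap = {}
        for f in idx.founders:
            for lab in idx.founder_labels(f):
                hap[lab] = [
                    _draw_allele(panel[l], rng) for l in loci
                ]
        for pos, l in enumerate(loci):
            labels: dict[str, tuple[int, int]] = {}
            for f in idx.founders:
                labels[f] = idx.founder_labels(f)
            for n in idx.nonfounders:
                ind = ped[n]
                bp_, bm_ = idx.bit_pair(n)
                labels[n] = (
                    labels[ind.father][paths[bp_, pos]],
                    labels[ind.mother][paths[bm_, pos]],
                )
            for i, (a, b) in labels.items():
                table[i][l] = tuple(sorted((hap[a][pos], hap[b][pos])))
    return MarkerGenotypes(table)


def _draw_allele(marker: Marker, rng: np.random.Generator) -> str:
    alleles = list(marker.allele_frequencies)
    freqs = np.array([marker.allele_frequencies[a] for a in alleles])
    return alleles[int(rng.choice(len(alleles), p=freqs / freqs.sum()))]


def apply_genotyping_noise(
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    rng: np.random.Generator,
    error_rate: float,
    missing_rate: float,
) -> MarkerGenotypes:
    """Replace alleles with random panel draws at ``error_rate`` and set
    genotypes missing at ``missing_rate`` (applied per genotype call)."""
    out: dict[str, list[Genotype]] = {}
    for i, row in genotypes.table.items():
        new_row: list[Genotype] = []
        for l, g in enumerate(row):
            if g is None or rng.random() < missing_rate:
                new_row.append(None)
                continue
            a, b = g
            if rng.random() < error_rate:
                a = _draw_allele(panel[l], rng)
            if rng.random() < error_rate:
                b = _draw_allele(panel[l], rng)
            new_row.append(tuple(sorted((a, b))))
        out[i] = new_row
    return MarkerGenotypes(out)


def qc_markers(
    ped: Pedigree, panel: MarkerPanel, genotypes: MarkerGenotypes,
    min_call_rate: float = 0.95,
) -> tuple[MarkerPanel, MarkerGenotypes]:
    """Standard post-generation SNP QC: drop markers with call rate below
    ``min_call_rate`` or with any Mendelian inconsistency in a trio."""
    keep = []
    ids = list(ped.individuals)
    for l in range(len(panel)):
        calls = [genotypes.get(i, l) for i in ids]
        rate = sum(g is not None for g in calls) / len(ids)
        if rate < min_call_rate:
            continue
        if _mendel_error(ped, genotypes, l):
            continue
        keep.append(l)
    new_panel = MarkerPanel([panel[l] for l in keep], build=panel.build)
    return new_panel, genotypes.subset(keep)


def _mendel_error(ped: Pedigree, genotypes: MarkerGenotypes, l: int) -> bool:
    for i in ped.individuals.values():
        if i.father is None:
            continue
        g = genotypes.get(i.id, l)
        gf = genotypes.get(i.father, l)
        gm = genotypes.get(i.mother, l)
        if g is None:
            continue
        if not _child_consistent(g, gf, gm):
            return True
    return False


def _child_consistent(g: Genotype, gf: Genotype, gm: Genotype) -> bool:
    pa_opts = gf if gf is not None else None
    ma_opts = gm if gm is not None else None
    for k in (0, 1):
        a, b = g[k], g[1 - k]
        if (pa_opts is None or a in pa_opts) and (ma_opts is None or b in ma_opts):
            return True
    return False


# ---------------------------------------------------------------------------
# Family dataset orchestrator


@dataclass
class FamilyDataset:
    config: SimulationConfig
    pedigree: Pedigree  # with affection statuses assigned
    panel: MarkerPanel
    genotypes: MarkerGenotypes
    causal_genotypes: dict[str, int]
    causal_vector: tuple[int, ...]
    n_drop_attempts: int
    #: chrom -> (marker cM positions, meiosis-bit paths), pre-QC truth
    meiosis_paths: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def true_ibd_segment(self) -> tuple[float, float]:
        """Ground-truth causal region in cM on the causal chromosome.

        The maximal contiguous marker interval around the causal locus over
        which no meiosis of any affected member has recombined away from
        the causal inheritance vector - i.e. where the IBD sharing among
        affecteds is exactly what it is at the causal locus.  The linkage
        peak is expected anywhere inside this segment: within a single
        family the statistic is constant over it.
        """
        chrom = self.config.causal.chromosome
        cms, paths = self.meiosis_paths[chrom]
        idx = PedigreeIndex(self.pedigree)
        bits = []
        for i in self.pedigree.affected():
            if not self.pedigree[i].is_founder:
                bits.extend(idx.bit_pair(i))
        anchor = int(np.argmin(np.abs(cms - self.config.causal.cM)))
        ref = paths[bits, anchor]
        ok = (paths[bits, :] == ref[:, None]).all(axis=0)
        lo = hi = anchor
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < len(cms) - 1 and ok[hi + 1]:
            hi += 1
        return float(cms[lo]), float(cms[hi])


def simulate_family_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    name: str = "simfam",
    linked: bool = True,
    apply_qc: bool = True,
) -> FamilyDataset:
    """Full family simulation: pedigree, ascertained gene drop, linked panel.

    With ``linked=False`` the causal inheritance vector is not embedded in
    the marker data (the unlinked null: affection pattern identical in law,
    markers independent of disease).  ``apply_qc`` runs the standard
    post-generation SNP filters (call rate, Mendelian-error marker drop).
    """
    rng = rng or np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng, name=name)
    model = config.penetrance_model
    tab = build_liability_classes(model)
    target = config.pedigree.n_affected_target
    attempts = 0
    while True:
        attempts += 1
        genos, affection, vector = gene_drop(
            ped, model, rng,
            force_founder_carrier=config.causal.force_founder_carrier,
            table=tab)
        n_aff = sum(1 for a in affection.values() if a == "affected")
        if target is None or n_aff >= target:
            break
        if attempts >= config.pedigree.max_retries:
            raise RuntimeError(
                f"n_affected target {target} not reached in "
                f"{config.pedigree.max_retries} gene drops "
                f"(last drop: {n_aff} affected)")
    ped = ped.with_affection(affection)
    panel = make_marker_panel(config.markers, rng)
    paths_out: dict = {}
    marker_genos = simulate_markers(
        ped, panel, rng,
        causal_vector=vector if linked else None,
        causal_chromosome=config.causal.chromosome,
        causal_cM=config.causal.cM,
        paths_out=paths_out,
    )
    marker_genos = apply_genotyping_noise(
        marker_genos, panel, rng,
        config.markers.genotyping_error_rate, config.markers.missing_rate)
    if apply_qc:
        panel, marker_genos = qc_markers(ped, panel, marker_genos)
    return FamilyDataset(
        config=config, pedigree=ped, panel=panel, genotypes=marker_genos,
        causal_genotypes=genos, causal_vector=vector,
        n_drop_attempts=attempts, meiosis_paths=paths_out,
    )


# ---------------------------------------------------------------------------
# Variant table fixture


def simulate_variant_table(
    regions: RegionSet,
    ped: Pedigree,
    sequenced_affected: Sequence[str],
    seed: int = 0,
    build: str = "GRCh38",
) -> tuple[list[AnnotatedVariant], dict[str, str]]:
    """Plant annotated variants with controlled fates in the selection cascade.

    Returns (variants, truth) where truth maps variant key to the expected
    outcome: "pass" (retained and segregating), "fail_maf", "fail_effect",
    "fail_region", "fail_het" (8-of-9-style near-miss), "pass_not_reported"
    (absent from every panel, retained).
    """
    rng = np.random.default_rng(seed)
    chrom, start, end = regions.regions[0]
    inside = lambda: int(rng.integers(start, end + 1))
    aff = list(sequenced_affected)
    unaff = [i.id for i in ped.individuals.values()
             if i.affection == "unaffected"]
    # unaffected members may carry the allele (reduced penetrance): ~40% het
    unaff_gts = {i: ("het" if rng.random() < 0.4 else "hom_ref")
                 for i in unaff}
    all_het = {i: "het" for i in aff} | unaff_gts
    near_miss = dict(all_het)
    near_miss[aff[-1]] = "hom_ref"
    low = lambda: round(float(rng.uniform(0.0005, 0.009)), 6)
    plan = [
        ("pass", chrom, inside(), "missense",
         {"exac_nfe": low(), "mine": low(), "gonl": low()}, all_het),
        ("pass_not_reported", chrom, inside(), "frameshift", {}, all_het),
        ("fail_maf", chrom, inside(), "missense",
         {"exac_nfe": 0.02, "mine": low(), "gonl": low()}, all_het),
        ("fail_effect", chrom, inside(), "synonymous",
         {"exac_nfe": low()}, all_het),
        ("fail_region", "99", 10_000, "missense",
         {"exac_nfe": low()}, all_het),
        ("fail_het", chrom, inside(), "missense",
         {"exac_nfe": low()}, near_miss),
    ]
    variants = []
    truth = {}
    for label, c, pos, eff, mafs, gts in plan:
        v = AnnotatedVariant(
            chromosome=c, pos=pos, ref="A", alt="G", build=build,
            gene=f"GENE_{label.upper()}", effect_class=eff,
            panel_mafs=mafs, genotypes=gts,
        )
        variants.append(v)
        truth[v.key] = label
    return variants, truth


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None,
):
    """Case-control cohort with sex, PCs and carrier states.

    Carrier frequency among controls is as configured; among cases it is
    raised to the frequency implied by the configured odds ratio.  An
    optional minority ancestry cluster (shifted PCs) exercises the 5-SD
    ancestry filter.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(config.seed)
    spec = config.cohort
    n = spec.n_cases + spec.n_controls
    status = np.concatenate([np.ones(spec.n_cases, dtype=int),
                             np.zeros(spec.n_controls, dtype=int)])
    familial = np.zeros(n, dtype=bool)
    fam_idx = rng.choice(spec.n_cases, size=min(spec.n_familial, spec.n_cases),
                         replace=False)
    familial[fam_idx] = True
    female = np.where(
        status == 1,
        rng.random(n) < spec.female_fraction_cases,
        rng.random(n) < spec.female_fraction_controls,
    )
    pcs = rng.standard_normal((n, spec.n_pcs))
    if spec.minority_fraction > 0:
        minority = rng.random(n) < spec.minority_fraction
        pcs[minority, :2] += spec.minority_shift
    else:
        minority = np.zeros(n, dtype=bool)
    df = pd.DataFrame({
        "id": [f"s{k}" for k in range(n)],
        "status": status,
        "familial": familial,
        "sex": female.astype(int),
        "minority": minority,
    })
    for k in range(spec.n_pcs):
        df[f"PC{k + 1}"] = pcs[:, k]
    for var in spec.variants:
        f0 = var.control_carrier_freq
        odds1 = var.odds_ratio * f0 / (1.0 - f0)
        f1 = odds1 / (1.0 + odds1)
        freq = np.where(status == 1, f1, f0)
        df[f"carrier_{var.name}"] = (rng.random(n) < freq).astype(int)
    return df
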
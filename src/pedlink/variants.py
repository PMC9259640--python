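"""Rare damaging-variant selection, segregation testing and expression lookup.

The selection cascade retains a variant when all of the following hold:

a. it lies inside a suggestive linkage region of the discovery family, or
   inside a previously reported locus;
b. its minor-allele frequency is <= 1% in every reference panel where it is
   reported (absence from all panels also passes);
c. its predicted effect class is in the frozen damaging vocabulary
   (12 classes, from transcript ablation down to missense);
d. every sequenced affected member of the discovery family is heterozygous
   for it.

Segregation in the extended family (after wider genotyping) holds iff every
affected genotyped member is heterozygous; counts are reported in the
"het/genotyped" form.  Expression priority flags candidate genes whose
median expression is in the top 20% of genes with non-zero median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pedigree import Pedigree

MAF_THRESHOLD = 0.01

#: Frozen vocabulary of damaging effect classes.
DAMAGING_EFFECT_CLASSES = frozenset({
    "exon_loss",
    "frameshift",
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "transcript_ablation",
    "rare_amino_acid",
    "inframe_deletion",
    "inframe_insertion",
    "missense",
})

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt", "missing")


class BuildMismatchError(ValueError):
    """Positions on different genome builds may not be combined."""


@dataclass(frozen=True)
class AnnotatedVariant:
    chromosome: str
    pos: int  # 1-based
    ref: str
    alt: str
    build: str
    gene: str
    effect_class: str
    panel_mafs: Mapping[str, float] = field(default_factory=dict)
    genotypes: Mapping[str, str] = field(default_factory=dict)  # id -> state

    def __post_init__(self) -> None:
        for p, maf in self.panel_mafs.items():
            if not (0.0 <= maf <= 0.5):
                raise ValueError(f"{self.key}: MAF {maf} in {p} outside [0, 0.5]")
        for i, g in self.genotypes.items():
            if g not in GENOTYPE_STATES:
                raise ValueError(f"{self.key}: bad genotype state {g!r} for {i}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class RegionSet:
    regions: list[tuple[str, int, int]]  # (chrom, start_bp, end_bp), 1-based incl.
    build: str
    provenance: str = "linkage"  # "linkage" | "prior_loci"

    def __post_init__(self) -> None:
        for c, s, e in self.regions:
            if s > e:
                raise ValueError(f"region {c}:{s}-{e} has start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.regions)

    @classmethod
    def from_bed(cls, path: str | Path, build: str,
                 provenance: str = "prior_loci") -> "RegionSet":
        regions = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            c, s, e = line.split("\t")[:3]
            regions.append((c, int(s) + 1, int(e)))  # BED is 0-based half-open
        return cls(regions, build=build, provenance=provenance)


# ---------------------------------------------------------------------------
# Candidate selection cascade (pure predicates; order-independent)


def in_candidate_regions(v: AnnotatedVariant, linkage: RegionSet | None,
                         prior: RegionSet | None) -> bool:
    for rs in (linkage, prior):
        if rs is None:
            continue
        if rs.build != v.build:
            raise BuildMismatchError(
                f"variant on {v.build} vs regions on {rs.build}")
        if rs.contains(v.chromosome, v.pos):
            return True
    return False


def rare_in_all_panels(v: AnnotatedVariant) -> bool:
    """MAF <= 1% in every panel where reported; absence from all also passes."""
    return all(maf <= MAF_THRESHOLD for maf in v.panel_mafs.values())


def damaging_effect(v: AnnotatedVariant) -> bool:
    if v.effect_class not in DAMAGING_EFFECT_CLASSES and \
            v.effect_class not in _WARNED:
        warnings.warn(f"unknown effect class {v.effect_class!r}; excluded")
        _WARNED.add(v.effect_class)
    return v.effect_class in DAMAGING_EFFECT_CLASSES


_WARNED: set[str] = set()


def all_affecteds_het(v: AnnotatedVariant, sequenced_affected: Iterable[str]) -> bool:
    """All sequenced affecteds heterozygous (strictly: hom-alt or missing fails)."""
    ids = list(sequenced_affected)
    return bool(ids) and all(v.genotypes.get(i, "missing") == "het" for i in ids)


def select_candidates(
    variants: Iterable[AnnotatedVariant],
    linkage_regions: RegionSet | None,
    prior_loci: RegionSet | None,
    sequenced_affected: Sequence[str],
) -> list[AnnotatedVariant]:
    """Apply the four-filter selection cascade; filters are pure and commute."""
    return [
        v for v in variants
        if in_candidate_regions(v, linkage_regions, prior_loci)
        and rare_in_all_panels(v)
        and damaging_effect(v)
        and all_affecteds_het(v, sequenced_affected)
    ]


# ---------------------------------------------------------------------------
# Segregation in the extended family


@dataclass(frozen=True)
class SegregationReport:
    variant_key: str
    segregating: bool
    het_cases: str  # "a/b": het affecteds / genotyped affecteds
    het_controls: str

    @property
    def n_het_cases(self) -> tuple[int, int]:
        a, b = self.het_cases.split("/")
        return int(a), int(b)


def segregation_test(
    variant: AnnotatedVariant,
    extended_genotypes: Mapping[str, str],
    ped: Pedigree,
) -> SegregationReport:
    """Segregation = every affected genotyped family member is heterozygous.

    ``extended_genotypes`` is the post-validation genotype table covering
    members beyond the initially sequenced set (the wet-lab confirmation
    step, consumed here as data).  Unaffected members never block
    segregation (reduced penetrance), but their carrier counts are reported.
    """
    def counts(ids: list[str]) -> tuple[int, int]:
        typed = [i for i in ids if extended_genotypes.get(i, "missing") != "missing"]
        het = [i for i in typed if extended_genotypes[i] == "het"]
        return len(het), len(typed)

    aff = [i.id for i in ped.individuals.values() if i.affection == "affected"]
    unaff = [i.id for i in ped.individuals.values() if i.affection == "unaffected"]
    het_a, n_a = counts(aff)
    het_u, n_u = counts(unaff)
    if n_a == 0:
        raise ValueError(f"{variant.key}: no affected member genotyped")
    return SegregationReport(
        variant_key=variant.key,
        segregating=het_a == n_a,
        het_cases=f"{het_a}/{n_a}",
        het_controls=f"{het_u}/{n_u}",
    )


def segregation_table(reports: Iterable[SegregationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant_key,
                "segregating": "Yes" if r.segregating else "No",
                "het_cases": r.het_cases,
                "het_controls": r.het_controls,
            }
            for r in reports
        ]
    )


# ---------------------------------------------------------------------------
# Expression-based prioritization


def expression_priority(
    expression: pd.DataFrame, candidate_genes: Sequence[str]
) -> pd.DataFrame:
    """Median expression and top-20% flag per candidate gene.

    ``expression`` is gene x sample (RPKM or similar).  A gene is flagged
    when its median over all samples is non-zero and at or above the 80th
    percentile of the non-zero-median gene set (inclusive at the boundary).
    """
    if expression.empty or expression.shape[1] == 0:
        raise ValueError("empty expression table")
    medians = expression.median(axis=1)
    nonzero = medians[medians > 0]
    cutoff = nonzero.quantile(0.8) if len(nonzero) else float("inf")
    rows = []
    for g in candidate_genes:
        med = float(medians.get(g, float("nan")))
        rows.append({
            "gene": g,
            "median": med,
            "top20": bool(med > 0 and med >= cutoff),
        })
    return pd.DataFrame(rows).set_index("gene")


def de_flag(de_table: pd.DataFrame, gene: str,
            fdr_column: str = "fdr") -> bool | None:
    """True iff the gene's FDR < 0.05 (strict); None when not evaluated."""
    if gene not in de_table.index:
        return None
    return bool(de_table.loc[gene, fdr_column] < 0.05)


# ---------------------------------------------------------------------------
# I/O: variants as VCF + annotation sidecar, or plain TSV


def read_variant_tsv(path: str | Path, build: str) -> list[AnnotatedVariant]:
    """Read a variant annotation TSV.

    Columns: chrom, pos, ref, alt, gene, effect_class, then ``maf_<panel>``
    columns (empty = not reported) and ``gt_<individual>`` genotype columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    gt_cols = [c for c in df.columns if c.startswith("gt_")]
    out = []
    for _, row in df.iterrows():
        mafs = {
            c[4:]: float(row[c]) for c in maf_cols if pd.notna(row[c])
        }
        gts = {c[3:]: str(row[c]) for c in gt_cols if pd.notna(row[c])}
        out.append(AnnotatedVariant(
            chromosome=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]), build=build,
            gene=str(row["gene"]), effect_class=str(row["effect_class"]),
            panel_mafs=mafs, genotypes=gts,
        ))
    return out


def write_variant_tsv(variants: Sequence[AnnotatedVariant],
                      path: str | Path) -> None:
    panels = sorted({p for v in variants for p in v.panel_mafs})
    inds = sorted({i for v in variants for i in v.genotypes})
    with open(path, "w") as fh:
        head = ["chrom", "pos", "ref", "alt", "gene", "effect_class"]
        head += [f"maf_{p}" for p in panels] + [f"gt_{i}" for i in inds]
        fh.write("\t".join(head) + "\n")
        for v in variants:
            row = [v.chromosome, str(v.pos), v.ref, v.alt, v.gene,
                   v.effect_class]
            row += ["" if p not in v.panel_mafs else f"{v.panel_mafs[p]:g}"
                    for p in panels]
            row += [v.genotypes.get(i, "") for i in inds]
            fh.write("\t".join(row) + "\n")


_GT_OUT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
           "missing": "./."}


def write_variant_vcf(variants: Sequence[AnnotatedVariant],
                      path: str | Path) -> None:
    """Write variants as a VCF with an ANN-style annotation INFO field.

    ANN carries ``gene|effect_class``; panel MAFs go to ``MAF_<panel>``
    INFO keys; genotypes become sample columns (0/1 coding).
    """
    variants = list(variants)
    samples = sorted({i for v in variants for i in v.genotypes})
    panels = sorted({p for v in variants for p in v.panel_mafs})
    chroms = []
    for v in variants:
        if v.chromosome not in chroms:
            chroms.append(v.chromosome)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,'
                 'Description="gene|effect_class">\n')
        for p in panels:
            fh.write(f'##INFO=<ID=MAF_{p},Number=1,Type=Float,'
                     f'Description="MAF in panel {p}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + samples
        fh.write("\t".join(cols) + "\n")
        for v in sorted(variants, key=lambda x: (chroms.index(x.chromosome),
                                                 x.pos)):
            info = [f"ANN={v.gene}|{v.effect_class}"]
            info += [f"MAF_{p}={v.panel_mafs[p]:g}" for p in panels
                     if p in v.panel_mafs]
            row = [v.chromosome, str(v.pos), ".", v.ref, v.alt, ".",
                   "PASS", ";".join(info), "GT"]
            row += [_GT_OUT[v.genotypes.get(s, "missing")] for s in samples]
            fh.write("\t".join(row) + "\n")


def _record_genotypes(rec, samples) -> dict[str, str]:
    gts = {}
    for s in samples:
        alleles = rec.samples[s].get("GT", (None, None))
        if alleles is None or None in alleles:
            gts[s] = "missing"
        else:
            gts[s] = GENOTYPE_STATES[sum(1 for a in alleles if a == 1)]
    return gts


def read_annotated_vcf(
    vcf_path: str | Path,
    annotation_tsv: str | Path | None = None,
    build: str = "GRCh38",
) -> list[AnnotatedVariant]:
    """Read annotated variants from a VCF.

    Annotations come either from an ANN-style INFO field
    (``gene|effect_class`` plus ``MAF_<panel>`` keys, as written by
    :func:`write_variant_vcf`) or from a sidecar TSV keyed on
    ``chrom:pos:ref:alt`` with ``gene``, ``effect_class`` and ``maf_<panel>``
    columns.  The VCF supplies positions and per-sample genotypes.
    """
    import pysam

    ann = None
    if annotation_tsv is not None:
        ann = pd.read_csv(annotation_tsv, sep="\t", dtype={"key": str})
        ann = ann.set_index("key")
        maf_cols = [c for c in ann.columns if c.startswith("maf_")]
    out = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                if ann is not None:
                    key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                    if key not in ann.index:
                        continue
                    row = ann.loc[key]
                    gene, effect = str(row["gene"]), str(row["effect_class"])
                    mafs = {c[4:]: float(row[c]) for c in maf_cols
                            if pd.notna(row[c])}
                else:
                    raw = rec.info.get("ANN")
                    if raw is None:
                        continue
                    first = raw[0] if isinstance(raw, tuple) else raw
                    gene, effect = str(first).split("|")[:2]
                    mafs = {k[4:]: float(v) for k, v in rec.info.items()
                            if k.startswith("MAF_")}
                out.append(AnnotatedVariant(
                    chromosome=rec.chrom, pos=rec.pos, ref=rec.ref,
                    alt=alt, build=build, gene=gene, effect_class=effect,
                    panel_mafs=mafs,
                    genotypes=_record_genotypes(rec, samples),
                ))
    return out
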
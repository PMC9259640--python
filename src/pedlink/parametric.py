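"""Parametric liability-class LOD scores.

The trait model is a biallelic risk locus with population frequency q and
age-decade penetrance classes (see :mod:`pedlink.penetrance`).  Three
quantities are computed:

* the baseline (unlinked) trait likelihood, by sum-product peeling over the
  family tree - P(affection statuses) marginalized over all trait-genotype
  configurations with founders in Hardy-Weinberg proportions;
* the trait likelihood conditional on an inheritance vector, by summing over
  assignments of the risk allele to the 2F founder-allele labels;
* the multipoint LOD track, LOD(x) = log10 of the posterior-averaged
  conditional likelihood at x over the baseline.  Averaging the conditional
  likelihood under the *prior* vector distribution recovers the baseline
  exactly (law of total probability), which is the module's core
  conservation property.

Individuals with unknown affection status or missing age contribute a
phenotype likelihood factor of 1 (no trait evidence).  Pedigrees with loops
(including couples where both members are pedigree nonfounders) are out of
scope and rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .inheritance import (
    DEFAULT_BIT_CAP,
    ExactEngine,
    PedigreeIndex,
    _label_arrays,
    descent_labels,
)
from .npl import ScoreTrack
from .penetrance import LiabilityClassTable, PenetranceModel, build_liability_classes
from .pedigree import MarkerGenotypes, MarkerPanel, Pedigree


class LoopedPedigreeError(ValueError):
    """Raised for pedigrees the tree-peeling algorithm cannot handle."""


@dataclass
class TraitModelContext:
    """A penetrance model bound to one pedigree's ages and affections."""

    model: PenetranceModel
    table: LiabilityClassTable
    ped: Pedigree

    @classmethod
    def from_model(cls, model: PenetranceModel, ped: Pedigree) -> "TraitModelContext":
        return cls(model=model, table=build_liability_classes(model), ped=ped)

    def phenotype_factor(self, ind_id: str, n_risk_alleles: int) -> float:
        """P(observed affection | genotype); 1.0 when status or age unknown."""
        ind = self.ped[ind_id]
        if ind.affection == "unknown" or ind.age is None:
            return 1.0
        f = self.table.penetrance(ind.age, n_risk_alleles)
        return f if ind.affection == "affected" else 1.0 - f

    def phenotype_factors(self, ind_id: str) -> np.ndarray:
        return np.array([self.phenotype_factor(ind_id, g) for g in range(3)])


def _hwe_prior(q: float) -> np.ndarray:
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def _transmission() -> np.ndarray:
    """t[gc, gf, gm] = P(child genotype | parent genotypes), allele counts 0..2."""
    t = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf = gf / 2.0  # P(transmit risk allele)
            pm = gm / 2.0
            t[0, gf, gm] = (1 - pf) * (1 - pm)
            t[1, gf, gm] = pf * (1 - pm) + (1 - pf) * pm
            t[2, gf, gm] = pf * pm
    return t


_TRANS = _transmission()


def trait_likelihood_unlinked(ped: Pedigree, ctx: TraitModelContext) -> float:
    """P(affection statuses) under the trait model, by pedigree peeling.

    Sum-product over the family tree; equals brute-force enumeration over
    all 3^n genotype vectors on small pedigrees.  Requires an outbred,
    loop-free pedigree in which every couple includes a married-in founder.
    """
    prior = _hwe_prior(ctx.model.trait_allele_freq)
    couples: dict[tuple[str, str], list[str]] = {}
    for ind in ped.individuals.values():
        if ind.father is not None:
            couples.setdefault((ind.father, ind.mother), []).append(ind.id)
    for fa, mo in couples:
        if not (ped[fa].is_founder or ped[mo].is_founder):
            raise LoopedPedigreeError(
                f"couple ({fa}, {mo}): neither member is a founder; looped or "
                "multi-line pedigrees are out of scope")
    couples_of: dict[str, list[tuple[str, list[str]]]] = {}
    for (fa, mo), kids in couples.items():
        couples_of.setdefault(fa, []).append((mo, kids))
        couples_of.setdefault(mo, []).append((fa, kids))

    visited: set[str] = set()

    def down(i: str, skip_spouse: str | None) -> np.ndarray:
        """Phenotype likelihood of i and everything below i, given g_i."""
        if i in visited:
            raise LoopedPedigreeError(f"individual {i} reached twice (loop)")
        visited.add(i)
        v = ctx.phenotype_factors(i)
        for spouse, kids in couples_of.get(i, []):
            if spouse == skip_spouse:
                continue
            if not ped[spouse].is_founder:
                raise LoopedPedigreeError(
                    f"spouse {spouse} of {i} is not a founder")
            sp = prior * down(spouse, skip_spouse=i)
            fam = np.zeros(3)
            for gi in range(3):
                for gs in range(3):
                    if sp[gs] == 0.0:
                        continue
                    contrib = sp[gs]
                    for c in kids:
                        trans = (_TRANS[:, gi, gs] if ped[c].father == i
                                 else _TRANS[:, gs, gi])
                        contrib *= float(trans @ down_cache(c))
                    fam[gi] += contrib
            v = v * fam
        return v

    # memoized child subtrees (each child visited once; cache keeps the
    # double loop over parental genotypes cheap)
    _cache: dict[str, np.ndarray] = {}

    def down_cache(c: str) -> np.ndarray:
        if c not in _cache:
            _cache[c] = down(c, skip_spouse=None)
        return _cache[c]

    total = 1.0
    order = ped.topological_order()
    for i in order:
        if i in visited or not ped[i].is_founder:
            continue
        # founders married to a nonfounder are reached through that spouse's
        # own subtree; rooting there would traverse upward
        if any(not ped[s].is_founder for s, _ in couples_of.get(i, [])):
            continue
        total *= float(prior @ down(i, skip_spouse=None))
    if len(visited) != len(ped):
        missing = set(ped.individuals) - visited
        raise LoopedPedigreeError(f"individuals not reachable by peeling: {missing}")
    return total


def trait_likelihood_brute_force(ped: Pedigree, ctx: TraitModelContext) -> float:
    """Enumeration oracle over all 3^n genotype vectors (tiny pedigrees only)."""
    ids = list(ped.individuals)
    if len(ids) > 10:
        raise ValueError("brute force limited to 10 individuals")
    prior = _hwe_prior(ctx.model.trait_allele_freq)
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(ids)):
        g = dict(zip(ids, combo))
        p = 1.0
        for i in ids:
            ind = ped[i]
            if ind.is_founder:
                p *= prior[g[i]]
            else:
                p *= _TRANS[g[i], g[ind.father], g[ind.mother]]
            p *= ctx.phenotype_factor(i, g[i])
            if p == 0.0:
                break
        total += p
    return total


def trait_likelihood_given_vector(
    ped: Pedigree, ctx: TraitModelContext, vector: Sequence[int]
) -> float:
    """P(affections | inheritance vector): sum over risk-allele assignments
    to the 2F founder labels, each label carrying the risk allele
    independently with probability q (founder HWE)."""
    idx = PedigreeIndex(ped)
    labels = descent_labels(ped, vector, idx)
    q = ctx.model.trait_allele_freq
    L = idx.n_labels
    total = 0.0
    for assign in itertools.product((0, 1), repeat=L):
        w = 1.0
        for a in assign:
            w *= q if a else (1.0 - q)
        if w == 0.0:
            continue
        for i in ped.individuals:
            pl, ml = labels[i]
            w *= ctx.phenotype_factor(i, assign[pl] + assign[ml])
            if w == 0.0:
                break
        total += w
    return total


def trait_likelihood_by_state(
    ped: Pedigree, ctx: TraitModelContext, bit_cap: int = DEFAULT_BIT_CAP
) -> np.ndarray:
    """Vectorized conditional trait likelihood for every vector state."""
    idx = PedigreeIndex(ped)
    if idx.n_bits > bit_cap:
        raise ValueError("pedigree exceeds exact cap")
    labels = _label_arrays(idx)
    q = ctx.model.trait_allele_freq
    L = idx.n_labels
    pen = {i: ctx.phenotype_factors(i) for i in ped.individuals}
    informative = [i for i in ped.individuals
                   if not np.allclose(pen[i], 1.0)]
    out = np.zeros(idx.n_states)
    for assign in itertools.product((0, 1), repeat=L):
        w = 1.0
        for a in assign:
            w *= q if a else (1.0 - q)
        if w == 0.0:
            continue
        risk = np.array(assign, dtype=np.int64)
        acc = np.full(idx.n_states, w)
        for i in informative:
            pl, ml = labels[i]
            gcount = risk[pl] + risk[ml]
            acc *= pen[i][gcount]
        out += acc
    return out


def parametric_lod_track(
    ped: Pedigree,
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    ctx: TraitModelContext,
    engine: ExactEngine | None = None,
    bit_cap: int = DEFAULT_BIT_CAP,
) -> ScoreTrack:
    """Multipoint parametric LOD at every marker position.

    LOD(x) = log10( E_{v ~ posterior(x)}[P(affections | v)] / P(affections) ).
    """
    base = trait_likelihood_unlinked(ped, ctx)
    if base <= 0.0:
        raise ValueError("baseline trait likelihood is zero")
    tl = trait_likelihood_by_state(ped, ctx, bit_cap=bit_cap)
    eng = engine or ExactEngine(ped, genotypes, panel, bit_cap=bit_cap)
    loci, exp = eng.expectation_track({"tl": tl})
    lod = np.log10(exp["tl"] / base)
    return ScoreTrack(
        chromosomes=[panel[l].chromosome for l in loci],
        bp=np.array([panel[l].bp for l in loci]),
        cM=np.array([panel[l].cM for l in loci]),
        values=lod,
        kind="LOD_parametric",
        pedigree=ped.name,
        meta={"model": ctx.model.name, "baseline_log10": math.log10(base)},
    )


def all_model_lod_tracks(
    ped: Pedigree,
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    models: Mapping[str, PenetranceModel],
    engine: ExactEngine | None = None,
    bit_cap: int = DEFAULT_BIT_CAP,
) -> dict[str, ScoreTrack]:
    """LOD tracks for every preset trait model (reported per model)."""
    eng = engine or ExactEngine(ped, genotypes, panel, bit_cap=bit_cap)
    return {
        name: parametric_lod_track(
            ped, genotypes, panel,
            TraitModelContext.from_model(model, ped), engine=eng,
            bit_cap=bit_cap)
        for name, model in models.items()
    }
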
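"""Inheritance vectors and their posterior given marker data.

An inheritance vector assigns one bit per meiosis (paternal and maternal bit
per nonfounder; 0 = grandpaternal allele transmitted).  The vector determines
which founder allele every individual carries (:func:`descent_labels`), and
therefore the probability of the observed marker genotypes
(:func:`single_marker_likelihood`).  Across a chromosome the vectors form a
hidden Markov chain whose per-bit flip probability between adjacent markers
is the Haldane recombination fraction theta = (1 - exp(-2 d / 100)) / 2 for
inter-marker distance d in cM.

Two posterior computations are provided:

* :func:`exact_posterior` / :class:`ExactEngine` - full forward-backward over
  the 2^B vector states (B = number of meiosis bits), feasible up to a
  configurable cap (default 16 bits).
* :func:`sample_posterior` - single-bit Metropolis-Hastings over the whole
  multilocus configuration, for pedigrees beyond the exact cap; its contract
  is agreement in distribution with the exact chain.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .pedigree import Genotype, Marker, MarkerGenotypes, MarkerPanel, Pedigree

DEFAULT_BIT_CAP = 16
_ASSIGNMENT_CAP = 1 << 16


class EngineError(RuntimeError):
    pass


class BitCapExceeded(EngineError):
    """Pedigree has too many meioses for exact enumeration; use the sampler."""


def haldane_theta(d_cM: float) -> float:
    """Recombination fraction for distance d cM under the Haldane map."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


# ---------------------------------------------------------------------------
# Pedigree indexing


class PedigreeIndex:
    """Fixed orderings: founders -> label pairs, nonfounders -> bit pairs.

    Founder i (in topological order) owns founder-allele labels (2i, 2i+1);
    nonfounder j owns bits (2j, 2j+1) = (paternal meiosis, maternal meiosis).
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        order = ped.topological_order()
        self.founders = [i for i in order if ped[i].is_founder]
        self.nonfounders = [i for i in order if not ped[i].is_founder]
        self.founder_index = {f: i for i, f in enumerate(self.founders)}
        self.nonfounder_index = {n: j for j, n in enumerate(self.nonfounders)}
        self.n_bits = 2 * len(self.nonfounders)
        self.n_labels = 2 * len(self.founders)
        self.n_states = 1 << self.n_bits

    def bit_pair(self, nonfounder_id: str) -> tuple[int, int]:
        j = self.nonfounder_index[nonfounder_id]
        return (2 * j, 2 * j + 1)

    def founder_labels(self, founder_id: str) -> tuple[int, int]:
        i = self.founder_index[founder_id]
        return (2 * i, 2 * i + 1)


InheritanceVector = tuple[int, ...]  # one bit per meiosis, len == n_bits


def vector_to_state(bits: Sequence[int]) -> int:
    s = 0
    for b, v in enumerate(bits):
        s |= (int(v) & 1) << b
    return s


def state_to_vector(state: int, n_bits: int) -> InheritanceVector:
    return tuple((state >> b) & 1 for b in range(n_bits))


def descent_labels(
    ped: Pedigree, vector: Sequence[int], index: PedigreeIndex | None = None
) -> dict[str, tuple[int, int]]:
    """Founder-allele labels carried by each individual under a vector.

    Bit 0 on a meiosis transmits the parent's *paternal* (grandpaternal)
    label.  Deterministic topological traversal.
    """
    idx = index or PedigreeIndex(ped)
    if len(vector) != idx.n_bits:
        raise EngineError(
            f"vector length {len(vector)} != {idx.n_bits} meiosis bits")
    labels: dict[str, tuple[int, int]] = {}
    for f in idx.founders:
        labels[f] = idx.founder_labels(f)
    for n in idx.nonfounders:
        ind = ped[n]
        bp, bm = idx.bit_pair(n)
        pat = labels[ind.father][vector[bp]]
        mat = labels[ind.mother][vector[bm]]
        labels[n] = (pat, mat)
    return labels


def _label_arrays(idx: PedigreeIndex) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(paternal, maternal) label of each individual for every vector state."""
    if idx.n_bits > DEFAULT_BIT_CAP + 4:
        raise BitCapExceeded(f"{idx.n_bits} bits exceeds vectorization limit")
    S = idx.n_states
    states = np.arange(S, dtype=np.int64)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in idx.founders:
        a, b = idx.founder_labels(f)
        out[f] = (np.full(S, a, dtype=np.int16), np.full(S, b, dtype=np.int16))
    for n in idx.nonfounders:
        ind = idx.ped[n]
        bp, bm = idx.bit_pair(n)
        bit_p = (states >> bp) & 1
        bit_m = (states >> bm) & 1
        fl = out[ind.father]
        ml = out[ind.mother]
        out[n] = (
            np.where(bit_p == 0, fl[0], fl[1]).astype(np.int16),
            np.where(bit_m == 0, ml[0], ml[1]).astype(np.int16),
        )
    return out


# ---------------------------------------------------------------------------
# Single-marker likelihood (scalar)


def single_marker_likelihood(
    ped: Pedigree,
    vector: Sequence[int],
    genotypes: Mapping[str, Genotype],
    allele_frequencies: Mapping[str, float],
    index: PedigreeIndex | None = None,
) -> float:
    """P(observed genotypes | inheritance vector) at one marker.

    Sums over assignments of population alleles to the 2F founder labels:
    each assignment contributes the product of its allele frequencies if it
    reproduces every observed genotype, else 0.  Missing genotypes impose no
    constraint; with all genotypes missing the likelihood is 1.
    """
    idx = index or PedigreeIndex(ped)
    labels = descent_labels(ped, vector, idx)
    typed = [(i, g) for i, g in genotypes.items() if g is not None and i in ped]
    if not typed:
        return 1.0
    alleles = list(allele_frequencies)
    freqs = [allele_frequencies[a] for a in alleles]
    # only labels actually observed in a typed individual constrain the sum;
    # unconstrained labels marginalize to 1
    used = sorted({l for i, _ in typed for l in labels[i]})
    if len(alleles) ** len(used) > _ASSIGNMENT_CAP:
        raise EngineError("too many founder-allele assignments to enumerate")
    pos = {l: k for k, l in enumerate(used)}
    total = 0.0
    for assign in itertools.product(range(len(alleles)), repeat=len(used)):
        ok = True
        for i, g in typed:
            pl, ml = labels[i]
            pair = tuple(sorted((alleles[assign[pos[pl]]], alleles[assign[pos[ml]]])))
            if pair != g:
                ok = False
                break
        if ok:
            w = 1.0
            for k in assign:
                w *= freqs[k]
            total += w
    return total


# ---------------------------------------------------------------------------
# Distributions


@dataclass
class InheritanceDistribution:
    """Posterior over inheritance vectors at one locus.

    Either an exact table (``probs`` over all 2^B states) or a weighted
    sample list (``samples``/``weights``).  State integers encode the vector
    bits little-endian (bit b of the integer = meiosis bit b).
    """

    n_bits: int
    position: tuple[str, int]  # (chromosome, locus index within panel)
    probs: np.ndarray | None = None
    samples: np.ndarray | None = None
    weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probs is not None:
            s = float(self.probs.sum())
            if abs(s - 1.0) > 1e-9:
                raise EngineError(f"posterior sums to {s}")
        elif self.samples is not None:
            if self.weights is None:
                self.weights = np.full(len(self.samples),
                                       1.0 / len(self.samples))
            if abs(float(self.weights.sum()) - 1.0) > 1e-9:
                raise EngineError("sample weights must sum to 1")
        else:
            raise EngineError("need probs or samples")

    @property
    def is_exact(self) -> bool:
        return self.probs is not None

    def state_probabilities(self) -> np.ndarray:
        """Dense length-2^B probability vector (aggregates samples if needed)."""
        if self.probs is not None:
            return self.probs
        dense = np.zeros(1 << self.n_bits)
        np.add.at(dense, self.samples, self.weights)
        return dense

    def expectation(self, score_by_state: np.ndarray) -> float:
        if self.probs is not None:
            return float(self.probs @ score_by_state)
        return float(self.weights @ score_by_state[self.samples])

    def tv_distance(self, other: "InheritanceDistribution") -> float:
        a = self.state_probabilities()
        b = other.state_probabilities()
        return 0.5 * float(np.abs(a - b).sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("vector\tweight\n")
            p = self.state_probabilities()
            for s in np.nonzero(p)[0]:
                bits = "".join(str(b) for b in state_to_vector(int(s), self.n_bits))
                fh.write(f"{bits}\t{p[s]:.10g}\n")


# ---------------------------------------------------------------------------
# Exact engine


class ExactEngine:
    """Forward-backward over inheritance-vector states along each chromosome.

    Emissions are vectorized over all states by enumerating founder-allele
    assignments once per marker; a separable fast path covers two-generation
    pedigrees (every nonfounder has two founder parents), where the emission
    factorizes over nonfounders as a Kronecker product.
    """

    def __init__(
        self,
        ped: Pedigree,
        genotypes: MarkerGenotypes,
        panel: MarkerPanel,
        bit_cap: int = DEFAULT_BIT_CAP,
    ):
        self.ped = ped
        self.genotypes = genotypes
        self.panel = panel
        self.idx = PedigreeIndex(ped)
        if self.idx.n_bits > bit_cap:
            raise BitCapExceeded(
                f"{self.idx.n_bits} meiosis bits exceed the exact cap "
                f"({bit_cap}); use sample_posterior")
        self.S = self.idx.n_states
        self.labels = _label_arrays(self.idx)
        self._flip = [
            np.arange(self.S, dtype=np.int64) ^ (1 << b)
            for b in range(self.idx.n_bits)
        ]
        self._separable = all(
            self.ped[self.ped[n].father].is_founder
            and self.ped[self.ped[n].mother].is_founder
            for n in self.idx.nonfounders
        )
        self._pair_code = {
            i: (self.labels[i][0].astype(np.int64) * self.idx.n_labels
                + self.labels[i][1].astype(np.int64))
            for i in ped.individuals
        }
        self._emissions: dict[int, np.ndarray] = {}
        #: markers whose data were Mendelian-inconsistent under *every*
        #: vector (upstream QC misses, e.g. genotyping error in a sibship);
        #: treated as uninformative and recorded here
        self.skipped_markers: list[int] = []

    # -- emissions ---------------------------------------------------------

    def emission(self, locus: int) -> np.ndarray:
        """P(genotypes at marker ``locus`` | state), for every state."""
        if locus not in self._emissions:
            self._emissions[locus] = self._compute_emission(locus)
        return self._emissions[locus]

    def _typed(self, locus: int) -> list[tuple[str, Genotype]]:
        return [
            (i, self.genotypes.get(i, locus))
            for i in self.ped.individuals
            if self.genotypes.get(i, locus) is not None
        ]

    def _compute_emission(self, locus: int) -> np.ndarray:
        marker = self.panel[locus]
        typed = self._typed(locus)
        if not typed:
            return np.ones(self.S)
        alleles = list(marker.alleles)
        nA = len(alleles)
        L = self.idx.n_labels
        if nA ** L > _ASSIGNMENT_CAP:
            raise EngineError(
                f"marker {marker.id}: {nA}^{L} founder-allele assignments "
                "exceed the enumeration cap")
        freqs = np.array([marker.allele_frequencies[a] for a in alleles])
        if self._separable:
            return self._emission_separable(typed, alleles, freqs)
        return self._emission_generic(typed, alleles, freqs)

    def _emission_generic(self, typed, alleles, freqs) -> np.ndarray:
        L = self.idx.n_labels
        nA = len(alleles)
        em = np.zeros(self.S)
        for assign in itertools.product(range(nA), repeat=L):
            w = float(np.prod(freqs[list(assign)]))
            acc: np.ndarray | None = None
            consistent = True
            for i, g in typed:
                table = np.zeros(L * L, dtype=bool)
                for p in range(L):
                    for m in range(L):
                        pair = tuple(sorted((alleles[assign[p]], alleles[assign[m]])))
                        table[p * L + m] = pair == g
                if not table.any():
                    consistent = False
                    break
                ok = table[self._pair_code[i]]
                acc = ok if acc is None else (acc & ok)
            if consistent and acc is not None:
                em += w * acc
        return em

    def _emission_separable(self, typed, alleles, freqs) -> np.ndarray:
        """Kronecker-product emission for two-generation pedigrees."""
        L = self.idx.n_labels
        nA = len(alleles)
        typed_f = [(i, g) for i, g in typed if self.ped[i].is_founder]
        typed_n = [(i, g) for i, g in typed if not self.ped[i].is_founder]
        geno_by_nf = {i: g for i, g in typed_n}
        em = np.zeros(self.S)
        for assign in itertools.product(range(nA), repeat=L):
            w = float(np.prod(freqs[list(assign)]))
            ok = True
            for i, g in typed_f:
                a, b = self.idx.founder_labels(i)
                if tuple(sorted((alleles[assign[a]], alleles[assign[b]]))) != g:
                    ok = False
                    break
            if not ok:
                continue
            arr = np.ones(1)
            for n in self.idx.nonfounders:
                g = geno_by_nf.get(n)
                if g is None:
                    f = np.ones(4)
                else:
                    ind = self.ped[n]
                    fl = self.idx.founder_labels(ind.father)
                    ml = self.idx.founder_labels(ind.mother)
                    f = np.empty(4)
                    for mb in range(2):
                        for pb in range(2):
                            pair = tuple(sorted((
                                alleles[assign[fl[pb]]], alleles[assign[ml[mb]]])))
                            f[mb * 2 + pb] = 1.0 if pair == g else 0.0
                    if not f.any():
                        ok = False
                        break
                arr = np.kron(f, arr)  # earlier nonfounders vary fastest
            if ok:
                em += w * arr
        return em

    # -- chain -------------------------------------------------------------

    def _mix(self, v: np.ndarray, theta: float) -> np.ndarray:
        """One inter-marker transition: each bit flips independently w.p. theta."""
        for flip in self._flip:
            v = (1.0 - theta) * v + theta * v[flip]
        return v

    def _thetas(self, loci: Sequence[int]) -> list[float]:
        return [
            haldane_theta(self.panel[b].cM - self.panel[a].cM)
            for a, b in zip(loci[:-1], loci[1:])
        ]

    def chromosome_posterior(self, chrom: str) -> tuple[list[int], np.ndarray]:
        """Posterior state distribution at every locus of a chromosome.

        Returns (locus indices, array of shape (n_loci, n_states)).
        """
        loci = self.panel.chromosome_indices(chrom)
        thetas = self._thetas(loci)
        n = len(loci)
        fwd = np.empty((n, self.S))
        v = self._safe_emission(loci[0]).copy()
        fwd[0] = v / v.sum()
        for k in range(1, n):
            v = self._mix(fwd[k - 1], thetas[k - 1]) * self._safe_emission(loci[k])
            fwd[k] = v / v.sum()
        post = np.empty_like(fwd)
        bwd = np.ones(self.S)
        post[n - 1] = fwd[n - 1]
        for k in range(n - 2, -1, -1):
            bwd = self._mix(bwd * self._safe_emission(loci[k + 1]), thetas[k])
            bwd /= bwd.sum()
            p = fwd[k] * bwd
            post[k] = p / p.sum()
        return loci, post

    def _safe_emission(self, locus: int) -> np.ndarray:
        em = self.emission(locus)
        if em.sum() == 0.0:
            if locus not in self.skipped_markers:
                self.skipped_markers.append(locus)
            return np.ones(self.S)
        return em

    def posterior(self, locus_index: int) -> InheritanceDistribution:
        chrom = self.panel[locus_index].chromosome
        loci, post = self.chromosome_posterior(chrom)
        k = loci.index(locus_index)
        return InheritanceDistribution(
            n_bits=self.idx.n_bits,
            position=(chrom, locus_index),
            probs=post[k],
            meta={"method": "exact"},
        )

    def expectation_track(
        self, scores: Mapping[str, np.ndarray]
    ) -> tuple[list[int], dict[str, np.ndarray]]:
        """Posterior expectation of state-indexed scores at every locus."""
        all_loci: list[int] = []
        out: dict[str, list[float]] = {k: [] for k in scores}
        for chrom in self.panel.chromosomes:
            loci, post = self.chromosome_posterior(chrom)
            all_loci.extend(loci)
            for name, arr in scores.items():
                out[name].extend(post @ arr)
        return all_loci, {k: np.asarray(v) for k, v in out.items()}


def exact_posterior(
    ped: Pedigree,
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    locus_index: int,
    bit_cap: int = DEFAULT_BIT_CAP,
) -> InheritanceDistribution:
    """Multipoint posterior over inheritance vectors at one locus (exact HMM)."""
    return ExactEngine(ped, genotypes, panel, bit_cap=bit_cap).posterior(locus_index)


# ---------------------------------------------------------------------------
# MCMC sampler


@dataclass(frozen=True)
class MCMCSchedule:
    """Total iterations, burn-in discarded, and thinning interval."""

    total: int = 90_000
    burn_in: int = 5_000
    thin: int = 30


def sample_posterior(
    ped: Pedigree,
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    locus_index: int,
    schedule: MCMCSchedule = MCMCSchedule(),
    seed: int = 0,
    max_start_attempts: int = 10_000,
    block_proposal_fraction: float = 0.2,
) -> InheritanceDistribution:
    """Single-bit Metropolis-Hastings over the multilocus vector chain.

    The target is the joint posterior of the inheritance vectors at every
    marker of the locus's chromosome; one iteration proposes flipping one
    uniformly chosen meiosis bit at one uniformly chosen marker and accepts
    by the posterior ratio.  Because single-bit moves cannot cross
    configurations that are Mendelian-inconsistent at a marker, a fraction
    of iterations (``block_proposal_fraction``) instead redraws the whole
    vector at one marker uniformly - a symmetric proposal that keeps the
    chain irreducible over the full consistent set.  A further fraction of
    iterations applies a founder-phase flip (swapping one founder's two
    allele labels by flipping its children's corresponding meiosis bits at
    every marker simultaneously) - the marker likelihood and the transition
    kernel are exactly invariant under this relabeling, so the move is
    always accepted and lets the chain hop between the otherwise
    near-unreachable phase-symmetric modes of the posterior.  The returned
    distribution is the empirical marginal at ``locus_index`` after burn-in
    and thinning.
    """
    rng = np.random.default_rng(seed)
    idx = PedigreeIndex(ped)
    chrom = panel[locus_index].chromosome
    loci = panel.chromosome_indices(chrom)
    pos = loci.index(locus_index)
    n_bits = idx.n_bits
    thetas = [
        haldane_theta(panel[b].cM - panel[a].cM)
        for a, b in zip(loci[:-1], loci[1:])
    ]
    log_theta = [(math.log(t) if t > 0 else -math.inf,
                  math.log(1 - t)) for t in thetas]

    geno_at = [
        {i: genotypes.get(i, l) for i in ped.individuals} for l in loci
    ]
    freqs_at = [panel[l].allele_frequencies for l in loci]
    lik_cache: list[dict[int, float]] = [dict() for _ in loci]

    def lik(k: int, state: int) -> float:
        cache = lik_cache[k]
        if state not in cache:
            cache[state] = single_marker_likelihood(
                ped, state_to_vector(state, n_bits), geno_at[k],
                freqs_at[k], idx)
        return cache[state]

    # start: per-locus rejection for a consistent configuration
    config = np.empty(len(loci), dtype=np.int64)
    for k in range(len(loci)):
        for attempt in range(max_start_attempts):
            s = int(rng.integers(0, 1 << n_bits))
            if lik(k, s) > 0:
                config[k] = s
                break
        else:
            raise EngineError(
                f"no consistent inheritance vector found at marker {loci[k]} "
                f"after {max_start_attempts} attempts")

    cur_lik = [lik(k, int(config[k])) for k in range(len(loci))]

    def trans_logratio(k_edge: int, bit: int, old_l: int, old_r: int,
                       new_l: int, new_r: int) -> float:
        lt, l1t = log_theta[k_edge]
        old = lt if ((old_l ^ old_r) >> bit) & 1 else l1t
        new = lt if ((new_l ^ new_r) >> bit) & 1 else l1t
        return new - old

    def trans_logp(k_edge: int, left: int, right: int) -> float:
        lt, l1t = log_theta[k_edge]
        d = bin(left ^ right).count("1")
        return (d * lt if d else 0.0) + (n_bits - d) * l1t

    # founder-phase flip masks: for founder f, the meiosis bits of its
    # children that select between f's two labels
    phase_masks = []
    for f in idx.founders:
        mask = 0
        for n in idx.nonfounders:
            ind = ped.individuals[n]
            bp_, bm_ = idx.bit_pair(n)
            if ind.father == f:
                mask |= 1 << bp_
            if ind.mother == f:
                mask |= 1 << bm_
        if mask:
            phase_masks.append(mask)

    phase_flip_fraction = 0.1 if phase_masks else 0.0
    kept: list[int] = []
    n_loci = len(loci)
    for it in range(schedule.total):
        u_move = rng.random()
        if u_move < phase_flip_fraction:
            mask = phase_masks[int(rng.integers(0, len(phase_masks)))]
            config ^= mask  # exact symmetry: always accepted
            for k2 in range(n_loci):
                s = int(config[k2])
                if s not in lik_cache[k2]:
                    lik_cache[k2][s] = cur_lik[k2]  # invariant under relabeling
                cur_lik[k2] = lik_cache[k2][s]
            if it >= schedule.burn_in and \
                    (it - schedule.burn_in) % schedule.thin == 0:
                kept.append(int(config[pos]))
            continue
        k = int(rng.integers(0, n_loci))
        old = int(config[k])
        if u_move < phase_flip_fraction + block_proposal_fraction:
            new = int(rng.integers(0, 1 << n_bits))
            changed_bits = None
        else:
            bit = int(rng.integers(0, n_bits))
            new = old ^ (1 << bit)
            changed_bits = bit
        if new == old:
            pass
        else:
            new_lik = lik(k, new)
            if new_lik > 0.0:
                logr = math.log(new_lik) - math.log(cur_lik[k])
                if changed_bits is not None:
                    bit = changed_bits
                    if k > 0:
                        logr += trans_logratio(k - 1, bit, int(config[k - 1]),
                                               old, int(config[k - 1]), new)
                    if k < n_loci - 1:
                        logr += trans_logratio(k, bit, old, int(config[k + 1]),
                                               new, int(config[k + 1]))
                else:
                    if k > 0:
                        logr += (trans_logp(k - 1, int(config[k - 1]), new)
                                 - trans_logp(k - 1, int(config[k - 1]), old))
                    if k < n_loci - 1:
                        logr += (trans_logp(k, new, int(config[k + 1]))
                                 - trans_logp(k, old, int(config[k + 1])))
                if logr >= 0 or rng.random() < math.exp(logr):
                    config[k] = new
                    cur_lik[k] = new_lik
        if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thin == 0:
            kept.append(int(config[pos]))

    samples = np.asarray(kept, dtype=np.int64)
    return InheritanceDistribution(
        n_bits=n_bits,
        position=(chrom, locus_index),
        samples=samples,
        meta={"method": "mcmc", "schedule": schedule, "seed": seed},
    )
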
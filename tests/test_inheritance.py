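"""Inheritance-vector machinery against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pedlink.inheritance import (
    BitCapExceeded,
    ExactEngine,
    MCMCSchedule,
    PedigreeIndex,
    descent_labels,
    exact_posterior,
    haldane_theta,
    sample_posterior,
    single_marker_likelihood,
    state_to_vector,
    vector_to_state,
)
from pedlink.pedigree import Individual, Marker, MarkerGenotypes, MarkerPanel
from pedlink.simulate import simulate_markers

from conftest import make_pedigree


# ---------------------------------------------------------------------------
# independent oracles


def oracle_labels(ped, vector, idx):
    """Gene-drop replay: recursively copy founder alleles down the tree."""
    out = {}

    def get(i):
        if i in out:
            return out[i]
        ind = ped[i]
        if ind.is_founder:
            out[i] = idx.founder_labels(i)
        else:
            bp, bm = idx.bit_pair(i)
            out[i] = (get(ind.father)[vector[bp]], get(ind.mother)[vector[bm]])
        return out[i]

    for i in ped.individuals:
        get(i)
    return out


def oracle_marker_likelihood(ped, vector, genotypes, freqs, idx):
    """Exhaustive sum over allele assignments to all 2F founder labels."""
    labels = oracle_labels(ped, vector, idx)
    alleles = list(freqs)
    total = 0.0
    for assign in itertools.product(alleles, repeat=idx.n_labels):
        w = 1.0
        for a in assign:
            w *= freqs[a]
        ok = True
        for i, g in genotypes.items():
            if g is None:
                continue
            pl, ml = labels[i]
            if tuple(sorted((assign[pl], assign[ml]))) != g:
                ok = False
                break
        if ok:
            total += w
    return total


def oracle_chain_posterior(ped, genos, panel, idx):
    """Direct summation over all vector paths of the multipoint chain."""
    S = idx.n_states
    loci = list(range(len(panel)))
    em = []
    for l in loci:
        g = {i: genos.get(i, l) for i in ped.individuals}
        em.append(np.array([
            oracle_marker_likelihood(ped, state_to_vector(s, idx.n_bits),
                                     g, panel[l].allele_frequencies, idx)
            for s in range(S)]))
    joint = np.ones([S] * len(loci)) / S
    for axis, e in enumerate(em):
        shape = [1] * len(loci)
        shape[axis] = S
        joint = joint * e.reshape(shape)
    for k in range(len(loci) - 1):
        theta = haldane_theta(panel[k + 1].cM - panel[k].cM)
        T = np.empty((S, S))
        for a in range(S):
            for b in range(S):
                d = bin(a ^ b).count("1")
                T[a, b] = theta ** d * (1 - theta) ** (idx.n_bits - d)
        shape = [1] * len(loci)
        shape[k], shape[k + 1] = S, S
        joint = joint * T.reshape(shape)
    joint /= joint.sum()
    return [joint.sum(axis=tuple(j for j in range(len(loci)) if j != k))
            for k in range(len(loci))]


# ---------------------------------------------------------------------------
# descent labels


def test_descent_labels_founder_and_full_sibs(sib_pair):
    idx = PedigreeIndex(sib_pair)
    v = (0, 1, 0, 1)  # identical bit pairs for both sibs
    labels = descent_labels(sib_pair, v, idx)
    assert labels["f"] == idx.founder_labels("f")
    assert labels["c1"] == labels["c2"]  # sharing both alleles IBD
    with pytest.raises(Exception):
        descent_labels(sib_pair, (0, 1))  # wrong length


def test_descent_labels_match_gene_drop_oracle(three_generation):
    idx = PedigreeIndex(three_generation)
    rng = np.random.default_rng(0)
    for _ in range(50):
        v = tuple(rng.integers(0, 2, size=idx.n_bits))
        assert descent_labels(three_generation, v, idx) == \
               oracle_labels(three_generation, v, idx)


# ---------------------------------------------------------------------------
# single-marker likelihood


def test_likelihood_all_missing_is_one(sib_pair):
    v = (0, 0, 0, 0)
    assert single_marker_likelihood(
        sib_pair, v, {i: None for i in sib_pair.individuals},
        {"A": 0.4, "B": 0.6}) == 1.0


def test_likelihood_mendelian_inconsistency_zero():
    trio = make_pedigree([
        Individual("f", sex="male"), Individual("m", sex="female"),
        Individual("c", father="f", mother="m", sex="male"),
    ])
    idx = PedigreeIndex(trio)
    genos = {"f": ("B", "B"), "m": None, "c": ("A", "A")}
    for s in range(idx.n_states):
        assert single_marker_likelihood(
            trio, state_to_vector(s, idx.n_bits), genos,
            {"A": 0.4, "B": 0.6}, idx) == 0.0


def test_likelihood_matches_enumeration_oracle(sib_pair):
    idx = PedigreeIndex(sib_pair)
    freqs = {"A": 0.4, "B": 0.6}
    rng = np.random.default_rng(1)
    for _ in range(20):
        genos = {}
        for i in sib_pair.individuals:
            if rng.random() < 0.2:
                genos[i] = None
            else:
                genos[i] = tuple(sorted(rng.choice(["A", "B"], size=2)))
        for s in range(idx.n_states):
            v = state_to_vector(s, idx.n_bits)
            assert single_marker_likelihood(sib_pair, v, genos, freqs, idx) \
                == pytest.approx(
                    oracle_marker_likelihood(sib_pair, v, genos, freqs, idx),
                    abs=1e-12)


# ---------------------------------------------------------------------------
# exact posterior


def test_uninformative_markers_give_uniform_posterior(sib_trio,
                                                      biallelic_panel):
    genos = MarkerGenotypes({i: [None] * 3 for i in sib_trio.individuals})
    dist = exact_posterior(sib_trio, genos, biallelic_panel, 1)
    assert np.allclose(dist.probs, 1.0 / dist.probs.size)


def test_single_informative_marker_sib_pair(sib_pair):
    """A fully informative marker pins the posterior to the observed sharing."""
    panel = MarkerPanel([Marker("m0", "1", 1000, 0.0,
                                {a: 0.25 for a in "ABCD"})])
    genos = MarkerGenotypes({
        "f": [("A", "B")], "m": [("C", "D")],
        "c1": [("A", "C")], "c2": [("A", "C")],
    })
    dist = exact_posterior(sib_pair, genos, panel, 0)
    idx = PedigreeIndex(sib_pair)
    for s in np.nonzero(dist.probs > 1e-12)[0]:
        labels = descent_labels(sib_pair, state_to_vector(int(s), idx.n_bits),
                                idx)
        assert labels["c1"] == labels["c2"]  # both alleles shared IBD
    assert dist.probs.sum() == pytest.approx(1.0)


def test_exact_posterior_matches_path_sum_oracle(sib_trio, biallelic_panel):
    rng = np.random.default_rng(7)
    mg = simulate_markers(sib_trio, biallelic_panel, rng)
    # knock out some calls to exercise partial information
    tab = {i: [g if rng.random() > 0.3 else None for g in row]
           for i, row in mg.table.items()}
    genos = MarkerGenotypes(tab)
    idx = PedigreeIndex(sib_trio)
    marg = oracle_chain_posterior(sib_trio, genos, biallelic_panel, idx)
    for locus in range(3):
        dist = exact_posterior(sib_trio, genos, biallelic_panel, locus)
        assert 0.5 * np.abs(dist.probs - marg[locus]).sum() < 1e-9


def test_emission_fast_path_equals_generic(sib_trio, biallelic_panel):
    rng = np.random.default_rng(3)
    mg = simulate_markers(sib_trio, biallelic_panel, rng)
    eng = ExactEngine(sib_trio, mg, biallelic_panel)
    assert eng._separable
    fast = [eng._compute_emission(k) for k in range(3)]
    eng._separable = False
    for k in range(3):
        assert np.allclose(fast[k], eng._compute_emission(k))


def test_posterior_invariant_under_founder_phase_symmetry(sib_trio,
                                                          biallelic_panel):
    """Swapping a founder's two labels everywhere permutes states but leaves
    each state's posterior equal to its phase-flipped image's."""
    rng = np.random.default_rng(5)
    mg = simulate_markers(sib_trio, biallelic_panel, rng)
    dist = exact_posterior(sib_trio, mg, biallelic_panel, 1)
    idx = PedigreeIndex(sib_trio)
    # flip father's phase: flip each child's paternal meiosis bit
    mask = 0
    for n in idx.nonfounders:
        bp, _ = idx.bit_pair(n)
        mask |= 1 << bp
    states = np.arange(idx.n_states)
    assert np.allclose(dist.probs, dist.probs[states ^ mask])


def test_prior_ibd_sharing_equals_four_kinship(three_generation):
    from pedlink.pedigree import kinship
    from pedlink.inheritance import _label_arrays
    idx = PedigreeIndex(three_generation)
    labels = _label_arrays(idx)
    for a, b in (("a1", "a2"), ("gf", "b1"), ("b1", "b2")):
        la, lb = labels[a], labels[b]
        f = np.zeros(idx.n_states)
        for x in la:
            for y in lb:
                f += (x == y).astype(int)
        assert f.mean() / 4.0 == pytest.approx(
            kinship(three_generation, a, b), abs=1e-12)


def test_bit_cap_raises():
    members = [Individual("f", sex="male"), Individual("m", sex="female")]
    members += [Individual(f"c{k}", father="f", mother="m", sex="male")
                for k in range(9)]  # 18 bits
    ped = make_pedigree(members)
    genos = MarkerGenotypes({i: [None] for i in ped.individuals})
    panel = MarkerPanel([Marker("m0", "1", 1, 0.0, {"A": 0.5, "B": 0.5})])
    with pytest.raises(BitCapExceeded):
        exact_posterior(ped, genos, panel, 0)


# ---------------------------------------------------------------------------
# MCMC sampler


def test_sampler_reproducible_and_close_to_exact(
        sib_trio, informative_panel, informative_sibtrio_genotypes):
    d1 = sample_posterior(sib_trio, informative_sibtrio_genotypes,
                          informative_panel, 1, seed=9)
    d2 = sample_posterior(sib_trio, informative_sibtrio_genotypes,
                          informative_panel, 1, seed=9)
    assert np.array_equal(d1.samples, d2.samples)
    exact = exact_posterior(sib_trio, informative_sibtrio_genotypes,
                            informative_panel, 1)
    assert d1.tv_distance(exact) < 0.05


def test_sampler_uniform_under_no_data(sib_pair):
    panel = MarkerPanel([Marker("m0", "1", 1000, 0.0, {"A": 0.5, "B": 0.5})])
    genos = MarkerGenotypes({i: [None] for i in sib_pair.individuals})
    d = sample_posterior(sib_pair, genos, panel, 0, seed=4)
    counts = np.bincount(d.samples, minlength=16)
    expected = counts.sum() / 16
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.99, 15)


def test_distribution_serialization_round_trip(tmp_path, sib_pair):
    panel = MarkerPanel([Marker("m0", "1", 1000, 0.0,
                                {a: 0.25 for a in "ABCD"})])
    genos = MarkerGenotypes({
        "f": [("A", "B")], "m": [("C", "D")],
        "c1": [("A", "C")], "c2": [("A", "C")],
    })
    dist = exact_posterior(sib_pair, genos, panel, 0)
    dist.to_tsv(tmp_path / "d.tsv")
    text = (tmp_path / "d.tsv").read_text().splitlines()
    assert text[0] == "vector\tweight"
    total = sum(float(l.split("\t")[1]) for l in text[1:])
    assert total == pytest.approx(1.0, abs=1e-6)


def test_haldane_map_function():
    assert haldane_theta(0.0) == 0.0
    assert haldane_theta(50.0) == pytest.approx((1 - np.exp(-1)) / 2)
    assert haldane_theta(1e9) == pytest.approx(0.5)
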
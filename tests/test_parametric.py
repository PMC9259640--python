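"""Parametric LOD machinery: peeling, conditional likelihoods, conservation."""

import itertools

import numpy as np
import pytest

from pedlink.inheritance import ExactEngine, PedigreeIndex, state_to_vector
from pedlink.npl import ScoreTrack
from pedlink.parametric import (
    LoopedPedigreeError,
    TraitModelContext,
    all_model_lod_tracks,
    parametric_lod_track,
    trait_likelihood_brute_force,
    trait_likelihood_by_state,
    trait_likelihood_given_vector,
    trait_likelihood_unlinked,
)
from pedlink.penetrance import (
    LiabilityClass,
    LiabilityClassTable,
    build_liability_classes,
    default_models,
)
from pedlink.pedigree import Individual, MarkerGenotypes
from pedlink.simulate import simulate_markers

from conftest import make_pedigree


def ctx_for(ped, model_name="dominant-high"):
    return TraitModelContext.from_model(default_models()[model_name], ped)


def test_single_affected_founder_hand_sum():
    """HWE(0.001) x dominant-high penetrance at age 72, three genotype terms."""
    ped = make_pedigree([
        Individual("a", sex="male", affection="affected", age=72)])
    got = trait_likelihood_unlinked(ped, ctx_for(ped))
    expected = 0.999**2 * 0.03 + 2 * 0.999 * 0.001 * 0.95 + 0.001**2 * 0.95
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(0.031839, abs=5e-7)


def test_unknown_status_founder_is_one():
    ped = make_pedigree([
        Individual("a", sex="male", affection="unknown", age=70)])
    assert trait_likelihood_unlinked(ped, ctx_for(ped)) == pytest.approx(1.0)
    # missing age contributes no trait evidence either
    ped2 = make_pedigree([
        Individual("a", sex="male", affection="affected", age=None)])
    assert trait_likelihood_unlinked(ped2, ctx_for(ped2)) == pytest.approx(1.0)


@pytest.mark.parametrize("model_name", list(default_models()))
def test_peeling_matches_brute_force_enumeration(model_name):
    members = [
        Individual("f", sex="male", affection="affected", age=80),
        Individual("m", sex="female", affection="unaffected", age=78),
    ]
    members += [
        Individual(f"c{k}", father="f", mother="m",
                   sex="male" if k % 2 else "female",
                   affection="affected" if k < 2 else "unaffected",
                   age=50.0 + k)
        for k in range(4)
    ]
    ped = make_pedigree(members)
    ctx = ctx_for(ped, model_name)
    assert trait_likelihood_unlinked(ped, ctx) == pytest.approx(
        trait_likelihood_brute_force(ped, ctx), rel=1e-9)


def test_peeling_three_generation_matches_brute_force(three_generation):
    ctx = ctx_for(three_generation)
    assert trait_likelihood_unlinked(three_generation, ctx) == pytest.approx(
        trait_likelihood_brute_force(three_generation, ctx), rel=1e-9)


def test_looped_pedigree_rejected():
    # two pedigree nonfounders mating
    ped = make_pedigree([
        Individual("f", sex="male"), Individual("m", sex="female"),
        Individual("s1", father="f", mother="m", sex="male",
                   affection="affected", age=50),
        Individual("s2", father="f", mother="m", sex="female",
                   affection="affected", age=48),
        Individual("k", father="s1", mother="s2", sex="male",
                   affection="affected", age=20),
    ])
    with pytest.raises(LoopedPedigreeError):
        trait_likelihood_unlinked(ped, ctx_for(ped))


def test_conditional_likelihood_no_phenotypes_is_one(sib_pair):
    ped = sib_pair.with_affection({
        "c1": "unknown", "c2": "unknown"})
    ctx = ctx_for(ped)
    assert trait_likelihood_given_vector(ped, ctx, (0, 0, 0, 0)) == \
        pytest.approx(1.0)


def test_conditional_likelihood_matches_label_enumeration(sib_pair):
    """Independent oracle: enumerate risk assignments over founder labels."""
    ped = make_pedigree([
        Individual("f", sex="male", affection="affected", age=75),
        Individual("m", sex="female", affection="unaffected", age=74),
        Individual("c1", father="f", mother="m", sex="male",
                   affection="affected", age=50),
        Individual("c2", father="f", mother="m", sex="female",
                   affection="unaffected", age=48),
    ])
    ctx = ctx_for(ped)
    idx = PedigreeIndex(ped)
    from pedlink.inheritance import descent_labels
    q = ctx.model.trait_allele_freq
    for s in range(idx.n_states):
        v = state_to_vector(s, idx.n_bits)
        labels = descent_labels(ped, v, idx)
        expected = 0.0
        for assign in itertools.product((0, 1), repeat=idx.n_labels):
            w = 1.0
            for a in assign:
                w *= q if a else 1 - q
            for i in ped.individuals:
                pl, ml = labels[i]
                w *= ctx.phenotype_factor(i, assign[pl] + assign[ml])
            expected += w
        assert trait_likelihood_given_vector(ped, ctx, v) == \
            pytest.approx(expected, rel=1e-12)
        arr = trait_likelihood_by_state(ped, ctx)
        assert arr[s] == pytest.approx(expected, rel=1e-12)


def test_shared_vector_beats_baseline_for_affected_sibs(sib_trio):
    ped = sib_trio.with_affection({})
    aged = {i: Individual(ind.id, ind.father, ind.mother, ind.sex,
                          ind.affection, 55.0 if not ind.is_founder else 80.0)
            for i, ind in ped.individuals.items()}
    ped = make_pedigree(list(aged.values()), name="aged")
    ctx = ctx_for(ped)
    shared = (0, 0, 0, 1, 0, 0)  # all sibs share the paternal allele
    assert trait_likelihood_given_vector(ped, ctx, shared) > \
        trait_likelihood_unlinked(ped, ctx)


def test_prior_average_equals_baseline_conservation(three_generation):
    """Law of total probability: E_prior[P(aff | v)] == peeling baseline."""
    for name in default_models():
        ctx = ctx_for(three_generation, name)
        tl = trait_likelihood_by_state(three_generation, ctx)
        base = trait_likelihood_unlinked(three_generation, ctx)
        assert tl.mean() == pytest.approx(base, rel=1e-9)


def test_lod_track_zero_for_uninformative_markers(biallelic_panel):
    members = [
        Individual("f", sex="male", affection="affected", age=80),
        Individual("m", sex="female", affection="unaffected", age=78),
        Individual("c0", father="f", mother="m", sex="male",
                   affection="affected", age=52),
        Individual("c1", father="f", mother="m", sex="male",
                   affection="affected", age=54),
    ]
    ped = make_pedigree(members)
    genos = MarkerGenotypes({i: [None] * 3 for i in ped.individuals})
    tr = parametric_lod_track(ped, genos, biallelic_panel, ctx_for(ped))
    assert np.allclose(tr.values, 0.0, atol=1e-9)
    assert tr.kind == "LOD_parametric"


def test_lod_invariant_to_uniform_penetrance_scaling():
    """Scaling all penetrance entries by c multiplies numerator and
    denominator alike on an affected-only pedigree, so LOD cancels."""
    members = [
        Individual("f", sex="male", affection="affected", age=80),
        Individual("m", sex="female", affection="unknown"),
        Individual("c0", father="f", mother="m", sex="male",
                   affection="affected", age=52),
        Individual("c1", father="f", mother="m", sex="male",
                   affection="affected", age=54),
    ]
    ped = make_pedigree(members)
    model = default_models()["dominant-high"]
    table = build_liability_classes(model)
    scaled = LiabilityClassTable(
        classes=[LiabilityClass(c.age_low, c.age_high, 0.5 * c.f0,
                                0.5 * c.f1, 0.5 * c.f2)
                 for c in table.classes],
        model=model, unknown_age_class=table.unknown_age_class)
    ctx = TraitModelContext(model=model, table=table, ped=ped)
    ctx_scaled = TraitModelContext(model=model, table=scaled, ped=ped)
    rng = np.random.default_rng(0)
    from conftest import make_pedigree as _
    from pedlink.pedigree import Marker, MarkerPanel
    panel = MarkerPanel([Marker("m0", "1", 1000, 0.0,
                                {a: 0.25 for a in "ABCD"})])
    genos = simulate_markers(ped, panel, rng)
    t1 = parametric_lod_track(ped, genos, panel, ctx)
    t2 = parametric_lod_track(ped, genos, panel, ctx_scaled)
    assert np.allclose(t1.values, t2.values, atol=1e-9)


def test_all_model_tracks_report_per_model(sib_trio, biallelic_panel):
    ped = make_pedigree([
        Individual("f", sex="male", affection="affected", age=80),
        Individual("m", sex="female", affection="unaffected", age=79),
        Individual("c0", father="f", mother="m", sex="male",
                   affection="affected", age=52),
        Individual("c1", father="f", mother="m", sex="male",
                   affection="affected", age=50),
    ])
    genos = MarkerGenotypes({i: [None] * 3 for i in ped.individuals})
    tracks = all_model_lod_tracks(ped, genos, biallelic_panel,
                                  default_models())
    assert set(tracks) == {"dominant-high", "dominant-low",
                           "recessive-high", "recessive-low"}
    for name, tr in tracks.items():
        assert tr.meta["model"] == name
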
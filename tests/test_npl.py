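"""Allele-sharing scores, NPL standardization, conversions, region calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedlink.inheritance import PedigreeIndex, state_to_vector
from pedlink.npl import (
    LinkageRegion,
    ScoreTrack,
    call_regions,
    lod_to_npl,
    npl_to_lod,
    npl_track,
    null_moments,
    read_track_tsv,
    score_pairs,
    score_robdom,
    scores_by_state,
)
from pedlink.pedigree import Individual, Marker, MarkerGenotypes, MarkerPanel

from conftest import make_pedigree


# ---------------------------------------------------------------------------
# score functions


def test_spairs_sib_pair_sharing(sib_pair):
    assert score_pairs(sib_pair, (0, 0, 0, 0)) == 2.0  # share both alleles
    assert score_pairs(sib_pair, (0, 0, 1, 1)) == 0.0  # share nothing


def test_spairs_three_sibs_one_shared_paternal_allele():
    members = [Individual("f", sex="male"), Individual("m", sex="female")]
    members += [Individual(f"c{k}", father="f", mother="m", sex="male",
                           affection="affected") for k in range(3)]
    ped = make_pedigree(members)
    # all three share the paternal allele; with a biparental mother two of
    # three maternal alleles must coincide, adding one more IBD combination
    v = (0, 0, 0, 1, 0, 0)  # labels c0=(0,2) c1=(0,3) c2=(0,2)
    # pairs: (0,1) paternal only = 1; (0,2) paternal+maternal = 2; (1,2) = 1
    assert score_pairs(ped, v) == 4.0
    # labels c0=(0,2) c1=(1,2) c2=(1,2): (0,1) maternal=1, (0,2)=1,
    # (1,2) paternal+maternal=2
    assert score_pairs(ped, (0, 0, 1, 0, 1, 0)) == 4.0


def test_srobdom_floor_and_geometric_growth():
    # k affected sibs all sharing one paternal allele, k = 2..6
    vals = []
    for k in range(2, 7):
        members = [Individual("f", sex="male"), Individual("m", sex="female")]
        members += [Individual(f"c{j}", father="f", mother="m", sex="male",
                               affection="affected") for j in range(k)]
        ped = make_pedigree(members)
        idx = PedigreeIndex(ped)
        v = [0] * idx.n_bits
        # alternate maternal bits to avoid extra maternal sharing clusters
        for j in range(k):
            v[2 * j + 1] = j % 2
        vals.append(score_robdom(ped, tuple(v)))
    diffs_ok = all(b > a for a, b in zip(vals, vals[1:]))
    assert diffs_ok
    # growth at least geometric in the sharing-cluster term
    shared_term = [2.0 ** k - k - 1 for k in range(2, 7)]
    ratios = [b / a for a, b in zip(shared_term[:-1], shared_term[1:])]
    assert min(ratios) > 1.5


def test_srobdom_no_sharing_floor_is_zero(sib_pair):
    assert score_robdom(sib_pair, (0, 0, 1, 1)) == 0.0


def test_scores_by_state_match_scalar(sib_trio):
    idx = PedigreeIndex(sib_trio)
    for kind, fn in (("pairs", score_pairs), ("robdom", score_robdom)):
        arr = scores_by_state(sib_trio, kind)
        for s in range(idx.n_states):
            assert arr[s] == fn(sib_trio, state_to_vector(s, idx.n_bits))


def test_score_requires_two_affecteds():
    solo = make_pedigree([
        Individual("f", sex="male", affection="affected"),
        Individual("m", sex="female"),
        Individual("c", father="f", mother="m", sex="male"),
    ])
    with pytest.raises(ValueError):
        score_pairs(solo, (0, 0))
    with pytest.raises(ValueError):
        null_moments("pairs", solo)


# ---------------------------------------------------------------------------
# null moments


def test_null_moments_sib_pair_exact(sib_pair):
    mean, sd = null_moments("pairs", sib_pair)
    assert mean == pytest.approx(1.0)
    assert sd == pytest.approx(math.sqrt(0.5))


def test_null_moments_monte_carlo_close_to_exact(sib_pair):
    mean_e, sd_e = null_moments("pairs", sib_pair)
    n_mc = 20_000
    mean_mc, sd_mc = null_moments("pairs", sib_pair, bit_cap=0,
                                  n_mc=n_mc, seed=2)
    se = sd_e / math.sqrt(n_mc)
    assert abs(mean_mc - mean_e) < 3 * se
    assert abs(sd_mc - sd_e) < 0.05


def test_degenerate_pedigree_sd_zero():
    # affected parent-child pair: they always share exactly one allele IBD
    ped = make_pedigree([
        Individual("f", sex="male", affection="affected"),
        Individual("m", sex="female"),
        Individual("c", father="f", mother="m", sex="male",
                   affection="affected"),
    ])
    with pytest.raises(ValueError, match="degenerate"):
        null_moments("pairs", ped)


# ---------------------------------------------------------------------------
# NPL tracks


def test_npl_track_zero_for_missing_data(sib_trio, biallelic_panel):
    genos = MarkerGenotypes({i: [None] * 3 for i in sib_trio.individuals})
    tr = npl_track(sib_trio, genos, biallelic_panel, "pairs")
    assert np.allclose(tr.values, 0.0, atol=1e-9)


def test_npl_track_reaches_max_when_all_share(sib_trio):
    """Fully informative markers showing all sibs sharing both alleles."""
    panel = MarkerPanel([Marker("m0", "1", 1000, 0.0,
                                {a: 0.25 for a in "ABCD"})])
    genos = MarkerGenotypes({
        "f": [("A", "B")], "m": [("C", "D")],
        "c0": [("A", "C")], "c1": [("A", "C")], "c2": [("A", "C")],
    })
    mean0, sd0 = null_moments("pairs", sib_trio)
    arr = scores_by_state(sib_trio, "pairs")
    tr = npl_track(sib_trio, genos, panel, "pairs")
    assert tr.values[0] == pytest.approx((arr.max() - mean0) / sd0)


def test_npl_z_invariant_to_affine_score_rescaling(sib_trio,
                                                   biallelic_panel):
    from pedlink.simulate import simulate_markers
    rng = np.random.default_rng(8)
    genos = simulate_markers(sib_trio, biallelic_panel, rng)
    tr = npl_track(sib_trio, genos, biallelic_panel, "pairs")
    affine = lambda ped, v: 7.0 * score_pairs(ped, v) - 3.0
    tr2 = npl_track(sib_trio, genos, biallelic_panel, affine)
    assert np.allclose(tr.values, tr2.values, atol=1e-9)


def test_npl_track_mcmc_close_to_exact(sib_trio, informative_panel,
                                       informative_sibtrio_genotypes):
    tr = npl_track(sib_trio, informative_sibtrio_genotypes,
                   informative_panel, "pairs", method="exact")
    tr2 = npl_track(sib_trio, informative_sibtrio_genotypes,
                    informative_panel, "pairs", method="mcmc", seed=3)
    assert np.abs(tr.values - tr2.values).max() < 0.35  # MC noise scale
    assert tr2.meta["method"] == "mcmc"


def test_robdom_track_flags_fallback(sib_trio, biallelic_panel):
    genos = MarkerGenotypes({i: [None] * 3 for i in sib_trio.individuals})
    tr = npl_track(sib_trio, genos, biallelic_panel, "robdom")
    assert tr.meta["robdom_variant"] == "fallback-robdom"


# ---------------------------------------------------------------------------
# conversions


@pytest.mark.parametrize("lod, npl", [(3.3, 3.90), (1.0, 2.15), (0.0, 0.0)])
def test_threshold_conversion(lod, npl):
    assert lod_to_npl(lod) == pytest.approx(npl, abs=0.005)
    assert npl_to_lod(lod_to_npl(lod)) == pytest.approx(lod, abs=1e-12)


@given(st.floats(min_value=0, max_value=100))
@settings(max_examples=50, deadline=None)
def test_conversion_round_trip(lod):
    assert npl_to_lod(lod_to_npl(lod)) == pytest.approx(lod, rel=1e-9,
                                                        abs=1e-9)


def test_conversion_rejects_negative():
    with pytest.raises(ValueError):
        lod_to_npl(-0.1)
    with pytest.raises(ValueError):
        npl_to_lod(-1.0)


# ---------------------------------------------------------------------------
# region calling


def _track(values, chrom="1"):
    n = len(values)
    return ScoreTrack(
        chromosomes=[chrom] * n,
        bp=np.arange(1, n + 1) * 1000,
        cM=np.arange(n, dtype=float),
        values=np.asarray(values, dtype=float),
        kind="NPL_robdom", pedigree="t")


def oracle_call_regions(track, high, gap):
    """Brute force over all candidate intervals."""
    out = []
    by_chrom = {}
    for i, c in enumerate(track.chromosomes):
        by_chrom.setdefault(c, []).append(i)
    for c, idxs in by_chrom.items():
        valid = []
        for a in idxs:
            for b in idxs:
                if b < a or track.values[a] < high or track.values[b] < high:
                    continue
                inner = [i for i in idxs if a <= i <= b]
                n_pass = sum(track.values[i] >= high for i in inner)
                ok = all(track.values[i] >= high or track.values[i] > gap
                         for i in inner)
                if ok and n_pass >= 3:
                    valid.append((a, b, n_pass))
        # keep maximal intervals only
        for a, b, n_pass in valid:
            if not any((a2 <= a and b <= b2 and (a2, b2) != (a, b))
                       for a2, b2, _ in valid):
                peak = max(range(a, b + 1), key=lambda i: track.values[i])
                out.append(LinkageRegion(
                    chromosome=c, start_bp=int(track.bp[a]),
                    end_bp=int(track.bp[b]),
                    peak_value=float(track.values[peak]),
                    peak_statistic=track.kind, n_markers_passing=n_pass))
    return out


def test_call_regions_hand_examples():
    assert call_regions(_track([1.0, 2.0, 1.5, 0.4]), 3.90, 2.15) == []
    # gap rule: one interior marker above the gap threshold joins the run
    regs = call_regions(_track([4.0, 4.1, 2.5, 4.2]), 3.90, 2.15)
    assert len(regs) == 1
    r = regs[0]
    assert (r.start_bp, r.end_bp, r.n_markers_passing) == (1000, 4000, 3)
    assert r.peak_value == pytest.approx(4.2)
    # only two passing markers -> no region
    assert call_regions(_track([4.0, 4.1]), 3.90, 2.15) == []
    # interior below gap splits the run
    assert call_regions(_track([4.0, 4.1, 1.0, 4.2]), 3.90, 2.15) == []


def test_call_regions_empty_track_raises():
    t = ScoreTrack(chromosomes=[], bp=np.array([]), cM=np.array([]),
                   values=np.array([]), kind="NPL_pairs", pedigree="t")
    with pytest.raises(ValueError):
        call_regions(t, 3.9, 2.15)


@given(st.lists(st.floats(min_value=-2, max_value=6, allow_nan=False),
                min_size=1, max_size=50),
       st.integers(min_value=0, max_value=1))
@settings(max_examples=80, deadline=None)
def test_call_regions_matches_brute_force(values, split):
    n = len(values)
    chroms = ["1"] * n if not split else ["1"] * (n // 2) + ["2"] * (n - n // 2)
    t = ScoreTrack(chromosomes=chroms,
                   bp=np.array([1000 * (i + 1) for i in range(n)]),
                   cM=np.arange(n, dtype=float),
                   values=np.asarray(values), kind="NPL_pairs", pedigree="t")
    assert call_regions(t, 3.90, 2.15) == oracle_call_regions(t, 3.90, 2.15)


def test_track_tsv_round_trip(tmp_path, sib_trio, biallelic_panel):
    genos = MarkerGenotypes({i: [None] * 3 for i in sib_trio.individuals})
    tr = npl_track(sib_trio, genos, biallelic_panel, "robdom")
    tr.to_tsv(tmp_path / "t.tsv")
    tr2 = read_track_tsv(tmp_path / "t.tsv")
    assert tr2.kind == tr.kind and tr2.pedigree == tr.pedigree
    assert np.allclose(tr2.values, tr.values, atol=1e-6)
    assert tr2.meta["robdom_variant"] == "fallback-robdom"
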
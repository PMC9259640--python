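"""Shared fixtures: small pedigrees and marker panels built by hand."""

import numpy as np
import pytest

from pedlink.pedigree import (
    Individual,
    Marker,
    MarkerGenotypes,
    MarkerPanel,
    Pedigree,
)


def make_pedigree(members, name="test"):
    return Pedigree({m.id: m for m in members}, name=name)


@pytest.fixture
def sib_pair():
    """Two affected sibs, parents phenotype-unknown."""
    return make_pedigree([
        Individual("f", sex="male", affection="unknown"),
        Individual("m", sex="female", affection="unknown"),
        Individual("c1", father="f", mother="m", sex="male",
                   affection="affected"),
        Individual("c2", father="f", mother="m", sex="female",
                   affection="affected"),
    ], name="sibpair")


@pytest.fixture
def sib_trio():
    """Three affected sibs (6 meiosis bits, 64 states)."""
    members = [Individual("f", sex="male"), Individual("m", sex="female")]
    members += [
        Individual(f"c{k}", father="f", mother="m", sex="male",
                   affection="affected")
        for k in range(3)
    ]
    return make_pedigree(members, name="sibtrio")


@pytest.fixture
def three_generation():
    """Fig-2-like three-generation pedigree, ages decreasing by generation."""
    return make_pedigree([
        Individual("gf", sex="male", affection="affected", age=82),
        Individual("gm", sex="female", affection="unaffected", age=80),
        Individual("a1", father="gf", mother="gm", sex="male",
                   affection="affected", age=55),
        Individual("a2", father="gf", mother="gm", sex="female",
                   affection="unaffected", age=52),
        Individual("sp", sex="female", affection="unknown", age=54),
        Individual("b1", father="a1", mother="sp", sex="male",
                   affection="affected", age=28),
        Individual("b2", father="a1", mother="sp", sex="female",
                   affection="unknown", age=26),
    ], name="threegen")


@pytest.fixture
def informative_panel():
    """Three linked 4-allele markers: near-fully informative meioses."""
    freqs = {a: 0.25 for a in "ABCD"}
    return MarkerPanel([
        Marker(f"m{k}", "1", 1_000_000 * (k + 1), 4.0 * k, freqs)
        for k in range(3)
    ])


@pytest.fixture
def informative_sibtrio_genotypes():
    """Fully phased-informative parents; one missing call."""
    return MarkerGenotypes({
        "f": [("A", "B"), ("A", "B"), ("A", "B")],
        "m": [("C", "D"), ("C", "D"), ("C", "D")],
        "c0": [("A", "C"), ("A", "C"), ("A", "C")],
        "c1": [("B", "C"), ("B", "C"), ("A", "C")],
        "c2": [("A", "D"), None, ("B", "D")],
    })


@pytest.fixture
def biallelic_panel():
    return MarkerPanel([
        Marker(f"s{k}", "1", 500_000 * (k + 1), 5.0 * k,
               {"A": 0.4, "B": 0.6})
        for k in range(3)
    ])
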
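"""Age-dependent liability-class penetrance models for a late-onset trait.

Intracranial aneurysm penetrance rises with age, so the parametric linkage
model assigns each individual to an age-decade liability class.  A carrier
reaches maximum penetrance at age 70 (0.95 for the high-penetrance model,
0.80 for the low one) and each younger decade subtracts 0.15 until the
population-prevalence phenocopy floor of 0.03 is reached.  Non-carriers are
affected at the phenocopy rate in every class.  Four presets are provided:
dominant/recessive x high/low penetrance, with trait-allele frequency 0.001
(dominant) or 0.01 (recessive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import yaml

DECADE = 10.0


@dataclass(frozen=True)
class PenetranceModel:
    inheritance: str  # "dominant" | "recessive"
    level: str  # "high" | "low"
    phenocopy: float = 0.03
    max_age: float = 70.0
    max_penetrance: float = 0.95
    decrement_per_decade: float = 0.15
    trait_allele_freq: float = 0.001

    def __post_init__(self) -> None:
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError(f"bad inheritance {self.inheritance!r}")
        if self.level not in ("high", "low"):
            raise ValueError(f"bad level {self.level!r}")
        if not (0.0 <= self.phenocopy <= self.max_penetrance <= 1.0):
            raise ValueError("require 0 <= phenocopy <= max_penetrance <= 1")
        if self.decrement_per_decade <= 0:
            raise ValueError("decrement_per_decade must be positive")

    @property
    def name(self) -> str:
        return f"{self.inheritance}-{self.level}"


@dataclass(frozen=True)
class LiabilityClass:
    age_low: float
    age_high: float  # inclusive-exclusive [age_low, age_high)
    f0: float  # P(affected | 0 risk alleles)
    f1: float
    f2: float

    @property
    def penetrances(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


@dataclass
class LiabilityClassTable:
    classes: list[LiabilityClass]
    model: PenetranceModel
    unknown_age_class: LiabilityClass | None = None

    def class_for_age(self, age: float | None) -> LiabilityClass | None:
        """Class containing ``age``; the distinguished unknown-age class if None.

        Individuals in the unknown-age class carry no genotype information
        (all three penetrances equal the phenocopy rate), so likelihood code
        may equivalently skip them.
        """
        if age is None:
            return self.unknown_age_class
        for c in self.classes:
            if c.age_low <= age < c.age_high:
                return c
        raise ValueError(f"no liability class for age {age}")

    def penetrance(self, age: float | None, n_risk_alleles: int) -> float:
        c = self.class_for_age(age)
        if c is None:
            return self.model.phenocopy
        return c.penetrances[n_risk_alleles]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("age_low\tage_high\tf0\tf1\tf2\n")
            for c in self.classes:
                hi = "inf" if c.age_high == float("inf") else f"{c.age_high:g}"
                fh.write(f"{c.age_low:g}\t{hi}\t{c.f0:g}\t{c.f1:g}\t{c.f2:g}\n")


def carrier_penetrance_at_age(model: PenetranceModel, age: float) -> float:
    """Penetrance of the at-risk genotype at a given age.

    Age >= max_age gives the model maximum; each full decade younger
    subtracts ``decrement_per_decade``, floored at the phenocopy rate.
    """
    import math

    if age >= model.max_age:
        n_below = 0
    else:
        n_below = int(math.ceil((model.max_age - age) / DECADE))
    return max(model.phenocopy,
               model.max_penetrance - n_below * model.decrement_per_decade)


def build_liability_classes(model: PenetranceModel) -> LiabilityClassTable:
    """Expand a penetrance model into age-decade liability classes.

    Decade boundaries are [0,10), [10,20), ..., [60,70), [70,inf); age 70
    exactly falls in the maximum-penetrance class.  Dominant models set
    f1 = f2 = age penetrance; recessive models set f1 = f0 = phenocopy.
    """
    bounds = [(lo, lo + DECADE) for lo in
              [i * DECADE for i in range(int(model.max_age / DECADE))]]
    bounds.append((model.max_age, float("inf")))
    classes = []
    for lo, hi in bounds:
        f_age = carrier_penetrance_at_age(model, lo)
        if model.inheritance == "dominant":
            f0, f1, f2 = model.phenocopy, f_age, f_age
        else:
            f0, f1, f2 = model.phenocopy, model.phenocopy, f_age
        classes.append(LiabilityClass(lo, hi, f0, f1, f2))
    unknown = LiabilityClass(float("nan"), float("nan"),
                             model.phenocopy, model.phenocopy, model.phenocopy)
    return LiabilityClassTable(classes, model, unknown_age_class=unknown)


def default_models() -> dict[str, PenetranceModel]:
    """The four preset trait models: dominant/recessive x high/low."""
    out = {}
    for inh, q in (("dominant", 0.001), ("recessive", 0.01)):
        for level, fmax in (("high", 0.95), ("low", 0.80)):
            m = PenetranceModel(
                inheritance=inh, level=level, max_penetrance=fmax,
                trait_allele_freq=q,
            )
            out[m.name] = m
    return out


def save_model(model: PenetranceModel, path: str | Path) -> None:
    p = Path(path)
    data = asdict(model)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(data))
    else:
        p.write_text(json.dumps(data, indent=2))


def load_model(path: str | Path) -> PenetranceModel:
    p = Path(path)
    data = (yaml.safe_load(p.read_text()) if p.suffix in (".yaml", ".yml")
            else json.loads(p.read_text()))
    return PenetranceModel(**data)
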
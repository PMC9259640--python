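"""Pedigree and marker data model with PED/MAP I/O and validation.

The data model is deliberately minimal: a :class:`Pedigree` is a set of
:class:`Individual` records whose parent references form an acyclic graph,
a :class:`MarkerPanel` is an ordered list of mapped markers with population
allele frequencies, and :class:`MarkerGenotypes` is an individual x marker
table of unordered allele pairs.  All base-pair coordinates are 1-based and
every positional object carries a genome-build tag; mixing builds is a hard
error downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

MISSING = "0"

SEX_CODES = {"1": "male", "2": "female"}
AFFECTION_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree inputs."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "male"  # "male" | "female"
    affection: str = "unknown"  # "affected" | "unaffected" | "unknown"
    age: float | None = None
    in_gs: bool = False
    in_array: bool = True

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.id}: father/mother must both be set or both absent"
            )
        if self.age is not None and self.age < 0:
            raise PedigreeError(f"individual {self.id}: negative age")

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A single family: individuals keyed by id, parent edges acyclic."""

    individuals: dict[str, Individual]
    name: str = "ped"

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        """Nonfounders in topological (parents-before-children) order."""
        order = self.topological_order()
        return [i for i in order if not self.individuals[i].is_founder]

    def topological_order(self) -> list[str]:
        g = self._parent_graph()
        return list(nx.topological_sort(g))

    def _parent_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            if ind.father is not None:
                g.add_edge(ind.father, ind.id)
                g.add_edge(ind.mother, ind.id)
        return g

    def children_of(self, ind_id: str) -> list[str]:
        return [
            i.id
            for i in self.individuals.values()
            if ind_id in (i.father, i.mother)
        ]

    def affected(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.affection == "affected"]

    def with_affection(self, statuses: Mapping[str, str]) -> "Pedigree":
        new = {
            k: (replace(v, affection=statuses[k]) if k in statuses else v)
            for k, v in self.individuals.items()
        }
        return Pedigree(new, name=self.name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "individuals": [vars(i) for i in self.individuals.values()],
            },
            indent=2,
        )


@dataclass(frozen=True)
class Violation:
    individual: str | None
    rule: str
    message: str


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check pedigree invariants; violations are returned as data, not raised.

    Rules checked: parent references resolve, parent sexes match roles,
    parent->child graph is acyclic, and at least one founder exists.
    """
    inds = ped.individuals
    out: list[Violation] = []
    for ind in inds.values():
        for role, pid in (("father", ind.father), ("mother", ind.mother)):
            if pid is None:
                continue
            if pid not in inds:
                out.append(
                    Violation(ind.id, "unresolved-parent",
                              f"{ind.id}: {role} {pid!r} not in pedigree")
                )
            else:
                want = "male" if role == "father" else "female"
                if inds[pid].sex != want:
                    out.append(
                        Violation(pid, "sex-role",
                                  f"{pid} is {role} of {ind.id} but sex={inds[pid].sex}")
                    )
    g = nx.DiGraph()
    g.add_nodes_from(inds)
    for ind in inds.values():
        for pid in (ind.father, ind.mother):
            if pid is not None and pid in inds:
                g.add_edge(pid, ind.id)
    if not nx.is_directed_acyclic_graph(g):
        cyc = next(iter(nx.simple_cycles(g)))
        out.append(Violation(cyc[0], "cycle",
                             f"individual {cyc[0]} is its own ancestor"))
    if inds and not any(i.is_founder for i in inds.values()):
        out.append(Violation(None, "no-founder", "pedigree has no founder"))
    return out


# ---------------------------------------------------------------------------
# Kinship


def kinship(ped: Pedigree, id_a: str, id_b: str) -> float:
    """Recursive kinship coefficient phi(a, b).

    phi(a, a) = 0.5 (1 + phi(father_a, mother_a)); for a != b the individual
    farther from the founders is peeled onto its parents.  Founders are
    assumed unrelated and non-inbred.
    """
    for i in (id_a, id_b):
        if i not in ped:
            raise KeyError(f"unknown individual {i!r}")
    depth = _generation_depth(ped)
    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        if depth[a] < depth[b] or (depth[a] == depth[b] and a > b):
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        ia = ped[a]
        if a == b:
            val = 0.5 if ia.is_founder else 0.5 * (1.0 + phi(ia.father, ia.mother))
        elif ia.is_founder:
            # both founders (a is the deeper or equal one) -> unrelated
            val = 0.0
        else:
            val = 0.5 * (phi(ia.father, b) + phi(ia.mother, b))
        cache[key] = val
        return val

    return phi(id_a, id_b)


def _generation_depth(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}
    for ind_id in ped.topological_order():
        ind = ped[ind_id]
        depth[ind_id] = 0 if ind.is_founder else 1 + max(
            depth[ind.father], depth[ind.mother]
        )
    return depth


# ---------------------------------------------------------------------------
# Markers


@dataclass(frozen=True)
class Marker:
    id: str
    chromosome: str
    bp: int  # 1-based
    cM: float
    allele_frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        tot = sum(self.allele_frequencies.values())
        if abs(tot - 1.0) > 1e-9:
            raise PedigreeError(f"marker {self.id}: allele frequencies sum to {tot}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.allele_frequencies)


@dataclass
class MarkerPanel:
    markers: list[Marker]
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        last: dict[str, tuple[int, float]] = {}
        for m in self.markers:
            if m.chromosome in last:
                bp, cm = last[m.chromosome]
                if m.bp <= bp:
                    raise PedigreeError(
                        f"markers out of bp order on chromosome {m.chromosome}")
                if m.cM < cm:
                    raise PedigreeError(
                        f"cM decreases with bp on chromosome {m.chromosome}")
            last[m.chromosome] = (m.bp, m.cM)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.chromosome not in seen:
                seen.append(m.chromosome)
        return seen

    def chromosome_indices(self, chrom: str) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.chromosome == chrom]


Genotype = tuple[str, str] | None


@dataclass
class MarkerGenotypes:
    """individual -> per-marker unordered allele pair (None = missing)."""

    table: dict[str, list[Genotype]]

    def get(self, ind_id: str, marker_index: int) -> Genotype:
        row = self.table.get(ind_id)
        return None if row is None else row[marker_index]

    def n_markers(self) -> int:
        return len(next(iter(self.table.values()))) if self.table else 0

    def subset(self, indices: Sequence[int]) -> "MarkerGenotypes":
        return MarkerGenotypes(
            {k: [row[i] for i in indices] for k, row in self.table.items()}
        )


# ---------------------------------------------------------------------------
# PED/MAP I/O


def read_map(map_path: str | Path) -> list[tuple[str, str, float, int]]:
    """Read a MAP file -> list of (chrom, marker_id, cM, bp)."""
    out = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PedigreeError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
        chrom, mid, cm, bp = parts
        out.append((chrom, mid, float(cm), int(bp)))
    return out


def read_ped(
    ped_path: str | Path,
    map_path: str | Path,
    ages_path: str | Path | None = None,
    build: str = "GRCh38",
) -> tuple[Pedigree, MarkerPanel, MarkerGenotypes]:
    """Read a single-family PED/MAP pair (0 = missing parent/allele).

    Allele frequencies are estimated from the observed allele counts across
    all genotyped members (uniform over the allele codes seen in the data);
    they can be overridden afterwards on the returned panel.  Ages live in a
    sidecar TSV (id<TAB>age) because PED has no age column.
    """
    fams = read_ped_multi(ped_path, map_path, ages_path, build=build)
    if len(fams) != 1:
        raise PedigreeError(
            f"{ped_path}: expected one family, found {sorted(fams)}; use read_ped_multi"
        )
    return next(iter(fams.values()))


def read_ped_multi(
    ped_path: str | Path,
    map_path: str | Path,
    ages_path: str | Path | None = None,
    build: str = "GRCh38",
) -> dict[str, tuple[Pedigree, MarkerPanel, MarkerGenotypes]]:
    mapping = read_map(map_path)
    n_mark = len(mapping)
    ages: dict[str, float] = {}
    if ages_path is not None:
        for line in Path(ages_path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "id\t")):
                continue
            iid, age = line.split("\t")[:2]
            ages[iid] = float(age)

    rows: dict[str, list[tuple[Individual, list[Genotype]]]] = {}
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_mark:
            raise PedigreeError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_mark} columns, got {len(parts)}"
            )
        fam, iid, fa, mo, sex, aff = parts[:6]
        if sex not in SEX_CODES:
            raise PedigreeError(f"{ped_path}:{ln}: bad sex code {sex!r}")
        if aff not in AFFECTION_CODES:
            raise PedigreeError(f"{ped_path}:{ln}: bad affection code {aff!r}")
        ind = Individual(
            id=iid,
            father=None if fa == MISSING else fa,
            mother=None if mo == MISSING else mo,
            sex=SEX_CODES[sex],
            affection=AFFECTION_CODES[aff],
            age=ages.get(iid),
        )
        genos: list[Genotype] = []
        for k in range(n_mark):
            a, b = parts[6 + 2 * k], parts[7 + 2 * k]
            if a == MISSING or b == MISSING:
                genos.append(None)
            else:
                genos.append(tuple(sorted((a, b))))
        rows.setdefault(fam, []).append((ind, genos))

    out: dict[str, tuple[Pedigree, MarkerPanel, MarkerGenotypes]] = {}
    for fam, members in rows.items():
        ped = Pedigree({ind.id: ind for ind, _ in members}, name=fam)
        bad = [v for v in validate_pedigree(ped) if v.rule == "unresolved-parent"]
        if bad:
            raise PedigreeError(bad[0].message)
        geno_table = {ind.id: genos for ind, genos in members}
        markers = []
        for k, (chrom, mid, cm, bp) in enumerate(mapping):
            counts: dict[str, int] = {}
            for _, genos in members:
                g = genos[k]
                if g is not None:
                    for al in g:
                        counts[al] = counts.get(al, 0) + 1
            if not counts:
                freqs = {"1": 0.5, "2": 0.5}  # no data: nominal biallelic
            else:
                tot = sum(counts.values())
                freqs = {al: c / tot for al, c in sorted(counts.items())}
            markers.append(Marker(mid, chrom, bp, cm, freqs))
        out[fam] = (ped, MarkerPanel(markers, build=build),
                    MarkerGenotypes(geno_table))
    return out


_SEX_OUT = {"male": "1", "female": "2"}
_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


def write_ped(
    ped: Pedigree,
    panel: MarkerPanel,
    genotypes: MarkerGenotypes,
    ped_path: str | Path,
    map_path: str | Path,
    ages_path: str | Path | None = None,
) -> None:
    """Write PED/MAP (and optional ages TSV); inverse of :func:`read_ped`."""
    with open(map_path, "w") as fh:
        for m in panel.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t{m.cM:.6g}\t{m.bp}\n")
    order = ped.topological_order()
    with open(ped_path, "w") as fh:
        for iid in order:
            ind = ped[iid]
            cols = [
                ped.name, iid,
                ind.father or MISSING, ind.mother or MISSING,
                _SEX_OUT[ind.sex], _AFF_OUT[ind.affection],
            ]
            row = genotypes.table.get(iid, [None] * len(panel))
            for g in row:
                cols.extend(("0", "0") if g is None else g)
            fh.write(" ".join(cols) + "\n")
    if ages_path is not None:
        with open(ages_path, "w") as fh:
            fh.write("id\tage\n")
            for iid in order:
                if ped[iid].age is not None:
                    fh.write(f"{iid}\t{ped[iid].age:g}\n")
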
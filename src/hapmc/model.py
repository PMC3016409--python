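"""Data model for pedigreed SNP resources and LINKAGE-style pedigree file I/O.

A *resource* is a mixed collection of pedigrees and unrelated singletons,
all typed at a common ordered panel of biallelic SNP markers.  Genotypes are
unordered allele pairs over ``{1, 2}`` with ``0`` coding a missing allele;
allele ``2`` is treated as the minor allele throughout the package.

The on-disk format is the pre-makeped LINKAGE / PLINK text dialect: six
fixed columns (family, individual, father, mother, sex, affection) followed
by ``2 n`` allele columns, whitespace separated.  Marker information is a
small two-column text file (index, marker id), one marker per line.
"""
from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: genotype / phenotype codes (LINKAGE conventions)
MISSING = 0
UNAFFECTED = 1
AFFECTED = 2


class PedParseError(ValueError):
    """Structured parse error for pedigree / marker files."""


class PedigreeError(ValueError):
    """Invariant violation in an assembled pedigree."""


class MendelianInconsistencyError(ValueError):
    """Genotypes incompatible with Mendelian inheritance."""


@dataclass(frozen=True)
class Marker:
    id: str
    index: int
    alleles: tuple[str, str] = ("1", "2")


@dataclass(eq=False)
class Individual:
    """One pedigree member (or singleton) with unphased genotypes.

    ``genotypes`` is an ``(n_markers, 2)`` int8 array of unordered allele
    pairs; ``0`` means missing.  ``father``/``mother`` are both ``None`` for
    founders and both set for non-founders.
    """

    family: str
    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: int
    affection: int
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.family}:{self.iid}: both-or-neither parents "
                f"must be named (father={self.father!r}, mother={self.mother!r})"
            )
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape[1] != 2:
            raise PedigreeError(f"individual {self.iid}: genotypes must be (n, 2)")
        self.genotypes = g

    @property
    def is_founder(self) -> bool:
        return self.father is None

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    def typed_fraction(self) -> float:
        """Fraction of markers with a fully observed genotype."""
        if self.n_markers == 0:
            return 0.0
        ok = np.all(self.genotypes != MISSING, axis=1)
        return float(ok.mean())

    def is_typed(self, threshold: float) -> bool:
        return self.typed_fraction() >= threshold and self.typed_fraction() > 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Individual):
            return NotImplemented
        return (
            (self.family, self.iid, self.father, self.mother, self.sex, self.affection)
            == (other.family, other.iid, other.father, other.mother, other.sex, other.affection)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(eq=False)
class Pedigree:
    """A set of related individuals with an acyclic parent-child graph.

    ``check=False`` skips validation; reserved for internal constructions
    that provably preserve an already-validated structure.
    """

    family: str
    members: dict[str, Individual] = field(default_factory=dict)
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        if check:
            self.validate()

    def validate(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"family {self.family}: individual {ind.iid} names "
                        f"parent {pid} that does not exist in the family"
                    )
        # acyclicity of the parent graph (iterative colouring)
        state: dict[str, int] = {}
        for start in self.members:
            if state.get(start):
                continue
            stack = [start]
            while stack:
                iid = stack[-1]
                if state.get(iid) == 2:
                    stack.pop()
                    continue
                if state.get(iid) == 1:
                    state[iid] = 2
                    stack.pop()
                    continue
                state[iid] = 1
                ind = self.members[iid]
                for pid in (ind.father, ind.mother):
                    if pid is None:
                        continue
                    if state.get(pid) == 1:
                        raise PedigreeError(f"family {self.family}: parent-child cycle at {pid}")
                    if state.get(pid) != 2:
                        stack.append(pid)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.members.values() if i.is_founder]

    @property
    def descendants(self) -> list[Individual]:
        return [i for i in self.members.values() if not i.is_founder]

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """All (father, mother, offspring list) mating units, each once.

        Offspring listed for a pair are exactly their common children, in
        file order; the list of units is ordered by first-offspring
        appearance, which keeps downstream processing deterministic.
        """
        units: dict[tuple[str, str], list[str]] = {}
        for ind in self.members.values():
            if ind.is_founder:
                continue
            key = (ind.father, ind.mother)  # type: ignore[arg-type]
            units.setdefault(key, []).append(ind.iid)
        return [(f, m, kids) for (f, m), kids in units.items()]

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children."""
        out: list[Individual] = []
        done: set[str] = set()
        pending = list(self.members.values())
        while pending:
            rest = []
            for ind in pending:
                if ind.is_founder or (ind.father in done and ind.mother in done):
                    out.append(ind)
                    done.add(ind.iid)
                else:
                    rest.append(ind)
            if len(rest) == len(pending):  # pragma: no cover - guarded by validate()
                raise PedigreeError(f"family {self.family}: unresolved parent ordering")
            pending = rest
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.family == other.family and self.members == other.members


@dataclass(eq=False)
class Resource:
    """A mixed collection of pedigrees and singletons over one marker panel."""

    markers: list[Marker]
    pedigrees: list[Pedigree] = field(default_factory=list)
    singletons: list[Individual] = field(default_factory=list)
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        if not check:
            return
        seen: set[str] = set()
        for fam in [p.family for p in self.pedigrees] + [s.family for s in self.singletons]:
            if fam in seen:
                raise PedigreeError(f"duplicate family id {fam!r}")
            seen.add(fam)
        n = self.n_markers
        for ind in self.individuals():
            if ind.n_markers != n:
                raise PedigreeError(
                    f"individual {ind.family}:{ind.iid} has {ind.n_markers} genotypes, "
                    f"expected {n}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def individuals(self) -> Iterator[Individual]:
        for ped in self.pedigrees:
            yield from ped
        yield from self.singletons

    def n_individuals(self) -> int:
        return sum(1 for _ in self.individuals())

    def genotype_matrix(self) -> np.ndarray:
        """Stacked ``(n_individuals, n_markers, 2)`` genotype array."""
        return np.stack([ind.genotypes for ind in self.individuals()])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Resource):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.pedigrees == other.pedigrees
            and self.singletons == other.singletons
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> list[Marker]:
    """Read a marker-info file: ``index id`` pairs or one id per line."""
    markers: list[Marker] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) >= 2:
                try:
                    idx = int(tokens[0])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise PedParseError(f"{path}:{lineno}: bad marker index {tokens[0]!r}")
                markers.append(Marker(id=tokens[1], index=idx))
            else:
                markers.append(Marker(id=tokens[0], index=len(markers)))
    # normalise to consecutive 0-based order
    markers.sort(key=lambda m: m.index)
    markers = [Marker(id=m.id, index=i, alleles=m.alleles) for i, m in enumerate(markers)]
    if len({m.id for m in markers}) != len(markers):
        raise PedParseError(f"{path}: duplicate marker ids")
    return markers


def _parse_parent(token: str) -> Optional[str]:
    return None if token == "0" else token


def read_ped(ped_path: str | Path, marker_path: str | Path) -> Resource:
    """Read a LINKAGE-style pre-makeped ped file plus marker info.

    Column layout: FID IID PAT MAT SEX AFF followed by ``2 n`` allele
    columns with codes ``{0, 1, 2}`` (0 = missing).  A half-missing genotype
    (exactly one allele 0) is coerced to fully missing and logged, since the
    phasing model carries no half-missing state.
    """
    markers = read_map(marker_path)
    n = len(markers)
    rows: list[tuple[int, Individual]] = []
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n} columns for "
                    f"{n} markers, got {len(tokens)}"
                )
            fid, iid, pat, mat, sex_s, aff_s = tokens[:6]
            try:
                alleles = np.array([int(t) for t in tokens[6:]], dtype=np.int8)
            except ValueError:
                raise PedParseError(f"{ped_path}:{lineno}: non-integer allele code")
            if np.any((alleles < 0) | (alleles > 2)):
                bad = alleles[(alleles < 0) | (alleles > 2)][0]
                raise PedParseError(
                    f"{ped_path}:{lineno}: allele code {bad} outside {{0,1,2}}"
                )
            geno = alleles.reshape(n, 2)
            half = (geno == 0).sum(axis=1) == 1
            if half.any():
                log.info(
                    "%s:%d: individual %s:%s has %d half-missing genotype(s); "
                    "coerced to fully missing",
                    ped_path, lineno, fid, iid, int(half.sum()),
                )
                geno[half] = 0
            try:
                ind = Individual(
                    family=fid, iid=iid,
                    father=_parse_parent(pat), mother=_parse_parent(mat),
                    sex=int(sex_s), affection=int(aff_s), genotypes=geno,
                )
            except PedigreeError as exc:
                raise PedParseError(f"{ped_path}:{lineno}: {exc}") from exc
            rows.append((lineno, ind))

    by_family: dict[str, list[tuple[int, Individual]]] = {}
    for lineno, ind in rows:
        by_family.setdefault(ind.family, []).append((lineno, ind))

    pedigrees: list[Pedigree] = []
    singletons: list[Individual] = []
    for fam, items in by_family.items():
        inds = [i for _, i in items]
        if len(inds) == 1 and inds[0].is_founder:
            singletons.append(inds[0])
            continue
        try:
            pedigrees.append(Pedigree(family=fam, members={i.iid: i for i in inds}))
        except PedigreeError as exc:
            lineno = items[0][0]
            raise PedParseError(f"{ped_path}:{lineno}: {exc}") from exc
    return Resource(markers=markers, pedigrees=pedigrees, singletons=singletons)


def write_ped(resource: Resource, ped_path: str | Path, marker_path: str | Path | None = None) -> None:
    """Write a resource back to tab-delimited ped (and optionally map) text."""
    with open(ped_path, "w") as fh:
        for ind in resource.individuals():
            fields = [
                ind.family, ind.iid,
                ind.father or "0", ind.mother or "0",
                str(ind.sex), str(ind.affection),
            ]
            fields += [str(int(a)) for a in ind.genotypes.ravel()]
            fh.write("\t".join(fields) + "\n")
    if marker_path is not None:
        with open(marker_path, "w") as fh:
            for m in resource.markers:
                fh.write(f"{m.index}\t{m.id}\n")
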
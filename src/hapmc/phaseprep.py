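"""Rule-based preprocessing of pedigree genotypes before haplotype enumeration.

Three responsibilities:

* **Pedigree splitting** — large pedigrees are cut down to the substructures
  worth phasing: nuclear families in which both parents and at least one
  offspring pass a genotyping threshold are retained and reconnected through
  shared members; everyone else is either phased as an independent
  individual or dropped from phasing (never from the later gene-dropping
  structure).
* **Bit-vector loading** — each individual's genotypes are expanded into six
  n-locus bit vectors (homozygous / heterozygous / unphased at the pair
  level; set / missing / value per haplotype), so that all deductions are
  whole-vector logical operations.
* **Iterated deduction rules** — homozygous parent-to-offspring and
  offspring-to-parent updates plus trio-level inheritance/transmission
  reasoning, repeated to a fixed point.  Every deduction is *sound*: it never
  removes a Mendelian-consistent haplotype configuration, it only shrinks
  the ambiguity that the enumeration step must expand.

All rules assume a zero-recombination autosomal region and error-free SNPs;
a contradiction therefore always raises :class:`MendelianInconsistencyError`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    Individual,
    MendelianInconsistencyError,
    Pedigree,
    Resource,
)

log = logging.getLogger(__name__)

FATHER = "F"
MOTHER = "M"


@dataclass
class PhaseState:
    """Six per-individual bit vectors plus a label-gauge flag.

    ``hom``/``het``/``unphased`` are pair-level; ``hset``/``miss``/``val``
    are per haplotype (rows 0 and 1).  ``val`` bit 1 means the minor allele
    ("2").  ``pinned`` records whether any rule has broken the label symmetry
    between the two haplotypes, i.e. whether haplotype indices 0/1 now carry
    meaning beyond an arbitrary ordering.
    """

    hom: np.ndarray
    het: np.ndarray
    unphased: np.ndarray
    hset: np.ndarray   # (2, n) bool
    miss: np.ndarray   # (2, n) bool
    val: np.ndarray    # (2, n) bool
    pinned: bool = False

    @property
    def n(self) -> int:
        return self.hom.shape[0]

    def copy(self) -> "PhaseState":
        return PhaseState(
            self.hom.copy(), self.het.copy(), self.unphased.copy(),
            self.hset.copy(), self.miss.copy(), self.val.copy(), self.pinned,
        )

    def fully_resolved(self) -> bool:
        return bool(self.hset.all())

    def dump(self, marker_width: int = 1) -> str:
        """Table-style text block (one row per bit variable), for fixtures."""
        def row(name: str, bits: np.ndarray) -> str:
            return name + "\t" + "".join("1" if b else "0" for b in bits)
        lines = [
            row("homozygous", self.hom),
            row("heterozygous", self.het),
            row("unphased", self.unphased),
        ]
        for k in (0, 1):
            lines += [
                row(f"set{k + 1}", self.hset[k]),
                row(f"missing{k + 1}", self.miss[k]),
                row(f"value{k + 1}", self.val[k]),
            ]
        return "\n".join(lines)


def load_phase_state(ind_or_genotypes: Individual | np.ndarray) -> PhaseState:
    """Load genotypes into the six bit variables (preprocessing step 1)."""
    if isinstance(ind_or_genotypes, Individual):
        g = ind_or_genotypes.genotypes
    else:
        g = np.asarray(ind_or_genotypes, dtype=np.int8)
    a1, a2 = g[:, 0], g[:, 1]
    missing = (a1 == 0) | (a2 == 0)
    hom = ~missing & (a1 == a2)
    het = ~missing & (a1 != a2)
    minor = hom & (a1 == 2)
    return PhaseState(
        hom=hom,
        het=het,
        unphased=het.copy(),
        hset=np.vstack([hom, hom]).copy(),
        miss=np.vstack([missing, missing]).copy(),
        val=np.vstack([minor, minor]).copy(),
    )


# ---------------------------------------------------------------------------
# pedigree splitting
# ---------------------------------------------------------------------------

@dataclass
class SubStructure:
    """A retained, connected pedigree fragment or a detached individual."""

    family: str
    members: list[str]                                 # iids retained for phasing
    families: list[tuple[str, str, list[str]]] = field(default_factory=list)
    individuals: dict[str, Individual] = field(default_factory=dict)

    @property
    def detached(self) -> bool:
        return not self.families

    @property
    def children(self) -> set[str]:
        return {c for _, _, kids in self.families for c in kids}

    @property
    def founders(self) -> list[str]:
        kids = self.children
        return [m for m in self.members if m not in kids]

    def structure_signature(self) -> tuple:
        """Hashable shape key (member positions, family wiring) for caching."""
        pos = {m: i for i, m in enumerate(self.members)}
        fams = tuple(
            (pos[f], pos[m], tuple(pos[c] for c in kids))
            for f, m, kids in self.families
        )
        return (len(self.members), fams)


def split_pedigree(ped: Pedigree, min_genotyped_fraction: float = 0.5) -> list[SubStructure]:
    """Select the substructures of a pedigree to retain for phasing.

    A nuclear family is retained when both parents and at least one offspring
    meet the genotyping threshold; offspring below the threshold are not
    carried into the substructure (they are coded fully missing downstream).
    Retained families sharing members are connected into maximal fragments.
    Typed members of no retained family become detached individuals; untyped
    ones are excluded from phasing altogether.

    Fragments whose family graph contains a loop (e.g. through inbreeding)
    are detached into typed singletons with a warning.
    """
    typed = {i.iid: i.is_typed(min_genotyped_fraction) for i in ped}
    retained: list[tuple[str, str, list[str]]] = []
    for f, m, kids in ped.nuclear_families():
        good_kids = [c for c in kids if typed[c]]
        if typed[f] and typed[m] and good_kids:
            retained.append((f, m, good_kids))

    # union-find over retained families; loop detection along the way
    parent = list(range(len(retained)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    loopy: set[int] = set()
    owner: dict[str, int] = {}
    for idx, (f, m, kids) in enumerate(retained):
        for iid in [f, m] + kids:
            if iid in owner:
                ra, rb = find(owner[iid]), find(idx)
                if ra == rb:
                    loopy.add(ra)
                else:
                    parent[rb] = ra
            else:
                owner[iid] = idx
    # a pair of families sharing >=2 members also closes a loop
    member_fams: dict[str, list[int]] = {}
    for idx, (f, m, kids) in enumerate(retained):
        for iid in [f, m] + kids:
            member_fams.setdefault(iid, []).append(idx)
    pair_count: dict[tuple[int, int], int] = {}
    for iid, fams in member_fams.items():
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                key = (min(fams[i], fams[j]), max(fams[i], fams[j]))
                pair_count[key] = pair_count.get(key, 0) + 1
    for (a, b), cnt in pair_count.items():
        if cnt >= 2:
            loopy.add(find(a))

    fragments: dict[int, list[int]] = {}
    for idx in range(len(retained)):
        fragments.setdefault(find(idx), []).append(idx)

    subs: list[SubStructure] = []
    in_fragment: set[str] = set()
    n_frag = 0
    for root, fam_idxs in fragments.items():
        fam_list = [retained[i] for i in fam_idxs]
        members: list[str] = []
        for f, m, kids in fam_list:
            for iid in [f, m] + kids:
                if iid not in members:
                    members.append(iid)
        if root in loopy:
            log.warning(
                "family %s: loop detected in retained substructure; "
                "members detached to independent individuals for phasing",
                ped.family,
            )
            for iid in members:
                if typed[iid]:
                    subs.append(SubStructure(
                        family=ped.family, members=[iid],
                        individuals={iid: ped.members[iid]},
                    ))
            in_fragment.update(members)
            continue
        n_frag += 1
        subs.append(SubStructure(
            family=ped.family,
            members=members,
            families=fam_list,
            individuals={iid: ped.members[iid] for iid in members},
        ))
        in_fragment.update(members)

    for ind in ped:
        if ind.iid not in in_fragment and typed[ind.iid]:
            subs.append(SubStructure(
                family=ped.family, members=[ind.iid],
                individuals={ind.iid: ind},
            ))
    return subs


def split_resource(
    resource: Resource, min_genotyped_fraction: float = 0.5, naive: bool = False
) -> list[SubStructure]:
    """Substructures for every pedigree plus typed singletons.

    With ``naive=True`` pedigree structure is ignored entirely and every
    typed individual is phased independently (the pedigree-naive baseline).
    """
    subs: list[SubStructure] = []
    if naive:
        for ind in resource.individuals():
            if ind.is_typed(min_genotyped_fraction):
                subs.append(SubStructure(
                    family=ind.family, members=[ind.iid],
                    individuals={ind.iid: ind},
                ))
        return subs
    for ped in resource.pedigrees:
        subs.extend(split_pedigree(ped, min_genotyped_fraction))
    for ind in resource.singletons:
        if ind.is_typed(min_genotyped_fraction):
            subs.append(SubStructure(
                family=ind.family, members=[ind.iid],
                individuals={ind.iid: ind},
            ))
    return subs


# ---------------------------------------------------------------------------
# deduction rules
# ---------------------------------------------------------------------------

@dataclass
class PrepResult:
    """Fixed-point phase states plus inheritance/transmission bookkeeping."""

    sub: SubStructure
    states: dict[str, PhaseState]
    # child iid -> [source of hap0, source of hap1] in {FATHER, MOTHER, None}
    inh: dict[str, list[Optional[str]]]
    # (parent iid, child iid) -> transmitted parental haplotype index
    trans: dict[tuple[str, str], Optional[int]]


def _err(ctx: str, detail: str) -> MendelianInconsistencyError:
    return MendelianInconsistencyError(f"{ctx}: {detail}")


def _normalize(st: PhaseState, ctx: str) -> bool:
    """Propagate forced complements and re-derive pair-level status bits."""
    changed = False
    while True:
        inner = False
        for j in (0, 1):
            m = st.het & st.hset[j] & ~st.hset[1 - j]
            if m.any():
                st.hset[1 - j] |= m
                st.val[1 - j] = np.where(m, ~st.val[j], st.val[1 - j])
                st.miss[1 - j] &= ~m
                inner = True
        known = st.hset[0] & st.hset[1]
        if (st.unphased & known).any():
            st.unphased &= ~known
            inner = True
        upd = known & ~(st.hom | st.het)
        if upd.any():
            eq = ~(st.val[0] ^ st.val[1])
            st.hom |= upd & eq
            st.het |= upd & ~eq
            inner = True
        for j in (0, 1):
            if (st.miss[j] & st.hset[j]).any():
                st.miss[j] &= ~st.hset[j]
                inner = True
        bad_hom = st.hom & known & (st.val[0] ^ st.val[1])
        if bad_hom.any():
            raise _err(ctx, f"homozygous locus {int(np.argmax(bad_hom))} phased to unequal alleles")
        bad_het = st.het & known & ~(st.val[0] ^ st.val[1])
        if bad_het.any():
            raise _err(ctx, f"heterozygous locus {int(np.argmax(bad_het))} phased to equal alleles")
        if not inner:
            return changed
        changed = True


def _conflict(sa: PhaseState, i: int, sb: PhaseState, j: int) -> np.ndarray:
    """Loci where haplotype ``i`` of ``sa`` provably differs from hap ``j`` of ``sb``."""
    return sa.hset[i] & sb.hset[j] & (sa.val[i] ^ sb.val[j])


def _excluded_from(sa: PhaseState, i: int, sb: PhaseState) -> bool:
    """True when hap ``i`` of ``sa`` can be *neither* haplotype of ``sb``."""
    return bool(_conflict(sa, i, sb, 0).any() and _conflict(sa, i, sb, 1).any())


def _other(role: str) -> str:
    return MOTHER if role == FATHER else FATHER


def _step2(
    P: PhaseState, Q: PhaseState, C: PhaseState,
    prole: str, inh_c: list[Optional[str]], ctx: str,
) -> bool:
    """Parent-to-offspring homozygous update (P = updating parent, Q = other)."""
    # outright impossibility: parent homozygous, both child haps set and unequal to it
    bad = P.hom & C.hset[0] & C.hset[1] & (C.val[0] ^ P.val[0]) & (C.val[1] ^ P.val[0])
    if bad.any():
        raise _err(ctx, f"parent homozygous at locus {int(np.argmax(bad))} conflicts with offspring")

    j: Optional[int] = None
    assign_after = False
    if prole in inh_c:
        j = inh_c.index(prole)
    elif inh_c[0] is not None or inh_c[1] is not None:
        # one hap attributed to the other parent -> the remaining one is P's
        k = 0 if inh_c[0] is not None else 1
        j = 1 - k
        assign_after = True
    elif not C.pinned:
        j = 0
        assign_after = True
    else:
        # inheritance rule (exclusion): which orientation is feasible?
        feas = []
        for jj in (0, 1):
            ok = not _excluded_from(C, jj, P) and not _excluded_from(C, 1 - jj, Q)
            feas.append(ok)
        if not any(feas):
            raise _err(ctx, "offspring haplotypes excluded from both parents")
        if feas[0] != feas[1]:
            j = 0 if feas[0] else 1
            assign_after = True
        else:
            return False  # inconclusive

    if inh_c[j] == prole:
        conf = P.hom & C.hset[j] & (C.val[j] ^ P.val[0])
        if conf.any():
            raise _err(ctx, f"inherited haplotype conflicts with parent at locus {int(np.argmax(conf))}")

    upd_unph = P.hom & C.unphased
    upd_miss = P.hom & C.miss[j]
    m = upd_unph | upd_miss
    if not m.any():
        return False
    C.hset[j] |= m
    C.val[j] = np.where(m, P.val[0], C.val[j])
    C.miss[j] &= ~m
    C.unphased &= ~upd_unph
    if assign_after or inh_c[j] is None:
        inh_c[j] = prole
        inh_c[1 - j] = _other(prole)
    C.pinned = True
    _normalize(C, ctx)
    return True


def _step3(
    P: PhaseState, C: PhaseState,
    trans: dict, pkey: tuple[str, str], ctx: str,
) -> bool:
    """Offspring-to-parent homozygous update."""
    bad = C.hom & P.hset[0] & P.hset[1] & (P.val[0] ^ C.val[0]) & (P.val[1] ^ C.val[0])
    if bad.any():
        raise _err(ctx, f"offspring homozygous at locus {int(np.argmax(bad))} conflicts with parent")

    q = trans.get(pkey)
    derived = False
    if q is None:
        if not P.pinned:
            q = 0
        else:
            # transmission rule (exclusion)
            ex0 = _excluded_from(P, 0, C)
            ex1 = _excluded_from(P, 1, C)
            if ex0 and ex1:
                raise _err(ctx, "both parental haplotypes excluded from offspring")
            if ex0:
                q, derived = 1, True
            elif ex1:
                q, derived = 0, True
            else:
                return False
    else:
        derived = True

    if derived:
        conf = C.hom & P.hset[q] & (P.val[q] ^ C.val[0])
        if conf.any():
            raise _err(ctx, f"transmitted haplotype conflicts with offspring at locus {int(np.argmax(conf))}")

    upd_unph = C.hom & P.unphased
    upd_miss = C.hom & P.miss[q]
    m = upd_unph | upd_miss
    if not m.any():
        return False
    P.hset[q] |= m
    P.val[q] = np.where(m, C.val[0], P.val[q])
    P.miss[q] &= ~m
    P.unphased &= ~upd_unph
    trans[pkey] = q
    P.pinned = True
    _normalize(P, ctx)
    return True


def _feasible_transmit(
    P: PhaseState, q: int, C: PhaseState, Q: PhaseState,
    prole: str, inh_c: list[Optional[str]], q_trans: Optional[int],
) -> bool:
    """Could parental haplotype ``q`` of P have been transmitted to C?

    Conditional exclusion: assume P transmits hap ``q``; the complementary
    offspring haplotype forced by C's genotypes must then be obtainable from
    the other parent Q.  Conservative: unknown positions never exclude.
    """
    for j in (0, 1):
        if inh_c[j] is not None and inh_c[j] != prole:
            continue
        if inh_c[1 - j] is not None and inh_c[1 - j] != _other(prole):
            continue
        if _conflict(P, q, C, j).any():
            continue
        o = 1 - j
        comp_mask = C.hset[o] | (P.hset[q] & C.het)
        comp_val = np.where(C.hset[o], C.val[o], ~P.val[q])
        rs = (q_trans,) if q_trans is not None else (0, 1)
        for r in rs:
            clash = Q.hset[r] & comp_mask & (Q.val[r] ^ comp_val)
            if not clash.any():
                return True
    return False


def _step4(
    F: PhaseState, M: PhaseState, C: PhaseState,
    cid: str, fid: str, mid: str,
    inh_c: list[Optional[str]], trans: dict, ctx: str,
) -> bool:
    """Trio-level inheritance/transmission reasoning."""
    changed = False

    # (i) resolve unknown transmissions by conditional exclusion
    for P, Q, pid, qid, prole in ((F, M, fid, mid, FATHER), (M, F, mid, fid, MOTHER)):
        pkey = (pid, cid)
        if trans.get(pkey) is None and P.pinned:
            qt = trans.get((qid, cid))
            feas = [
                _feasible_transmit(P, q, C, Q, prole, inh_c, qt) for q in (0, 1)
            ]
            if not any(feas):
                raise _err(ctx, f"no transmissible haplotype from parent {pid}")
            if feas[0] != feas[1]:
                trans[pkey] = 0 if feas[0] else 1
                changed = True

    # (ii) resolve unknown inheritance from known transmissions
    if inh_c[0] is None and inh_c[1] is None:
        for P, pid, prole in ((F, fid, FATHER), (M, mid, MOTHER)):
            q = trans.get((pid, cid))
            if q is None:
                continue
            ne = [bool(_conflict(C, j, P, q).any()) for j in (0, 1)]
            if ne[0] and ne[1]:
                raise _err(ctx, f"transmitted haplotype of {pid} matches neither offspring haplotype")
            if ne[0] != ne[1]:
                j_not = 0 if ne[0] else 1
                inh_c[j_not] = _other(prole)
                inh_c[1 - j_not] = prole
                C.pinned = True
                changed = True
                break

    # (iii) rule-7 style copy along a fully identified shared haplotype
    for P, pid, prole in ((F, fid, FATHER), (M, mid, MOTHER)):
        q = trans.get((pid, cid))
        if q is None or prole not in inh_c:
            continue
        j = inh_c.index(prole)
        conf = _conflict(C, j, P, q)
        if conf.any():
            raise _err(ctx, f"shared haplotype of {pid}/{cid} conflicts at locus {int(np.argmax(conf))}")
        to_parent = C.hset[j] & ~P.hset[q]
        if to_parent.any():
            P.hset[q] |= to_parent
            P.val[q] = np.where(to_parent, C.val[j], P.val[q])
            P.miss[q] &= ~to_parent
            P.unphased &= ~(to_parent & P.het)
            P.pinned = True
            _normalize(P, ctx)
            changed = True
        to_child = P.hset[q] & ~C.hset[j]
        if to_child.any():
            C.hset[j] |= to_child
            C.val[j] = np.where(to_child, P.val[q], C.val[j])
            C.miss[j] &= ~to_child
            C.unphased &= ~(to_child & C.het)
            C.pinned = True
            _normalize(C, ctx)
            changed = True

    return changed


def _rule13(st: PhaseState) -> bool:
    """Gauge-fix the last ambiguous heterozygous locus of a symmetric state.

    When the two haplotypes are still interchangeable (not pinned) and only
    one heterozygous locus remains unphased, the phase choice is a pure
    relabelling; fix it deterministically (haplotype 1 gets the major
    allele).
    """
    if st.pinned or int(st.unphased.sum()) != 1:
        return False
    i = int(np.argmax(st.unphased))
    st.hset[:, i] = True
    st.val[0, i] = False
    st.val[1, i] = True
    st.unphased[i] = False
    st.pinned = True
    return True


def run_preprocessing(sub: SubStructure, loci: slice | None = None) -> PrepResult:
    """Iterate deduction steps over all retained trios to a fixed point.

    ``loci`` optionally restricts the states to a marker window (used by the
    partition-ligation strategy); the substructure membership itself is
    always decided on the full-length data.
    """
    loci = loci if loci is not None else slice(None)
    states = {
        iid: load_phase_state(sub.individuals[iid].genotypes[loci])
        for iid in sub.members
    }
    inh: dict[str, list[Optional[str]]] = {c: [None, None] for c in sub.children}
    trans: dict[tuple[str, str], Optional[int]] = {}
    if sub.detached:
        return PrepResult(sub=sub, states=states, inh=inh, trans=trans)

    n = next(iter(states.values())).n
    m = len(sub.members)
    max_sweeps = 2 * n * m + 8
    for _ in range(max_sweeps):
        changed = False
        for fid, mid, kids in sub.families:
            F, M = states[fid], states[mid]
            for cid in kids:
                C = states[cid]
                ctx = f"family {sub.family}, trio ({fid},{mid},{cid})"
                changed |= _step2(F, M, C, FATHER, inh[cid], ctx)
                changed |= _step2(M, F, C, MOTHER, inh[cid], ctx)
                changed |= _step3(F, C, trans, (fid, cid), ctx)
                changed |= _step3(M, C, trans, (mid, cid), ctx)
                changed |= _step4(F, M, C, cid, fid, mid, inh[cid], trans, ctx)
        for iid in sub.members:
            changed |= _rule13(states[iid])
        if not changed:
            break
    else:  # pragma: no cover - termination is monotone in set bits
        log.warning("preprocessing sweep cap reached for family %s", sub.family)
    return PrepResult(sub=sub, states=states, inh=inh, trans=trans)
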
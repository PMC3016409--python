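"""Enumeration of Mendelian-consistent haplotype configurations.

Haplotypes over ``n`` loci are packed into Python ints: bit ``i`` is 1 when
the allele at locus ``i`` is the minor allele "2".  A *configuration* of a
substructure assigns an ordered haplotype pair to every member such that
each offspring receives one haplotype from each parent.

Internally a configuration is stored as an *event*: one ordered (or, for
label-symmetric founders, canonical sorted) haplotype pair per member plus
the (maternal, paternal) orientation of every offspring, compiled into
arrays suitable for the EM step.  Genotype elimination is integrated into
construction: partial configurations incompatible with any member's
genotypes are discarded as the enumeration extends offspring by offspring.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model import MendelianInconsistencyError
from .phaseprep import FATHER, MOTHER, PhaseState, PrepResult, SubStructure

Pair = tuple[int, int]

#: default cap on partial configurations during enumeration
DEFAULT_CAP = 5_000_000


class ConfigSpaceError(RuntimeError):
    """Enumeration exceeded the configuration cap.

    Raise the genotyping threshold (or shorten partitions) to shrink the
    state space for this substructure.
    """


def hap_to_str(h: int, n: int) -> str:
    return "".join("2" if (h >> i) & 1 else "1" for i in range(n))


def str_to_hap(s: str) -> int:
    h = 0
    for i, ch in enumerate(s):
        if ch == "2":
            h |= 1 << i
        elif ch != "1":
            raise ValueError(f"bad allele character {ch!r}")
    return h


def genotype_masks(genotypes: np.ndarray, loci: Sequence[int] | None = None) -> tuple[int, int, int]:
    """Pack genotypes into (hom-major, hom-minor, het) bit masks over ``loci``."""
    g = genotypes if loci is None else genotypes[list(loci)]
    hom1 = hom2 = het = 0
    for i, (a1, a2) in enumerate(g):
        if a1 == 0 or a2 == 0:
            continue
        if a1 == a2:
            if a1 == 1:
                hom1 |= 1 << i
            else:
                hom2 |= 1 << i
        else:
            het |= 1 << i
    return hom1, hom2, het


def pair_consistent(h0: int, h1: int, masks: tuple[int, int, int]) -> bool:
    """Does the ordered pair reproduce the genotypes encoded in ``masks``?"""
    hom1, hom2, het = masks
    if (h0 | h1) & hom1:
        return False
    if (h0 & hom2) != hom2 or (h1 & hom2) != hom2:
        return False
    return ((h0 ^ h1) & het) == het


# ---------------------------------------------------------------------------
# per-individual expansion
# ---------------------------------------------------------------------------

def individual_pairs(state: PhaseState, cap: int = DEFAULT_CAP) -> list[Pair]:
    """All ordered haplotype pairs consistent with a post-preprocessing state.

    Expansion covers every locus the deduction rules left open: unphased
    heterozygous loci contribute the two phase orders, fully missing loci all
    four ordered allele pairs, half-resolved missing loci the two values of
    the free allele.
    """
    pairs: list[Pair] = [(0, 0)]
    for i in range(state.n):
        bit = 1 << i
        s0, s1 = bool(state.hset[0, i]), bool(state.hset[1, i])
        if s0 and s1:
            opts = [(int(state.val[0, i]), int(state.val[1, i]))]
        elif state.unphased[i]:
            opts = [(0, 1), (1, 0)]
        elif s0 and not s1:
            v = int(state.val[0, i])
            opts = [(v, 0), (v, 1)]
        elif s1 and not s0:
            v = int(state.val[1, i])
            opts = [(0, v), (1, v)]
        else:
            opts = [(0, 0), (0, 1), (1, 0), (1, 1)]
        if len(opts) == 1:
            b0, b1 = opts[0]
            if b0 or b1:
                pairs = [(h0 | (bit * b0), h1 | (bit * b1)) for h0, h1 in pairs]
            continue
        new: list[Pair] = []
        for h0, h1 in pairs:
            for b0, b1 in opts:
                new.append((h0 | (bit * b0), h1 | (bit * b1)))
            if len(new) > cap:
                raise ConfigSpaceError(
                    f"individual haplotype-pair expansion exceeded cap {cap}"
                )
        pairs = new
    return pairs


def canonical_pairs(pairs: Sequence[Pair]) -> list[Pair]:
    """Deduplicate to unordered canonical (sorted) pairs, preserving order."""
    seen: set[Pair] = set()
    out: list[Pair] = []
    for h0, h1 in pairs:
        key = (h0, h1) if h0 <= h1 else (h1, h0)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# compiled substructure configurations
# ---------------------------------------------------------------------------

@dataclass
class SubConfigs:
    """All configurations of one substructure, compiled for the EM step.

    ``member_pairs[e, m]`` is the ordered pair of member ``m`` in event
    ``e``: (maternal, paternal) for offspring, label/canonical order for
    founders.  ``logmult[e]`` carries the Hardy-Weinberg multiplicity
    ``log(2)`` per unequal founder pair.  ``founder_cols`` indexes the
    founder members within ``members``.
    """

    family: str
    members: list[str]
    founder_cols: np.ndarray
    child_parent: dict[int, tuple[int, int]]   # child col -> (mother col, father col)
    member_pairs: np.ndarray                   # (E, M, 2) int64
    logmult: np.ndarray                        # (E,) float64
    n_children: int
    # shared memo for the canonical-configuration reduction (one box per
    # compiled array set, shared across rebound copies)
    canon_box: list = None  # type: ignore[assignment]

    @property
    def n_events(self) -> int:
        return self.member_pairs.shape[0]

    def founder_haps(self) -> np.ndarray:
        """(E, 2F) founder haplotype values per event."""
        return self.member_pairs[:, self.founder_cols, :].reshape(self.n_events, -1)

    def canonical(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique canonical configs, event -> config index).

        Canonical form sorts founder pairs (their internal order is gauge)
        and keeps offspring pairs in (maternal, paternal) orientation.
        """
        if self.canon_box is None:
            self.canon_box = []
        if not self.canon_box:
            canon = self.member_pairs.copy()
            if len(self.founder_cols):
                canon[:, self.founder_cols, :] = np.sort(
                    canon[:, self.founder_cols, :], axis=2
                )
            flat = canon.reshape(self.n_events, -1)
            uniq, inv = np.unique(flat, axis=0, return_inverse=True)
            self.canon_box.append((uniq.reshape(-1, len(self.members), 2), inv))
        return self.canon_box[0]


# an event during enumeration: labels (member -> label-space pair) and
# mp (offspring -> (maternal, paternal) pair)
_Event = tuple[dict, dict]


def _order_families(families: list[tuple[str, str, list[str]]]) -> list[int]:
    remaining = list(range(len(families)))
    ordered: list[int] = []
    placed: set[str] = set()
    while remaining:
        pick = None
        for idx in remaining:
            f, m, kids = families[idx]
            if not ordered or placed & set([f, m] + kids):
                pick = idx
                break
        if pick is None:
            pick = remaining[0]
        ordered.append(pick)
        f, m, kids = families[pick]
        placed.update([f, m] + kids)
        remaining.remove(pick)
    return ordered


def _enumerate_events(
    families: list[tuple[str, str, list[str]]],
    parent_pairs: Callable[[str], list[Pair]],
    child_label: Callable[[str, int, int, Optional[Pair]], list[Pair]],
    trans_sel: Callable[[str, str], Optional[int]],
    family_label: str,
    cap: int,
) -> list[_Event]:
    """Join nuclear-family configurations through linking individuals.

    ``child_label(cid, mat, pat, fixed)`` validates an offspring assignment
    and returns the offspring's admissible label-space pairs (empty list to
    reject); ``fixed`` is a label pair already bound by a previously
    processed family.  Offspring are extended in ascending order of their
    option counts so that incompatible partial configurations are discarded
    early.
    """
    events: list[_Event] = [({}, {})]
    for idx in _order_families(families):
        fid, mid, kids = families[idx]
        fam_cache: dict[tuple, list[_Event]] = {}
        new_events: list[_Event] = []
        for labels, mp in events:
            key = (labels.get(fid), labels.get(mid),
                   tuple(labels.get(k) for k in kids))
            if key not in fam_cache:
                pf_list = [labels[fid]] if fid in labels else parent_pairs(fid)
                pm_list = [labels[mid]] if mid in labels else parent_pairs(mid)
                locals_: list[_Event] = []
                for pf in pf_list:
                    for pm in pm_list:
                        # per-child admissible assignments under these parents
                        child_opts: list[tuple[str, list[tuple[Pair, Pair]]]] = []
                        dead = False
                        for cid in kids:
                            tf = trans_sel(fid, cid)
                            tm = trans_sel(mid, cid)
                            # a deduced transmission restricts the selector by
                            # *value*: when the parent's two haplotypes are
                            # equal the selectors are indistinguishable and
                            # both carry probability mass
                            ts = tuple(t for t in (0, 1) if tf is None or pf[t] == pf[tf])
                            ss = tuple(s for s in (0, 1) if tm is None or pm[s] == pm[tm])
                            fixed = labels.get(cid)
                            opts: list[tuple[Pair, Pair]] = []
                            for s in ss:
                                for t in ts:
                                    mat, pat = pm[s], pf[t]
                                    for lab in child_label(cid, mat, pat, fixed):
                                        opts.append((lab, (mat, pat)))
                            if not opts:
                                dead = True
                                break
                            child_opts.append((cid, opts))
                        if dead:
                            continue
                        child_opts.sort(key=lambda co: len(co[1]))
                        partial: list[_Event] = [({fid: pf, mid: pm}, {})]
                        for cid, opts in child_opts:
                            ext: list[_Event] = []
                            for plab, pmp in partial:
                                for lab, matpat in opts:
                                    ql = dict(plab)
                                    qm = dict(pmp)
                                    ql[cid] = lab
                                    qm[cid] = matpat
                                    ext.append((ql, qm))
                            partial = ext
                            if len(partial) > cap:
                                raise ConfigSpaceError(
                                    f"family {family_label}: configuration count "
                                    f"exceeded cap {cap}"
                                )
                        locals_.extend(partial)
                fam_cache[key] = locals_
            for dlab, dmp in fam_cache[key]:
                ml = dict(labels)
                ml.update(dlab)
                mm = dict(mp)
                mm.update(dmp)
                new_events.append((ml, mm))
            if len(new_events) > cap:
                raise ConfigSpaceError(
                    f"family {family_label}: configuration count exceeded cap {cap}"
                )
        events = new_events
        if not events:
            raise MendelianInconsistencyError(
                f"family {family_label}: no Mendelian-consistent haplotype "
                f"configuration"
            )
    return events


def _compile(
    family: str,
    members: list[str],
    families: list[tuple[str, str, list[str]]],
    events: list[_Event],
) -> SubConfigs:
    pos = {m: i for i, m in enumerate(members)}
    children = {c for _, _, kids in families for c in kids}
    founder_cols = np.array(
        [pos[m] for m in members if m not in children], dtype=np.int64
    )
    child_parent: dict[int, tuple[int, int]] = {}
    for fid, mid, kids in families:
        for c in kids:
            child_parent[pos[c]] = (pos[mid], pos[fid])
    E = len(events)
    M = len(members)
    mp = np.zeros((E, M, 2), dtype=np.int64)
    for e, (labels, matpat) in enumerate(events):
        for m in members:
            mp[e, pos[m]] = matpat[m] if m in matpat else labels[m]
    fh = mp[:, founder_cols, :]
    logmult = np.log(2.0) * (fh[:, :, 0] != fh[:, :, 1]).sum(axis=1).astype(np.float64)
    return SubConfigs(
        family=family,
        members=members,
        founder_cols=founder_cols,
        child_parent=child_parent,
        member_pairs=mp,
        logmult=logmult,
        n_children=len(children),
    )


def substructure_configs(prep: PrepResult, cap: int = DEFAULT_CAP) -> SubConfigs:
    """All Mendelian-consistent configurations for a preprocessed substructure.

    Construction seeds each nuclear family from its parent pairs and extends
    offspring by offspring (fewest possibilities first), discarding
    incompatible partial configurations; families are then joined through
    their linking individuals.
    """
    sub = prep.sub
    if sub.detached:
        iid = sub.members[0]
        pairs = canonical_pairs(individual_pairs(prep.states[iid], cap))
        events: list[_Event] = [({iid: p}, {}) for p in pairs]
        return _compile(sub.family, sub.members, [], events)

    founders = set(sub.founders)
    pair_lists: dict[str, list[Pair]] = {}
    pair_sets: dict[str, set[Pair]] = {}
    for iid in sub.members:
        st = prep.states[iid]
        pl = individual_pairs(st, cap)
        if iid in founders and not st.pinned:
            pl = canonical_pairs(pl)
        pair_lists[iid] = pl
        pair_sets[iid] = set(pl)

    inh = prep.inh

    def parent_pairs(iid: str) -> list[Pair]:
        return pair_lists[iid]

    def child_label(cid: str, mat: int, pat: int, fixed: Optional[Pair]) -> list[Pair]:
        ori = inh[cid]
        if ori == [FATHER, MOTHER]:
            candidates = [(pat, mat)]
        elif ori == [MOTHER, FATHER]:
            candidates = [(mat, pat)]
        elif fixed is not None:
            # label already bound by a previously processed family; either
            # orientation of (mat, pat) may realise it
            candidates = [c for c in ((mat, pat), (pat, mat)) if c == fixed]
        elif prep.states[cid].pinned:
            # pinned labels carry meaning (e.g. transmissions to this
            # member's own offspring), so the two labellings of one
            # (mat, pat) assignment are physically distinct configurations
            candidates = [(mat, pat)]
            if pat != mat:
                candidates.append((pat, mat))
        else:
            # orientation free and labels meaningless: both labellings
            # describe the same physical configuration, one representative
            if (mat, pat) in pair_sets[cid]:
                candidates = [(mat, pat)]
            else:
                candidates = [(pat, mat)]
        return [
            lab for lab in dict.fromkeys(candidates)
            if lab in pair_sets[cid] and (fixed is None or lab == fixed)
        ]

    def trans_sel(pid: str, cid: str) -> Optional[int]:
        return prep.trans.get((pid, cid))

    events = _enumerate_events(
        sub.families, parent_pairs, child_label, trans_sel, sub.family, cap
    )
    return _compile(sub.family, sub.members, sub.families, events)


def restricted_configs(
    sub: SubStructure,
    loci: Sequence[int],
    cand: np.ndarray,
    extra_pairs: dict[str, list[Pair]] | None = None,
    cap: int = DEFAULT_CAP,
) -> SubConfigs:
    """Configurations drawn from a restricted candidate haplotype set.

    Used during partition ligation: every member's haplotypes must come from
    ``cand`` (plus per-member ``extra_pairs`` reinstated by the fallback),
    subject to genotype consistency over ``loci``.
    """
    cand = np.asarray(cand, dtype=np.int64)
    masks = {
        iid: genotype_masks(sub.individuals[iid].genotypes, loci)
        for iid in sub.members
    }

    def cons_pairs(iid: str) -> list[Pair]:
        hom1, hom2, het = masks[iid]
        x = cand[:, None]
        y = cand[None, :]
        ok = (
            ((x | y) & hom1) == 0
        ) & (
            ((x & hom2) == hom2) & ((y & hom2) == hom2)
        ) & (
            ((x ^ y) & het) == het
        )
        iu, ju = np.nonzero(np.triu(ok))
        pairs = [(int(cand[i]), int(cand[j])) for i, j in zip(iu, ju)]
        if extra_pairs and iid in extra_pairs:
            have = set(pairs)
            for p in extra_pairs[iid]:
                key = (min(p), max(p))
                if key not in have:
                    pairs.append(key)
                    have.add(key)
        return pairs

    if sub.detached:
        iid = sub.members[0]
        pairs = cons_pairs(iid)
        if not pairs:
            raise MendelianInconsistencyError(
                f"family {sub.family}: individual {iid} has no consistent "
                f"candidate haplotype pair"
            )
        events: list[_Event] = [({iid: p}, {}) for p in pairs]
        return _compile(sub.family, sub.members, [], events)

    cache: dict[str, list[Pair]] = {}

    def parent_pairs(iid: str) -> list[Pair]:
        if iid not in cache:
            pl = cons_pairs(iid)
            if not pl:
                raise MendelianInconsistencyError(
                    f"family {sub.family}: individual {iid} has no consistent "
                    f"candidate haplotype pair"
                )
            cache[iid] = pl
        return cache[iid]

    def child_label(cid: str, mat: int, pat: int, fixed: Optional[Pair]) -> list[Pair]:
        if not pair_consistent(mat, pat, masks[cid]):
            return []
        if fixed is not None:
            if fixed != (mat, pat) and fixed != (pat, mat):
                return []
            return [fixed]
        return [(mat, pat)]

    def trans_sel(pid: str, cid: str) -> Optional[int]:
        return None

    events = _enumerate_events(
        sub.families, parent_pairs, child_label, trans_sel, sub.family, cap
    )
    return _compile(sub.family, sub.members, sub.families, events)
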
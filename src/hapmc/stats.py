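"""Association statistics on MLE-phased haplotype data.

All statistics here are Monte Carlo *test statistics*: significance is never
taken from an asymptotic distribution but from the gene-dropping null
(:mod:`hapmc.mc`), which is what keeps tests on MLE haplotypes valid.

Exposure coding is either *haploid* (the chromosome is the unit: carries the
target haplotype or not) or *diploid* (the individual is the unit: 0, 1 or 2
copies of the target).  Controls are either explicit (EC: genotyped
unaffected individuals) or pseudocontrols (PC: the two parental haplotypes
not transmitted to an affected case, replacing those parents' explicit
contribution).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .configs import Pair
from .em import PhasingResult
from .model import AFFECTED, UNAFFECTED, Individual, Resource

log = logging.getLogger(__name__)

Statistic = Literal["trend", "chisq", "odds_ratio", "tdt"]
Coding = Literal["haploid", "diploid"]
ControlMode = Literal["EC", "PC"]


@dataclass
class AnalysisSpec:
    """What to test: locus subset, target haplotype, statistic, controls."""

    statistic: Statistic = "trend"
    target: int = 0                      # haplotype encoding over the locus subset
    loci: Optional[tuple[int, ...]] = None   # None = full marker set
    coding: Coding = "diploid"
    controls: ControlMode = "EC"
    n_null: int = 1000

    def __post_init__(self) -> None:
        if self.statistic == "tdt" and self.controls == "PC":
            # the TDT draws its own comparison from transmissions
            self.controls = "EC"


def extract_subhaplotype(pair: Pair, loci: Sequence[int]) -> Pair:
    """Positional projection of both haplotypes onto ``loci``."""
    h0, h1 = pair
    p0 = p1 = 0
    for j, l in enumerate(loci):
        p0 |= ((h0 >> l) & 1) << j
        p1 |= ((h1 >> l) & 1) << j
    return (p0, p1)


# ---------------------------------------------------------------------------
# control selection and pseudocontrols
# ---------------------------------------------------------------------------

def _untransmitted(parent_pair: Pair, transmitted: int) -> int:
    a, b = parent_pair
    return b if transmitted == a else a


def generate_pseudocontrol(
    father_pair: Pair, mother_pair: Pair, case_pair: Pair, oriented: bool
) -> Optional[Pair]:
    """The two parental haplotypes not transmitted to the case.

    ``oriented`` means the case pair is known to be (maternal, paternal)
    from the phasing configuration; otherwise both orientations are tried
    and the pseudocontrol must be unambiguous.  Returns ``None`` when the
    transmission cannot be resolved (caller falls back to explicit
    controls).
    """
    orientations: Iterable[Pair]
    if oriented:
        orientations = [case_pair]
    else:
        h0, h1 = case_pair
        orientations = [(h0, h1)] if h0 == h1 else [(h0, h1), (h1, h0)]
    candidates: set[tuple[int, int]] = set()
    for cm, cp in orientations:
        if cm in mother_pair and cp in father_pair:
            pc = (_untransmitted(mother_pair, cm), _untransmitted(father_pair, cp))
            candidates.add(tuple(sorted(pc)))
    if len(candidates) != 1:
        return None
    return next(iter(candidates))


@dataclass
class Exposure:
    pair: Pair
    is_case: bool
    role: str       # "case" | "explicit" | "pseudo"


def select_controls(
    resource: Resource, phasing: PhasingResult, mode: ControlMode
) -> list[Exposure]:
    """Cases plus controls under the requested mode.

    Cases are all affected phased individuals in both modes.  EC takes every
    unaffected phased individual as a control.  PC replaces, for each case
    with both parents phased and unaffected, the two parents' explicit
    contributions by one pseudocontrol; unaffected individuals not consumed
    this way remain explicit controls.  A case whose transmissions cannot be
    resolved from the phasing keeps its parents as explicit controls
    (logged).
    """
    mle = phasing.mle
    oriented = phasing.oriented
    out: list[Exposure] = []
    consumed: set[tuple[str, str]] = set()
    pseudos: list[Exposure] = []

    def phased(ind: Individual) -> bool:
        return (ind.family, ind.iid) in mle

    if mode == "PC":
        for ped in resource.pedigrees:
            for ind in ped:
                if ind.affection != AFFECTED or not phased(ind) or ind.is_founder:
                    continue
                fa = ped.members.get(ind.father)   # type: ignore[arg-type]
                mo = ped.members.get(ind.mother)   # type: ignore[arg-type]
                if fa is None or mo is None:
                    continue
                if fa.affection != UNAFFECTED or mo.affection != UNAFFECTED:
                    continue
                if not (phased(fa) and phased(mo)):
                    continue
                pc = generate_pseudocontrol(
                    mle[(ped.family, fa.iid)],
                    mle[(ped.family, mo.iid)],
                    mle[(ped.family, ind.iid)],
                    oriented=(ped.family, ind.iid) in oriented,
                )
                if pc is None:
                    log.info(
                        "pseudocontrol unresolved for case %s:%s; parents kept "
                        "as explicit controls", ped.family, ind.iid,
                    )
                    continue
                pseudos.append(Exposure(pair=pc, is_case=False, role="pseudo"))
                consumed.add((ped.family, fa.iid))
                consumed.add((ped.family, mo.iid))

    for ind in resource.individuals():
        key = (ind.family, ind.iid)
        if not phased(ind):
            continue
        if ind.affection == AFFECTED:
            out.append(Exposure(pair=mle[key], is_case=True, role="case"))
        elif ind.affection == UNAFFECTED and key not in consumed:
            out.append(Exposure(pair=mle[key], is_case=False, role="explicit"))
    out.extend(pseudos)
    return out


# ---------------------------------------------------------------------------
# exposure tables and statistics
# ---------------------------------------------------------------------------

def diploid_table(exposures: Sequence[Exposure], target: int) -> np.ndarray:
    """2x3 counts: (case, control) x copies of the target haplotype."""
    t = np.zeros((2, 3), dtype=np.int64)
    for e in exposures:
        copies = int(e.pair[0] == target) + int(e.pair[1] == target)
        t[0 if e.is_case else 1, copies] += 1
    return t


def haploid_table(exposures: Sequence[Exposure], target: int) -> np.ndarray:
    """2x2 counts: (case, control) chromosomes x (target, other)."""
    t = np.zeros((2, 2), dtype=np.int64)
    for e in exposures:
        for h in e.pair:
            t[0 if e.is_case else 1, 0 if h == target else 1] += 1
    return t


def trend_test(table: np.ndarray, scores: Sequence[float] = (0.0, 1.0, 2.0)) -> float:
    """Cochran-Armitage test for trend (1 df chi-square form)."""
    table = np.asarray(table, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    n = table.sum(axis=0)
    r = table[0]
    N = table.sum()
    R = r.sum()
    if N == 0 or R == 0 or R == N:
        log.warning("trend test degenerate: no cases or no controls")
        return 0.0
    num = float(np.sum(s * (r - n * R / N)))
    var_s = float(np.sum(s * s * n) - np.sum(s * n) ** 2 / N)
    denom = R * (1.0 - R / N) * var_s
    if denom <= 0.0:
        log.warning("trend test degenerate: zero score variance (monomorphic)")
        return 0.0
    return N * num * num / denom


def chi_square(table: np.ndarray) -> float:
    """Pearson chi-square (1 df) for a 2x2 table."""
    table = np.asarray(table, dtype=np.float64)
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        log.warning("chi-square degenerate: empty margin")
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def odds_ratio(table: np.ndarray) -> float:
    """Odds ratio ad/bc with Haldane 0.5 correction when any cell is zero."""
    table = np.asarray(table, dtype=np.float64)
    if (table == 0).any():
        log.info("odds ratio: zero cell, applying Haldane correction")
        table = table + 0.5
    a, b = table[0]
    c, d = table[1]
    return float((a * d) / (b * c))


def _resolve_orientation(
    case_pair: Pair, father_pair: Pair, mother_pair: Pair, oriented: bool
) -> Optional[Pair]:
    """(maternal, paternal) orientation of a case pair, or None if ambiguous."""
    if oriented:
        return case_pair
    h0, h1 = case_pair
    cands = set()
    for cm, cp in ((h0, h1), (h1, h0)):
        if cm in mother_pair and cp in father_pair:
            cands.add((cm, cp))
    if len(cands) != 1:
        return None
    return next(iter(cands))


def tdt(
    resource: Resource,
    phasing: PhasingResult,
    target: int,
    loci: Optional[Sequence[int]] = None,
) -> tuple[float, int, int]:
    """Transmission/disequilibrium statistic ``(b - c)^2 / (b + c)``.

    ``b`` counts transmissions of the target from informative parents
    (exactly one of the parent's two haplotypes is the target) to affected
    offspring, ``c`` non-transmissions; each parent / affected-offspring
    pair contributes once.  Transmissions are read from the phasing
    configuration; pairs whose transmission cannot be resolved are skipped.
    """
    mle = phasing.mle
    oriented = phasing.oriented
    b = c = 0
    for ped in resource.pedigrees:
        for ind in ped:
            if ind.affection != AFFECTED or ind.is_founder:
                continue
            key = (ped.family, ind.iid)
            if key not in mle:
                continue
            fa_key = (ped.family, ind.father)
            mo_key = (ped.family, ind.mother)
            if fa_key not in mle or mo_key not in mle:
                continue
            res = _resolve_orientation(
                mle[key], mle[fa_key], mle[mo_key], key in oriented
            )
            if res is None:
                log.info("TDT transmission unresolved for %s:%s; skipped",
                         ped.family, ind.iid)
                continue
            cm, cp = res
            for ppair, transmitted in ((mle[mo_key], cm), (mle[fa_key], cp)):
                if loci is not None:
                    ppair = extract_subhaplotype(ppair, loci)
                    transmitted = extract_subhaplotype((transmitted, 0), loci)[0]
                n_t = int(ppair[0] == target) + int(ppair[1] == target)
                if n_t != 1:
                    continue  # uninformative parent
                if transmitted == target:
                    b += 1
                else:
                    c += 1
    if b + c == 0:
        log.warning("TDT degenerate: no informative transmissions")
        return 0.0, b, c
    return float((b - c) ** 2 / (b + c)), b, c


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def compute_statistic(
    resource: Resource, phasing: PhasingResult, spec: AnalysisSpec
) -> float:
    """Observed (or null) value of the configured statistic."""
    loci = spec.loci
    if spec.statistic == "tdt":
        stat, _, _ = tdt(resource, phasing, spec.target, loci)
        return stat
    exposures = select_controls(resource, phasing, spec.controls)
    if loci is not None:
        exposures = [
            Exposure(pair=extract_subhaplotype(e.pair, loci), is_case=e.is_case, role=e.role)
            for e in exposures
        ]
    if spec.statistic == "trend":
        return trend_test(diploid_table(exposures, spec.target))
    if spec.coding == "diploid":
        # carrier-collapsed 2x2 for diploid chisq / OR
        t3 = diploid_table(exposures, spec.target)
        table = np.stack([t3[:, 0], t3[:, 1] + t3[:, 2]], axis=1)[:, ::-1]
    else:
        table = haploid_table(exposures, spec.target)
    if spec.statistic == "chisq":
        return chi_square(table)
    if spec.statistic == "odds_ratio":
        return odds_ratio(table)
    raise ValueError(f"unknown statistic {spec.statistic!r}")
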
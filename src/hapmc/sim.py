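"""Synthetic study-design generator for validity and power experiments.

Founder haplotypes are drawn from a population frequency table; a hidden
disease SNP (dSNP) is assigned per founder haplotype so that the indicator
of the chosen *risk haplotype* and the dSNP risk allele have a prescribed
squared correlation r² across chromosomes; haplotypes (with their dSNP
allele, zero recombination) are gene-dropped to descendants; affection is
drawn from a multiplicative penetrance model (baseline *sporadic rate*
times GRR per dSNP risk allele); the design's ascertainment rule is applied
and the dSNP is stripped, leaving only the marker genotypes plus a hidden
truth record for accuracy scoring.

The packaged default pool is a synthetic 15-haplotype table over 15
biallelic SNPs with low pairwise marker r² (mimicking a tagging-SNP panel
in a non-recombining region); it contains haplotypes at frequencies 0.17,
0.10, 0.07 and 0.04 that serve as risk haplotypes, and all 15 haplotypes
remain distinct when projected onto the first five loci, so analyses may be
scaled down in marker count without changing q.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Literal, Optional

import numpy as np

from .configs import str_to_hap
from .em import FrequencyTable
from .model import AFFECTED, UNAFFECTED, Individual, Pedigree, Resource, Marker

log = logging.getLogger(__name__)

# packaged synthetic haplotype pool (allele strings, minor allele = "2")
_POOL_HAPS = [
    "121112212111121",
    "112121111211111",
    "221221111112121",
    "112212122212112",
    "111112221112211",
    "112222122121122",
    "122211222121111",
    "112111221121122",
    "121221112121122",
    "221121211111112",
    "212212112111211",
    "211221211122211",
    "121121121122122",
    "122222221222112",
    "212121211111111",
]
_POOL_FREQS = [
    0.17, 0.12, 0.11, 0.10, 0.09, 0.08, 0.07, 0.06,
    0.05, 0.04, 0.03, 0.025, 0.02, 0.02, 0.015,
]
#: packaged risk haplotypes by frequency
RISK_INDEX = {0.17: 0, 0.10: 3, 0.07: 6, 0.04: 9}


def default_pool(n_markers: int = 15) -> FrequencyTable:
    """The packaged haplotype pool, optionally projected onto a marker prefix."""
    if not 2 <= n_markers <= 15:
        raise ValueError("packaged pool supports 2..15 markers")
    freqs: dict[int, float] = {}
    for s, f in zip(_POOL_HAPS, _POOL_FREQS):
        h = str_to_hap(s[:n_markers])
        freqs[h] = freqs.get(h, 0.0) + f
    return FrequencyTable(n_loci=n_markers, freqs=freqs)


def risk_haplotype(q: float, n_markers: int = 15) -> int:
    """The packaged risk haplotype at frequency ``q`` (0.17/0.10/0.07/0.04)."""
    if q not in RISK_INDEX:
        raise ValueError(f"no packaged risk haplotype at frequency {q}")
    return str_to_hap(_POOL_HAPS[RISK_INDEX[q]][:n_markers])


def default_markers(n_markers: int = 15) -> list[Marker]:
    return [Marker(id=f"M{i + 1}", index=i) for i in range(n_markers)]


@dataclass
class DiseaseModel:
    """Risk haplotype, hidden-dSNP LD, and multiplicative penetrance.

    ``grr=1.0`` is the null model (affection independent of genotype, the
    sporadic rate alone).  The dSNP marginal risk-allele frequency is set
    equal to ``q``, the unique symmetric choice that makes r the sole LD
    parameter.
    """

    risk_hap: int
    q: float
    grr: float
    r2: float = 0.8
    sporadic: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must lie in (0, 1]")
        if self.grr < 1.0:
            raise ValueError("GRR must be >= 1")
        if self.sporadic * self.grr ** 2 > 1.0:
            raise ValueError("infeasible model: GRR^2 * sporadic rate exceeds 1")

    @property
    def is_null(self) -> bool:
        return self.grr == 1.0

    def penetrance(self, g: int) -> float:
        return min(1.0, self.sporadic * self.grr ** g)


def dsnp_conditionals(model: DiseaseModel) -> tuple[float, float]:
    """P(dSNP risk allele | risk haplotype) and P(... | any other haplotype).

    With the dSNP allele frequency equal to q, the covariance needed for a
    squared correlation r² is D = sqrt(r²) q (1 - q), giving
    ``p1 = q + sqrt(r²)(1 - q)`` and ``p0 = q (1 - sqrt(r²))``; the marginal
    allele frequency q is preserved.
    """
    r = math.sqrt(model.r2)
    p1 = model.q + r * (1.0 - model.q)
    p0 = model.q * (1.0 - r)
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise ValueError("infeasible LD model: conditional probability outside [0, 1]")
    return p1, p0


Design = Literal["CC", "TRIO", "ASP", "LP1", "LP2"]


@dataclass
class DesignSpec:
    """A study design with its ascertainment rule and sample-size targets.

    Defaults are the standard full-size designs: 500 cases + 500 controls
    (CC), 500 case-parent trios, 250 affected-sib-pair families, and large
    five-generation pedigrees ascertained for at least 14 cases with family
    controls sampled at 2x the case count (LP1) or 1x (LP2), composed of
    80% close relatives of a case (50% parents, 30% siblings) and 20%
    beyond first degree.
    """

    design: Design
    n_cases: int = 500
    n_controls: int = 500
    n_families: int = 500
    missing_rate: float = 0.0
    min_lp_cases: int = 14
    max_attempts: int = 2_000_000

    @classmethod
    def cc(cls, n_cases: int = 500, n_controls: int = 500, **kw) -> "DesignSpec":
        return cls(design="CC", n_cases=n_cases, n_controls=n_controls, **kw)

    @classmethod
    def trio(cls, n_families: int = 500, **kw) -> "DesignSpec":
        return cls(design="TRIO", n_families=n_families, **kw)

    @classmethod
    def asp(cls, n_families: int = 250, **kw) -> "DesignSpec":
        return cls(design="ASP", n_families=n_families, **kw)

    @classmethod
    def lp(cls, which: int = 1, n_cases: int = 500, **kw) -> "DesignSpec":
        return cls(design=f"LP{which}", n_cases=n_cases, **kw)  # type: ignore[arg-type]


#: hidden truth: (family, iid) -> ((maternal hap, paternal hap), (maternal dSNP, paternal dSNP))
Truth = dict[tuple[str, str], tuple[tuple[int, int], tuple[int, int]]]


class _Dropper:
    """Draws founder chromosomes (haplotype + linked dSNP allele) and drops them."""

    def __init__(self, model: DiseaseModel, pool: FrequencyTable, rng: np.random.Generator):
        if pool[model.risk_hap] <= 0.0:
            raise ValueError("risk haplotype absent from the haplotype pool")
        self.model = model
        self.rng = rng
        self.haps = pool.haplotypes()
        p = np.array([pool.freqs[int(h)] for h in self.haps])
        self.p = p / p.sum()
        self.p1, self.p0 = dsnp_conditionals(model)

    def founder(self) -> tuple[tuple[int, int], tuple[int, int]]:
        hs = self.rng.choice(self.haps, size=2, p=self.p)
        ds = tuple(
            int(self.rng.random() < (self.p1 if int(h) == self.model.risk_hap else self.p0))
            for h in hs
        )
        return (int(hs[0]), int(hs[1])), ds  # type: ignore[return-value]

    def child(self, mother, father) -> tuple[tuple[int, int], tuple[int, int]]:
        (mh, md), (fh, fd) = mother, father
        i = int(self.rng.integers(2))
        j = int(self.rng.integers(2))
        return (mh[i], fh[j]), (md[i], fd[j])

    def affection(self, dsnp: tuple[int, int]) -> int:
        g = dsnp[0] + dsnp[1]
        return AFFECTED if self.rng.random() < self.model.penetrance(g) else UNAFFECTED


def _genotypes(haps: tuple[int, int], n: int) -> np.ndarray:
    bits = np.arange(n)
    a = ((haps[0] >> bits) & 1) + 1
    b = ((haps[1] >> bits) & 1) + 1
    return np.sort(np.stack([a, b], axis=1), axis=1).astype(np.int8)


def _missing(n: int) -> np.ndarray:
    return np.zeros((n, 2), dtype=np.int8)


def _simulate_cc(spec, model, pool, rng, n):
    d = _Dropper(model, pool, rng)
    cases: list[Individual] = []
    controls: list[Individual] = []
    truth: Truth = {}
    for _ in range(spec.max_attempts):
        if len(cases) >= spec.n_cases and len(controls) >= spec.n_controls:
            break
        haps, ds = d.founder()
        aff = d.affection(ds)
        bucket = cases if aff == AFFECTED else controls
        want = spec.n_cases if aff == AFFECTED else spec.n_controls
        if len(bucket) >= want:
            continue
        fam = f"{'A' if aff == AFFECTED else 'U'}{len(bucket) + 1}"
        ind = Individual(
            family=fam, iid="1", father=None, mother=None,
            sex=1 + int(rng.integers(2)), affection=aff, genotypes=_genotypes(haps, n),
        )
        bucket.append(ind)
        truth[(fam, "1")] = (haps, ds)
    else:
        raise RuntimeError("CC ascertainment failed: attempt budget exhausted")
    return Resource(markers=default_markers(n), singletons=cases + controls), truth


def _nuclear(spec, model, pool, rng, n, sibs: int):
    """TRIO (sibs=1, affected child) and ASP (sibs=2, both affected)."""
    d = _Dropper(model, pool, rng)
    peds: list[Pedigree] = []
    truth: Truth = {}
    attempts = 0
    while len(peds) < spec.n_families:
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError("nuclear-family ascertainment failed: attempt budget exhausted")
        fa = d.founder()
        mo = d.founder()
        kids = [d.child(mo, fa) for _ in range(sibs)]
        affs = [d.affection(ds) for _, ds in kids]
        if any(a != AFFECTED for a in affs):
            continue
        fam = f"{'T' if sibs == 1 else 'S'}{len(peds) + 1}"
        members: dict[str, Individual] = {}
        members["F"] = Individual(
            family=fam, iid="F", father=None, mother=None, sex=1,
            affection=d.affection(fa[1]), genotypes=_genotypes(fa[0], n),
        )
        members["M"] = Individual(
            family=fam, iid="M", father=None, mother=None, sex=2,
            affection=d.affection(mo[1]), genotypes=_genotypes(mo[0], n),
        )
        truth[(fam, "F")] = fa
        truth[(fam, "M")] = mo
        for k, (haps, ds) in enumerate(kids, 1):
            cid = f"C{k}"
            members[cid] = Individual(
                family=fam, iid=cid, father="F", mother="M",
                sex=1 + int(rng.integers(2)), affection=AFFECTED,
                genotypes=_genotypes(haps, n),
            )
            truth[(fam, cid)] = (haps, ds)
        peds.append(Pedigree(family=fam, members=members))
    return Resource(markers=default_markers(n), pedigrees=peds), truth


# five-generation template: (number of children per couple, how many of them marry in)
_LP_SHAPE = [(5, 4), (5, 3), (4, 2), (3, 0)]


def _lp_structure() -> tuple[list[tuple[str, Optional[str], Optional[str], int]], dict[str, int]]:
    """Member list (iid, father, mother, generation) for the LP template."""
    members: list[tuple[str, Optional[str], Optional[str], int]] = []
    gen: dict[str, int] = {}
    counter = [0]

    def new(gen_no: int, father=None, mother=None) -> str:
        counter[0] += 1
        iid = str(counter[0])
        members.append((iid, father, mother, gen_no))
        gen[iid] = gen_no
        return iid

    g1f = new(1)
    g1m = new(1)
    couples = [(g1f, g1m)]
    for level, (n_kids, n_marry) in enumerate(_LP_SHAPE, start=1):
        next_couples = []
        for (fa, mo) in couples:
            kids = [new(level + 1, fa, mo) for _ in range(n_kids)]
            for kid in kids[:n_marry]:
                spouse = new(level + 1)
                next_couples.append((kid, spouse))
        couples = next_couples
    return members, gen


def _simulate_lp(spec, model, pool, rng, n, cluster_model: Optional[DiseaseModel]):
    """Large five-generation high-risk pedigrees.

    Phenotypes come from the penetrance model (or, for null simulations,
    from a separate clustering model whose genotypes are then re-dropped
    independently).  A pedigree is kept when at least ``min_lp_cases``
    sampled-generation members are affected.  The top two generations are
    always fully missing; family controls are sampled to ``n_controls_per``
    times the case count with the 80/20 close/distant composition.
    """
    control_ratio = 2.0 if spec.design == "LP1" else 1.0
    pheno_model = cluster_model if (model.is_null and cluster_model is not None) else model
    peds: list[Pedigree] = []
    truth: Truth = {}
    total_cases = 0
    attempts = 0
    fam_no = 0
    struct, gen = _lp_structure()
    child_of: dict[str, tuple[Optional[str], Optional[str]]] = {
        iid: (fa, mo) for iid, fa, mo, _ in struct
    }
    while total_cases < spec.n_cases:
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError("LP ascertainment failed: attempt budget exhausted")
        dp = _Dropper(pheno_model, pool, rng)
        chrom: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
        aff: dict[str, int] = {}
        for iid, fa, mo, _ in struct:
            chrom[iid] = dp.founder() if fa is None else dp.child(chrom[mo], chrom[fa])
            aff[iid] = dp.affection(chrom[iid][1])
        sampled_gen = {iid for iid in gen if gen[iid] >= 3}
        case_ids = [iid for iid in sampled_gen if aff[iid] == AFFECTED]
        if len(case_ids) < spec.min_lp_cases:
            continue
        if model.is_null:
            # genotypes independent of the clustered phenotype
            dg = _Dropper(model, pool, rng)
            chrom = {}
            for iid, fa, mo, _ in struct:
                chrom[iid] = dg.founder() if fa is None else dg.child(chrom[mo], chrom[fa])

        # control sampling among unaffected sampled-generation members
        unaff = [iid for iid in sampled_gen if aff[iid] == UNAFFECTED]
        case_set = set(case_ids)
        parents_of_case: set[str] = set()
        sibs_of_case: set[str] = set()
        for cid in case_ids:
            fa, mo = child_of[cid]
            for p in (fa, mo):
                if p is not None:
                    parents_of_case.add(p)
        for iid in unaff:
            fa, mo = child_of[iid]
            if fa is None:
                continue
            for cid in case_ids:
                if child_of[cid] == (fa, mo):
                    sibs_of_case.add(iid)
                    break
        first_degree = parents_of_case | sibs_of_case
        for iid in unaff:  # children of cases are first degree too
            if child_of[iid][0] in case_set or child_of[iid][1] in case_set:
                first_degree.add(iid)

        def pick(items: list[str], k: int) -> list[str]:
            if k <= 0 or not items:
                return []
            return [str(x) for x in rng.choice(items, size=min(k, len(items)), replace=False)]

        pool_parents = sorted(set(unaff) & parents_of_case)
        pool_sibs = sorted((set(unaff) & sibs_of_case) - parents_of_case)
        pool_far = sorted(set(unaff) - first_degree)
        target = int(round(control_ratio * len(case_ids)))
        controls = pick(pool_parents, int(round(0.5 * target)))
        controls += pick(pool_sibs, int(round(0.3 * target)))
        controls += pick(pool_far, target - len(controls))
        if len(controls) < target:
            rest = sorted(set(unaff) - set(controls))
            controls += pick(rest, target - len(controls))

        fam_no += 1
        fam = f"L{fam_no}"
        genotyped = case_set | set(controls)
        members: dict[str, Individual] = {}
        for iid, fa, mo, g in struct:
            typed = iid in genotyped and g >= 3
            members[iid] = Individual(
                family=fam, iid=iid, father=fa, mother=mo,
                sex=1 + int(rng.integers(2)),
                affection=0 if g <= 2 else aff[iid],
                genotypes=_genotypes(chrom[iid][0], n) if typed else _missing(n),
            )
            truth[(fam, iid)] = chrom[iid]
        peds.append(Pedigree(family=fam, members=members))
        total_cases += len(case_ids)
    return Resource(markers=default_markers(n), pedigrees=peds), truth


#: clustering model used for null large-pedigree phenotype simulation
DEFAULT_LP_CLUSTER = dict(grr=1.5, q=0.10)


def simulate_design(
    spec: DesignSpec,
    model: DiseaseModel,
    pool: FrequencyTable,
    rng: np.random.Generator,
    cluster_model: Optional[DiseaseModel] = None,
) -> tuple[Resource, Truth]:
    """Generate one replicate of a study design.

    Returns the resource (marker genotypes, affection; dSNP stripped) plus
    the hidden truth (true ordered haplotypes and dSNP alleles).  For null
    LP simulations a clustering model (default GRR 1.5 at q 0.10) shapes
    the phenotypes while genotypes are dropped independently.
    """
    n = pool.n_loci
    if spec.design == "CC":
        res, truth = _simulate_cc(spec, model, pool, rng, n)
    elif spec.design == "TRIO":
        res, truth = _nuclear(spec, model, pool, rng, n, sibs=1)
    elif spec.design == "ASP":
        res, truth = _nuclear(spec, model, pool, rng, n, sibs=2)
    elif spec.design in ("LP1", "LP2"):
        if model.is_null and cluster_model is None:
            cluster_model = DiseaseModel(
                risk_hap=risk_haplotype(DEFAULT_LP_CLUSTER["q"], n),
                q=DEFAULT_LP_CLUSTER["q"],
                grr=DEFAULT_LP_CLUSTER["grr"],
                r2=model.r2,
                sporadic=model.sporadic,
            )
        res, truth = _simulate_lp(spec, model, pool, rng, n, cluster_model)
    else:
        raise ValueError(f"unknown design {spec.design!r}")
    if spec.missing_rate > 0.0:
        res = inject_missing(res, spec.missing_rate, rng)
    return res, truth


def inject_missing(resource: Resource, rate: float, rng: np.random.Generator) -> Resource:
    """Set each typed individual's genotypes missing independently at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return resource

    def knock(ind: Individual) -> Individual:
        if not np.any(ind.genotypes != 0):
            return ind  # untyped individuals unchanged
        mask = rng.random(ind.n_markers) < rate
        if not mask.any():
            return ind
        g = ind.genotypes.copy()
        g[mask] = 0
        return dc_replace(ind, genotypes=g)

    peds = [
        Pedigree(family=p.family, members={i.iid: knock(i) for i in p}, check=False)
        for p in resource.pedigrees
    ]
    singles = [knock(s) for s in resource.singletons]
    return Resource(markers=resource.markers, pedigrees=peds, singletons=singles,
                    check=False)


def merge_resources(a: Resource, b: Resource, prefix_b: str = "X") -> Resource:
    """Join two resources over the same marker panel into one mixed resource."""
    if len(a.markers) != len(b.markers):
        raise ValueError("resources have different marker panels")

    def rename(ind: Individual, fam: str) -> Individual:
        return dc_replace(ind, family=fam)

    peds = list(a.pedigrees)
    singles = list(a.singletons)
    for p in b.pedigrees:
        fam = prefix_b + p.family
        peds.append(Pedigree(
            family=fam, members={i.iid: rename(i, fam) for i in p}
        ))
    for s in b.singletons:
        singles.append(rename(s, prefix_b + s.family))
    return Resource(markers=a.markers, pedigrees=peds, singletons=singles)


def phasing_accuracy(mle: dict, truth: Truth) -> float:
    """Fraction of phased individuals with both haplotypes correct.

    Pairs are compared unordered; imputed positions count, so a wrong
    imputation at a missing locus fails the individual.
    """
    n_ok = 0
    n_tot = 0
    for key, pair in mle.items():
        if key not in truth:
            continue
        t = truth[key][0]
        n_tot += 1
        if tuple(sorted(pair)) == tuple(sorted(t)):
            n_ok += 1
    if n_tot == 0:
        raise ValueError("no phased individual overlaps the truth record")
    return n_ok / n_tot
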
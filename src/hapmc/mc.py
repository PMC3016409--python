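"""Gene-dropping Monte Carlo procedure for empirical significance.

Null genotype configurations are simulated under no association: founders
and independent individuals draw haplotype pairs from the frequencies
estimated on the *observed* data, descendants receive one haplotype from
each parent by Mendelian gene-dropping; the observed missing-data mask is
then imposed and phase is erased.  Each null is re-phased with exactly the
same pipeline and settings as the observed data — matching the full phasing
process between observed and null data is what makes tests on MLE
haplotypes valid — and the statistic of interest is recomputed.  The
empirical p-value uses the add-one Monte Carlo convention.

The full pedigree structure (including members excluded from phasing) is
always used for the gene drop, so familial correlation is fully accounted
for in the null distribution.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .em import (
    EMDegeneracyError,
    EnumerationCache,
    FrequencyTable,
    PhasingSettings,
    phase_resource,
    rebind_substructures,
)
from .phaseprep import split_resource
from .configs import ConfigSpaceError
from .model import Individual, MendelianInconsistencyError, Pedigree, Resource
from .stats import AnalysisSpec, compute_statistic

log = logging.getLogger(__name__)


@dataclass
class StatResult:
    """Observed statistic, its null sample, and the empirical p-value."""

    statistic: str
    observed: float
    nulls: np.ndarray
    p: float
    seed: int
    n_null: int
    n_redrawn: int = 0


def empirical_p(observed: float, nulls: Sequence[float]) -> float:
    """Add-one Monte Carlo p-value ``(1 + #{null >= obs}) / (1 + n_null)``.

    Ties between null and observed values count toward the null tail
    (conservative); the result is always in ``(0, 1]``.
    """
    nulls = np.asarray(nulls, dtype=np.float64)
    if nulls.size < 1:
        raise ValueError("empirical p-value requires at least one null statistic")
    return float((1 + int(np.sum(nulls >= observed))) / (1 + nulls.size))


def threshold_code(resource: Resource, threshold: float) -> Resource:
    """Code individuals below the genotyping threshold as completely missing."""
    def code(ind: Individual) -> Individual:
        if ind.is_typed(threshold):
            return ind
        return dc_replace(ind, genotypes=np.zeros_like(ind.genotypes))

    peds = [
        Pedigree(family=p.family, members={i.iid: code(i) for i in p}, check=False)
        for p in resource.pedigrees
    ]
    singles = [code(s) for s in resource.singletons]
    return Resource(markers=resource.markers, pedigrees=peds, singletons=singles,
                    check=False)


def _pairs_to_genotypes(pairs: np.ndarray, n: int) -> np.ndarray:
    """(m, 2) haplotype ints -> (m, n, 2) sorted allele pairs (phase erased)."""
    bits = np.arange(n, dtype=np.int64)
    g = ((pairs[:, :, None] >> bits[None, None, :]) & 1) + 1
    return np.sort(g.transpose(0, 2, 1), axis=2).astype(np.int8)


def gene_drop(
    resource: Resource, freqs: FrequencyTable, rng: np.random.Generator
) -> Resource:
    """One null genotype configuration for the whole resource.

    Founders and singletons draw two haplotypes i.i.d. from ``freqs``; each
    descendant receives one haplotype from each parent uniformly.  The
    observed missing-data pattern is imposed afterwards, phenotypes are
    untouched.
    """
    if not freqs.freqs:
        raise ValueError("empty haplotype frequency table")
    n = resource.n_markers
    haps = freqs.haplotypes()
    p = np.array([freqs.freqs[int(h)] for h in haps])
    p = p / p.sum()

    n_founders = sum(len(ped.founders) for ped in resource.pedigrees)
    n_founders += len(resource.singletons)
    draws = rng.choice(haps, size=(n_founders, 2), p=p)
    di = 0

    # assign haplotype pairs to everyone, then convert genotypes in one batch
    all_inds: list[Individual] = []
    all_pairs: list[tuple[int, int]] = []
    ped_slices: list[tuple[Pedigree, int, int]] = []
    for ped in resource.pedigrees:
        pairs: dict[str, tuple[int, int]] = {}
        for ind in ped.topological_order():
            if ind.is_founder:
                pairs[ind.iid] = (int(draws[di, 0]), int(draws[di, 1]))
                di += 1
            else:
                mat = pairs[ind.mother][int(rng.integers(2))]   # type: ignore[index]
                pat = pairs[ind.father][int(rng.integers(2))]   # type: ignore[index]
                pairs[ind.iid] = (mat, pat)
        lo = len(all_inds)
        for ind in ped:
            all_inds.append(ind)
            all_pairs.append(pairs[ind.iid])
        ped_slices.append((ped, lo, len(all_inds)))
    slo = len(all_inds)
    for ind in resource.singletons:
        all_inds.append(ind)
        all_pairs.append((int(draws[di, 0]), int(draws[di, 1])))
        di += 1

    geno = _pairs_to_genotypes(np.array(all_pairs, dtype=np.int64), n)
    for i, ind in enumerate(all_inds):
        geno[i][np.any(ind.genotypes == 0, axis=1)] = 0

    new_peds = [
        Pedigree(
            family=ped.family,
            members={
                all_inds[i].iid: dc_replace(all_inds[i], genotypes=geno[i])
                for i in range(lo, hi)
            },
            check=False,
        )
        for ped, lo, hi in ped_slices
    ]
    new_singles = [
        dc_replace(all_inds[i], genotypes=geno[i]) for i in range(slo, len(all_inds))
    ]
    return Resource(markers=resource.markers, pedigrees=new_peds,
                    singletons=new_singles, check=False)


def _transform(statistic: str, value: float) -> float:
    """Map a statistic onto a one-tailed 'larger is more extreme' scale."""
    if statistic == "odds_ratio":
        return abs(math.log(value)) if value > 0 else math.inf
    return value


def run_analysis(
    resource: Resource,
    spec: AnalysisSpec,
    settings: PhasingSettings | None = None,
    seed: int = 0,
    cache: EnumerationCache | None = None,
    keep_nulls: bool = True,
) -> StatResult:
    """Full observed-plus-null pipeline for one statistic.

    Phases the observed data, computes the observed statistic, then for each
    of ``spec.n_null`` iterations gene-drops a null configuration, re-phases
    it with identical settings, and recomputes the statistic.  A null whose
    phasing fails is redrawn (logged); a redraw rate above 1% is an error.
    """
    if spec.n_null < 1:
        raise ValueError("n_null must be >= 1 to form a null distribution")
    settings = settings or PhasingSettings()
    cache = cache or EnumerationCache()
    rng = np.random.default_rng(seed)

    coded = threshold_code(resource, settings.threshold)
    subs = split_resource(coded, settings.threshold, naive=settings.naive)
    phasing = phase_resource(coded, settings, cache, subs=subs)
    observed = compute_statistic(coded, phasing, spec)

    nulls = np.empty(spec.n_null)
    redrawn = 0
    max_redraws = max(10, int(0.01 * spec.n_null) + 1)
    for i in range(spec.n_null):
        while True:
            null = gene_drop(coded, phasing.freqs, rng)
            try:
                null_phasing = phase_resource(
                    null, settings, cache, subs=rebind_substructures(subs, null)
                )
            except (MendelianInconsistencyError, EMDegeneracyError, ConfigSpaceError) as exc:
                redrawn += 1
                log.warning("null %d redrawn after phasing failure: %s", i, exc)
                if redrawn > max_redraws:
                    raise RuntimeError(
                        f"null phasing failure rate exceeded 1% ({redrawn} redraws)"
                    ) from exc
                continue
            nulls[i] = compute_statistic(null, null_phasing, spec)
            break

    obs_t = _transform(spec.statistic, observed)
    nulls_t = np.array([_transform(spec.statistic, v) for v in nulls])
    return StatResult(
        statistic=spec.statistic,
        observed=observed,
        nulls=nulls if keep_nulls else np.empty(0),
        p=empirical_p(obs_t, nulls_t),
        seed=seed,
        n_null=spec.n_null,
        n_redrawn=redrawn,
    )
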
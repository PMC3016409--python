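"""EM estimation of haplotype frequencies over pedigree configurations.

The observed-data likelihood of one substructure follows the Elston-Stewart
factorisation: a sum over Mendelian-consistent configurations of founder
Hardy-Weinberg pair probabilities times per-offspring transmission
probabilities (one half per transmitting parent).  The EM alternates
configuration posteriors (E-step) with frequency updates from expected
founder haplotype counts (M-step); only founder and independent chromosomes
enter the denominator, since descendant chromosomes are copies.

For marker sets longer than one partition, a partition-ligation strategy
(PL-EM) phases overlapping windows, prunes rare haplotypes per window, and
re-estimates over ligated candidates until the full length is reached.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .configs import (
    DEFAULT_CAP,
    Pair,
    SubConfigs,
    individual_pairs,
    restricted_configs,
    substructure_configs,
)
from .model import MendelianInconsistencyError, Resource
from .phaseprep import SubStructure, load_phase_state, run_preprocessing, split_resource

log = logging.getLogger(__name__)


class EMDegeneracyError(RuntimeError):
    """All configuration priors vanished for some substructure."""


@dataclass
class FrequencyTable:
    """Population haplotype frequencies over ``n_loci`` markers."""

    n_loci: int
    freqs: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative haplotype frequency")

    def __getitem__(self, hap: int) -> float:
        return self.freqs.get(hap, 0.0)

    def items(self):
        return self.freqs.items()

    def haplotypes(self) -> np.ndarray:
        return np.array(sorted(self.freqs), dtype=np.int64)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        haps = self.haplotypes()
        p = np.array([self.freqs[int(h)] for h in haps])
        p = p / p.sum()
        return rng.choice(haps, size=size, p=p)


def config_prior(config: np.ndarray, table: SubConfigs, freqs: FrequencyTable) -> float:
    """Prior probability of one canonical configuration.

    Product over founders of the HWE pair probability (``f**2`` for equal
    haplotypes, ``2 f f'`` otherwise) times, for every offspring, the
    Mendelian transmission probability of its (maternal, paternal) pair
    given the parents' pairs.
    """
    p = 1.0
    for col in table.founder_cols:
        a, b = int(config[col, 0]), int(config[col, 1])
        fa, fb = freqs[a], freqs[b]
        p *= fa * fb * (2.0 if a != b else 1.0)
    for child, (mcol, fcol) in table.child_parent.items():
        mat, pat = int(config[child, 0]), int(config[child, 1])
        mpair = [int(config[mcol, 0]), int(config[mcol, 1])]
        fpair = [int(config[fcol, 0]), int(config[fcol, 1])]
        p *= mpair.count(mat) / 2.0
        p *= fpair.count(pat) / 2.0
    return p


# ---------------------------------------------------------------------------
# core EM over compiled configuration tables
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    freqs: FrequencyTable
    posteriors: list[np.ndarray]      # per table: event posteriors
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def em_estimate(
    tables: Sequence[SubConfigs],
    n_loci: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EMResult:
    """Run the EM across all substructures jointly.

    The E-step computes configuration posteriors under the current
    frequencies (normalised within each substructure); the M-step divides
    the posterior-weighted founder haplotype counts by the total number of
    founder/independent chromosomes.
    """
    if not tables:
        raise ValueError("no substructure configurations to estimate from")
    # flatten founder-haplotype slots across tables
    slot_hap_parts: list[np.ndarray] = []
    slot_event_parts: list[np.ndarray] = []
    logmult_parts: list[np.ndarray] = []
    seg_starts: list[int] = []
    trans_const = 0.0
    ev_off = 0
    denom = 0
    for t in tables:
        fh = t.founder_haps()
        E, S = fh.shape
        if E == 0:
            raise MendelianInconsistencyError(
                f"family {t.family}: empty configuration list"
            )
        slot_hap_parts.append(fh.ravel())
        slot_event_parts.append(np.repeat(np.arange(E, dtype=np.int64) + ev_off, S))
        logmult_parts.append(t.logmult)
        seg_starts.append(ev_off)
        trans_const += t.n_children * np.log(0.25)
        denom += S
        ev_off += E
    slot_hap_vals = np.concatenate(slot_hap_parts)
    slot_event = np.concatenate(slot_event_parts)
    logmult = np.concatenate(logmult_parts)
    NE = ev_off
    seg_starts_arr = np.array(seg_starts, dtype=np.int64)
    seg_of_event = np.zeros(NE, dtype=np.int64)
    seg_of_event[seg_starts_arr[1:]] = 1
    seg_of_event = np.cumsum(seg_of_event)

    universe, slot_hap = np.unique(slot_hap_vals, return_inverse=True)
    NH = universe.size

    f = np.full(NH, 1.0 / NH)
    trace: list[float] = []
    converged = False
    it = 0
    post = np.zeros(NE)
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            logf = np.log(f)
        slot_logf = logf[slot_hap]
        slot_logf = np.where(np.isneginf(slot_logf), -1e300, slot_logf)
        logp = np.bincount(slot_event, weights=slot_logf, minlength=NE) + logmult
        seg_max = np.maximum.reduceat(logp, seg_starts_arr)
        w = np.exp(logp - seg_max[seg_of_event])
        seg_sum = np.add.reduceat(w, seg_starts_arr)
        if np.any(seg_sum <= 0.0) or not np.all(np.isfinite(seg_sum)):
            raise EMDegeneracyError("all configuration priors vanished in a substructure")
        post = w / seg_sum[seg_of_event]
        ll = float(np.sum(np.log(seg_sum) + seg_max)) + trans_const
        trace.append(ll)
        counts = np.bincount(slot_hap, weights=post[slot_event], minlength=NH)
        f_new = counts / denom
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break

    freqs = FrequencyTable(
        n_loci=n_loci,
        freqs={int(h): float(p) for h, p in zip(universe, f / f.sum())},
    )
    posteriors: list[np.ndarray] = []
    for i, t in enumerate(tables):
        lo = seg_starts[i]
        hi = seg_starts[i + 1] if i + 1 < len(tables) else NE
        posteriors.append(post[lo:hi])
    return EMResult(
        freqs=freqs,
        posteriors=posteriors,
        loglik=trace[-1] if trace else float("-inf"),
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# MLE haplotype pairs
# ---------------------------------------------------------------------------

@dataclass
class PhasingResult:
    """Frequencies, per-individual MLE pairs and configuration posteriors."""

    n_loci: int
    freqs: FrequencyTable
    tables: list[SubConfigs]
    posteriors: list[np.ndarray]
    loglik: float
    n_iter: int
    converged: bool
    # (family, iid) -> ordered MLE pair ((maternal, paternal) for offspring,
    # canonical sorted for founders/independents)
    mle: dict[tuple[str, str], Pair] = field(default_factory=dict)
    # (family, iid) -> posterior probability of the chosen configuration
    mle_posterior: dict[tuple[str, str], float] = field(default_factory=dict)
    # per table: the chosen canonical configuration array
    best_configs: list[np.ndarray] = field(default_factory=list)
    # individuals whose MLE pair is (maternal, paternal) oriented
    oriented: set[tuple[str, str]] = field(default_factory=set)


def mle_pairs(tables: Sequence[SubConfigs], posteriors: Sequence[np.ndarray]) -> tuple[
    dict[tuple[str, str], Pair], dict[tuple[str, str], float], list[np.ndarray],
    set[tuple[str, str]],
]:
    """Maximum-posterior configuration per substructure.

    Events are merged into canonical configurations before the argmax; ties
    break to the lexicographically smallest configuration encoding so
    results are deterministic across runs.
    """
    mle: dict[tuple[str, str], Pair] = {}
    mle_post: dict[tuple[str, str], float] = {}
    best_configs: list[np.ndarray] = []
    oriented: set[tuple[str, str]] = set()
    for t, post in zip(tables, posteriors):
        uniq, inv = t.canonical()
        agg = np.bincount(inv, weights=post, minlength=uniq.shape[0])
        best = int(np.argmax(agg))  # first max = lexicographically smallest
        cfg = uniq[best]
        best_configs.append(cfg)
        for i, iid in enumerate(t.members):
            mle[(t.family, iid)] = (int(cfg[i, 0]), int(cfg[i, 1]))
            mle_post[(t.family, iid)] = float(agg[best])
            if i in t.child_parent:
                oriented.add((t.family, iid))
    return mle, mle_post, best_configs, oriented


# ---------------------------------------------------------------------------
# resource-level phasing (full EM and PL-EM)
# ---------------------------------------------------------------------------

@dataclass
class PhasingSettings:
    """Tunable parameters of the phasing pipeline.

    Defaults follow common partition-ligation practice for tightly linked
    SNP panels: 5-locus partitions with a 1-locus overlap, a 1e-6 frequency
    cutoff and a buffer of 25 additional haplotypes kept below the cutoff.
    """

    threshold: float = 0.5
    partition_len: int = 5
    overlap: int = 1
    cutoff: float = 1e-6
    buffer: int = 25
    tol: float = 1e-6
    max_iter: int = 1000
    naive: bool = False
    cap: int = DEFAULT_CAP


class EnumerationCache:
    """Memoises window enumerations keyed by structure and genotypes.

    Gene-dropped null data revisit the same pedigree shapes with a limited
    variety of genotype patterns, so caching compiled configuration tables
    across the Monte Carlo loop removes most enumeration cost.
    """

    def __init__(self, max_entries: int = 300_000) -> None:
        self._store: dict = {}
        self.max_entries = max_entries
        self.hits = 0
        self.misses = 0

    def get(self, sub: SubStructure, start: int, end: int, cap: int) -> SubConfigs:
        geno = np.concatenate(
            [sub.individuals[iid].genotypes[start:end].ravel() for iid in sub.members]
        )
        key = (sub.structure_signature(), start, end, geno.tobytes())
        hit = self._store.get(key)
        if hit is None:
            self.misses += 1
            prep = run_preprocessing(sub, loci=slice(start, end))
            table = substructure_configs(prep, cap=cap)
            hit = SubConfigs(
                family=table.family,
                members=table.members,
                founder_cols=table.founder_cols,
                child_parent=table.child_parent,
                member_pairs=table.member_pairs << start if start else table.member_pairs,
                logmult=table.logmult,
                n_children=table.n_children,
                canon_box=[],
            )
            if len(self._store) >= self.max_entries:
                self._store.clear()
            self._store[key] = hit
        else:
            self.hits += 1
        # rebind identity: structurally identical substructures share the
        # compiled arrays but carry their own family and member ids
        return SubConfigs(
            family=sub.family,
            members=list(sub.members),
            founder_cols=hit.founder_cols,
            child_parent=hit.child_parent,
            member_pairs=hit.member_pairs,
            logmult=hit.logmult,
            n_children=hit.n_children,
            canon_box=hit.canon_box,
        )


def _survivors(freqs: FrequencyTable, cutoff: float, buffer: int) -> np.ndarray:
    items = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = [h for h, f in items if f >= cutoff]
    below = [h for h, f in items if f < cutoff]
    keep += below[:buffer]
    return np.array(sorted(keep), dtype=np.int64)


def _windows(n: int, partition_len: int, overlap: int) -> list[tuple[int, int]]:
    if partition_len < 2 or overlap < 1 or overlap >= partition_len:
        raise ValueError("need partition_len >= 2 and 1 <= overlap < partition_len")
    wins: list[tuple[int, int]] = []
    s = 0
    while True:
        e = min(s + partition_len, n)
        if e - s < 2:  # widen a runt final window
            s = e - 2
        wins.append((s, e))
        if e == n:
            return wins
        s = e - overlap


def _own_pairs(sub: SubStructure, iid: str, end: int, cap: int) -> list[Pair]:
    state = load_phase_state(sub.individuals[iid].genotypes[:end])
    return individual_pairs(state, cap)


def rebind_substructures(
    subs: Sequence[SubStructure], resource: Resource
) -> list[SubStructure]:
    """Reuse a pedigree split on a resource with identical missingness.

    Gene-dropped nulls preserve the observed missing-data mask, so the
    membership decisions of the split are unchanged; only the Individual
    objects (and their genotypes) need rebinding.
    """
    lookup = {(ind.family, ind.iid): ind for ind in resource.individuals()}
    return [
        SubStructure(
            family=s.family,
            members=s.members,
            families=s.families,
            individuals={iid: lookup[(s.family, iid)] for iid in s.members},
        )
        for s in subs
    ]


def phase_resource(
    resource: Resource,
    settings: PhasingSettings | None = None,
    cache: EnumerationCache | None = None,
    subs: Sequence[SubStructure] | None = None,
) -> PhasingResult:
    """Phase a resource: frequencies plus MLE haplotype pairs.

    Splits pedigrees into substructures, enumerates configurations (per
    partition window when the panel exceeds one partition), and runs the EM;
    windows are then ligated left to right, pruning rare haplotypes after
    each estimation round.  With ``settings.naive=True`` every typed
    individual is treated as unrelated (the pedigree-naive baseline).
    """
    settings = settings or PhasingSettings()
    cache = cache or EnumerationCache()
    n = resource.n_markers
    if subs is None:
        subs = split_resource(resource, settings.threshold, naive=settings.naive)
    if not subs:
        raise ValueError("no individual passes the genotyping threshold")

    def finish(em: EMResult, tables: list[SubConfigs]) -> PhasingResult:
        mle, mle_post, best, oriented = mle_pairs(tables, em.posteriors)
        return PhasingResult(
            n_loci=n,
            freqs=em.freqs,
            tables=tables,
            posteriors=em.posteriors,
            loglik=em.loglik,
            n_iter=em.n_iter,
            converged=em.converged,
            mle=mle,
            mle_posterior=mle_post,
            best_configs=best,
            oriented=oriented,
        )

    if n <= settings.partition_len:
        tables = [cache.get(sub, 0, n, settings.cap) for sub in subs]
        em = em_estimate(tables, n, settings.tol, settings.max_iter)
        return finish(em, tables)

    wins = _windows(n, settings.partition_len, settings.overlap)
    block_haps: Optional[np.ndarray] = None
    block_end = 0
    em: Optional[EMResult] = None
    tables: list[SubConfigs] = []
    for (s, e) in wins:
        tables_w = [cache.get(sub, s, e, settings.cap) for sub in subs]
        em_w = em_estimate(tables_w, n, settings.tol, settings.max_iter)
        surv_w = _survivors(em_w.freqs, settings.cutoff, settings.buffer)
        if block_haps is None:
            block_haps, block_end = surv_w, e
            em, tables = em_w, tables_w
            continue
        om = ((1 << (block_end - s)) - 1) << s
        a = block_haps[:, None]
        b = surv_w[None, :]
        match = (a & om) == (b & om)
        ai, bi = np.nonzero(match)
        if ai.size == 0:
            raise EMDegeneracyError(
                "partition ligation produced no overlap-consistent haplotypes"
            )
        cand = np.unique(block_haps[ai] | surv_w[bi])
        loci = range(0, e)
        extra: dict[str, dict[str, list[Pair]]] = {}
        tables = []
        for sub in subs:
            sub_extra: dict[str, list[Pair]] = {}
            for attempt in range(len(sub.members) + 1):
                try:
                    sub_cand = cand
                    if sub_extra:
                        add = np.unique(
                            np.array(
                                [h for p in sub_extra.values() for pr in p for h in pr],
                                dtype=np.int64,
                            )
                        )
                        sub_cand = np.unique(np.concatenate([cand, add]))
                    tables.append(
                        restricted_configs(sub, loci, sub_cand, cap=settings.cap)
                    )
                    break
                except MendelianInconsistencyError as exc:
                    # fallback: reinstate the failing member's own
                    # genotype-consistent haplotypes and retry
                    msg = str(exc)
                    failing = None
                    for iid in sub.members:
                        if f"individual {iid} " in msg:
                            failing = iid
                            break
                    if failing is None or failing in sub_extra:
                        raise
                    log.info(
                        "ligation fallback: reinstating haplotypes of %s:%s",
                        sub.family, failing,
                    )
                    sub_extra[failing] = _own_pairs(sub, failing, e, settings.cap)
        em = em_estimate(tables, n, settings.tol, settings.max_iter)
        block_haps = _survivors(em.freqs, settings.cutoff, settings.buffer)
        block_end = e
    assert em is not None
    return finish(em, tables)
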
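"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own enumeration and EM
code paths: configurations are enumerated by raw cross-product expansion
with Mendelian filtering, and the reference EM is a direct textbook
genotype-EM for unrelated individuals.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from hapmc.configs import genotype_masks, pair_consistent
from hapmc.em import FrequencyTable
from hapmc.model import Individual, Marker, Pedigree, Resource


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def make_individual(fam, iid, father, mother, genotypes, aff=1, sex=1):
    return Individual(
        family=fam, iid=iid, father=father, mother=mother, sex=sex,
        affection=aff, genotypes=np.asarray(genotypes, dtype=np.int8),
    )


def geno_from_haps(h0: int, h1: int, n: int, rng=None, miss_rate: float = 0.0):
    bits = np.arange(n)
    a = ((h0 >> bits) & 1) + 1
    b = ((h1 >> bits) & 1) + 1
    g = np.sort(np.stack([a, b], axis=1), axis=1).astype(np.int8)
    if rng is not None and miss_rate > 0:
        g[rng.random(n) < miss_rate] = 0
    return g


def markers(n: int) -> list[Marker]:
    return [Marker(id=f"M{i + 1}", index=i) for i in range(n)]


def random_consistent_pedigree(rng, n_loci: int, miss_rate: float) -> Pedigree:
    """A 2-3 generation pedigree generated from true haplotypes."""
    n = n_loci

    def hap() -> int:
        return int(rng.integers(0, 1 << n))

    F = (hap(), hap())
    M = (hap(), hap())
    members = {
        "F": make_individual("P", "F", None, None, geno_from_haps(*F, n, rng, miss_rate)),
        "M": make_individual("P", "M", None, None, geno_from_haps(*M, n, rng, miss_rate)),
    }
    kids = int(rng.integers(1, 4))
    child_haps = {}
    for k in range(kids):
        c = (M[rng.integers(2)], F[rng.integers(2)])
        child_haps[k] = c
        members[f"C{k}"] = make_individual(
            "P", f"C{k}", "F", "M", geno_from_haps(*c, n, rng, miss_rate)
        )
    if rng.random() < 0.5:
        S = (hap(), hap())
        members["S"] = make_individual(
            "P", "S", None, None, geno_from_haps(*S, n, rng, miss_rate)
        )
        G = (S[rng.integers(2)], child_haps[0][rng.integers(2)])
        members["G"] = make_individual(
            "P", "G", "C0", "S", geno_from_haps(*G, n, rng, miss_rate)
        )
    return Pedigree(family="P", members=members)


@pytest.fixture
def dense_pool() -> tuple[FrequencyTable, int]:
    """A 40-haplotype pool over 10 loci with genuine phase ambiguity.

    Unlike the sparse packaged pool, many genotypes here admit several
    haplotype pairs, so pedigree information visibly improves phasing.
    Returns (pool, risk haplotype = the most frequent one).
    """
    rng = np.random.default_rng(42)
    n = 10
    haps = rng.choice(1 << n, size=40, replace=False)
    w = rng.dirichlet(np.ones(40) * 1.2)
    pool = FrequencyTable(
        n_loci=n, freqs={int(h): float(p) for h, p in zip(haps, w / w.sum())}
    )
    return pool, int(haps[np.argmax(w)])


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_genotype_pairs(genotypes: np.ndarray, n: int) -> list[tuple[int, int]]:
    """All unordered haplotype pairs consistent with raw genotypes."""
    opts = []
    for i in range(n):
        a1, a2 = genotypes[i]
        if a1 == 0 or a2 == 0:
            opts.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif a1 == a2:
            b = int(a1 == 2)
            opts.append([(b, b)])
        else:
            opts.append([(0, 1), (1, 0)])
    pairs = set()
    for combo in itertools.product(*opts):
        h0 = sum(b0 << i for i, (b0, _) in enumerate(combo))
        h1 = sum(b1 << i for i, (_, b1) in enumerate(combo))
        pairs.add((min(h0, h1), max(h0, h1)))
    return sorted(pairs)


def oracle_configurations(ped: Pedigree, n: int) -> set[tuple]:
    """Brute-force canonical configurations of a whole pedigree.

    Founders take unordered pairs, descendants (maternal, paternal) pairs
    from their parents, filtered on genotype consistency only.
    """
    members = list(ped.members.values())
    ids = [m.iid for m in members]
    founders = [m for m in members if m.is_founder]
    desc = [m for m in ped.topological_order() if not m.is_founder]
    fpairs = {m.iid: oracle_genotype_pairs(m.genotypes, n) for m in founders}
    masks = {m.iid: genotype_masks(m.genotypes) for m in members}
    out: set[tuple] = set()
    for fassign in itertools.product(*[fpairs[f.iid] for f in founders]):
        stack = [(0, {f.iid: p for f, p in zip(founders, fassign)})]
        while stack:
            k, cur = stack.pop()
            if k == len(desc):
                out.add(tuple(tuple(cur[i]) for i in ids))
                continue
            d = desc[k]
            mp, fp = cur[d.mother], cur[d.father]
            seen = set()
            for s in (0, 1):
                for t in (0, 1):
                    matpat = (mp[s], fp[t])
                    if matpat in seen:
                        continue
                    seen.add(matpat)
                    if not pair_consistent(*matpat, masks[d.iid]):
                        continue
                    nxt = dict(cur)
                    nxt[d.iid] = matpat
                    stack.append((k + 1, nxt))
    return out


def oracle_genotype_em(
    genolist: list[np.ndarray], n: int, tol: float = 1e-12, iters: int = 10000
) -> dict[int, float]:
    """Textbook genotype-EM for unrelated individuals (the reference)."""
    plists = [oracle_genotype_pairs(g, n) for g in genolist]
    universe = sorted({h for pl in plists for p in pl for h in p})
    idx = {h: i for i, h in enumerate(universe)}
    f = np.full(len(universe), 1.0 / len(universe))
    for _ in range(iters):
        counts = np.zeros(len(universe))
        for pl in plists:
            w = np.array([f[idx[a]] * f[idx[b]] * (2 if a != b else 1) for a, b in pl])
            w = w / w.sum()
            for (a, b), wi in zip(pl, w):
                counts[idx[a]] += wi
                counts[idx[b]] += wi
        f_new = counts / (2 * len(plists))
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return {h: float(f[idx[h]]) for h in universe}
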
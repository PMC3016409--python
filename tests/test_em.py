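"""EM haplotype-frequency estimation, PL-EM, and MLE pairs."""
import numpy as np
import pytest

from hapmc.configs import str_to_hap
from hapmc.em import (
    FrequencyTable,
    PhasingSettings,
    config_prior,
    em_estimate,
    phase_resource,
)
from hapmc.mc import threshold_code
from hapmc.model import Individual, Pedigree, Resource
from hapmc.phaseprep import run_preprocessing, split_resource
from hapmc.configs import substructure_configs
from hapmc.sim import DesignSpec, DiseaseModel, phasing_accuracy, simulate_design

from conftest import geno_from_haps, make_individual, markers, oracle_genotype_em


def singleton_resource(genos, n):
    inds = [
        make_individual(f"I{i}", "1", None, None, g) for i, g in enumerate(genos)
    ]
    return Resource(markers=markers(n), singletons=inds)


def hap_resource(rng, pool, n, size, miss=0.0):
    haps = pool.haplotypes()
    p = np.array([pool.freqs[int(h)] for h in haps])
    p = p / p.sum()
    genos = []
    for _ in range(size):
        h0, h1 = rng.choice(haps, size=2, p=p)
        genos.append(geno_from_haps(int(h0), int(h1), n, rng, miss))
    return singleton_resource(genos, n)


class TestConfigPrior:
    def test_founder_pair_probabilities(self):
        n = 2
        freqs = FrequencyTable(n_loci=n, freqs={0b00: 0.3, 0b11: 0.2, 0b01: 0.5})
        ind = make_individual("X", "1", None, None, geno_from_haps(0b00, 0b11, n))
        res = Resource(markers=markers(n), singletons=[ind])
        sub = split_resource(res, 0.0)[0]
        table = substructure_configs(run_preprocessing(sub))
        uniq, _ = table.canonical()
        cfg = uniq[0]
        # unequal founder pair: 2 * 0.3 * 0.2
        assert config_prior(cfg, table, freqs) == pytest.approx(0.12)

    def test_equal_pair_is_squared(self):
        n = 2
        freqs = FrequencyTable(n_loci=n, freqs={0b00: 0.3, 0b11: 0.7})
        ind = make_individual("X", "1", None, None, geno_from_haps(0b00, 0b00, n))
        res = Resource(markers=markers(n), singletons=[ind])
        sub = split_resource(res, 0.0)[0]
        table = substructure_configs(run_preprocessing(sub))
        cfg = table.canonical()[0][0]
        assert config_prior(cfg, table, freqs) == pytest.approx(0.09)

    def test_trio_transmission_factors(self):
        """Child receiving one specific haplotype from each het parent: x 1/4."""
        n = 1
        freqs = FrequencyTable(n_loci=n, freqs={0: 0.6, 1: 0.4})
        inds = {
            "F": make_individual("P", "F", None, None, np.array([[1, 2]], dtype=np.int8)),
            "M": make_individual("P", "M", None, None, np.array([[1, 2]], dtype=np.int8), sex=2),
            "C": make_individual("P", "C", "F", "M", np.array([[1, 1]], dtype=np.int8)),
        }
        ped = Pedigree(family="P", members=inds)
        res = Resource(markers=markers(n), pedigrees=[ped])
        sub = split_resource(res, 0.0)[0]
        table = substructure_configs(run_preprocessing(sub))
        uniq, _ = table.canonical()
        assert uniq.shape[0] == 1
        # two het founders (2*0.6*0.4 each) times (1/2)(1/2) transmission
        assert config_prior(uniq[0], table, freqs) == pytest.approx(
            (2 * 0.6 * 0.4) ** 2 * 0.25
        )


class TestEMCorrectness:
    def test_double_heterozygote_stationary_point(self):
        """One individual 12/12: symmetric quarter frequencies, posteriors 1/2."""
        res = singleton_resource([np.array([[1, 2], [1, 2]], dtype=np.int8)], 2)
        ph = phase_resource(res)
        assert ph.freqs[0b00] == pytest.approx(0.25, abs=1e-9)
        assert ph.freqs[0b11] == pytest.approx(0.25, abs=1e-9)
        assert np.allclose(ph.posteriors[0], [0.5, 0.5])

    def test_phase_known_sample_is_counting(self):
        """Unambiguous individuals: frequencies are plain counting proportions."""
        genos = (
            [geno_from_haps(0b00, 0b00, 2)] * 3
            + [geno_from_haps(0b11, 0b11, 2)] * 2
            + [geno_from_haps(0b01, 0b01, 2)] * 5
        )
        ph = phase_resource(singleton_resource(genos, 2))
        assert ph.freqs[0b00] == pytest.approx(0.3, abs=1e-9)
        assert ph.freqs[0b11] == pytest.approx(0.2, abs=1e-9)
        assert ph.freqs[0b01] == pytest.approx(0.5, abs=1e-9)

    def test_matches_independent_genotype_em_oracle(self):
        """Unrelated-only resources reproduce a textbook genotype-EM."""
        from hapmc.sim import default_pool

        rng = np.random.default_rng(5)
        n = 4
        res = hap_resource(rng, default_pool(n), n, 40, miss=0.1)
        ph = phase_resource(res, PhasingSettings(tol=1e-12, max_iter=10000))
        oracle = oracle_genotype_em([s.genotypes for s in res.singletons], n)
        for h, f in oracle.items():
            assert ph.freqs[h] == pytest.approx(f, abs=1e-6)

    def test_loglik_monotone_and_frequencies_normalised(self, dense_pool):
        """Across random fixtures the EM never decreases the log-likelihood."""
        pool, _ = dense_pool
        rng = np.random.default_rng(11)
        n = 4
        from hapmc.sim import default_pool

        for rep in range(100):
            res = hap_resource(rng, default_pool(n), n, int(rng.integers(5, 25)),
                               miss=float(rng.choice([0.0, 0.1, 0.3])))
            subs = split_resource(res, 0.0)
            tables = [
                substructure_configs(run_preprocessing(s)) for s in subs
            ]
            em = em_estimate(tables, n, tol=1e-9, max_iter=500)
            trace = np.array(em.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)
            assert sum(f for _, f in em.freqs.items()) == pytest.approx(1.0, abs=1e-9)
            assert all(f >= 0 for _, f in em.freqs.items())

    def test_allele_label_symmetry(self):
        """Swapping allele labels at one marker permutes haplotypes only."""
        rng = np.random.default_rng(9)
        from hapmc.sim import default_pool

        n = 3
        res = hap_resource(rng, default_pool(n), n, 30, miss=0.1)
        ph = phase_resource(res, PhasingSettings(tol=1e-10, max_iter=5000))
        flip_locus = 1
        flipped = []
        for s in res.singletons:
            g = s.genotypes.copy()
            nonmiss = g[flip_locus] != 0
            g[flip_locus][nonmiss] = 3 - g[flip_locus][nonmiss]
            g[flip_locus] = np.sort(g[flip_locus])
            flipped.append(g)
        res2 = singleton_resource(flipped, n)
        ph2 = phase_resource(res2, PhasingSettings(tol=1e-10, max_iter=5000))
        assert ph2.loglik == pytest.approx(ph.loglik, abs=1e-6)
        for h, f in ph.freqs.items():
            assert ph2.freqs[h ^ (1 << flip_locus)] == pytest.approx(f, abs=1e-6)


class TestPLEM:
    def test_single_partition_equals_full_em(self):
        rng = np.random.default_rng(2)
        from hapmc.sim import default_pool

        n = 5
        res = hap_resource(rng, default_pool(n), n, 50, miss=0.05)
        a = phase_resource(res, PhasingSettings(partition_len=5))
        b = phase_resource(res, PhasingSettings(partition_len=10))
        for h, f in a.freqs.items():
            assert b.freqs[h] == pytest.approx(f, abs=1e-9)

    def test_no_pruning_matches_full_em(self):
        """cutoff 0 and unbounded buffer reproduce full-length EM to 1e-6."""
        rng = np.random.default_rng(4)
        from hapmc.sim import default_pool

        n = 8
        res = hap_resource(rng, default_pool(n), n, 60, miss=0.05)
        full = phase_resource(res, PhasingSettings(partition_len=8, tol=1e-10, max_iter=5000))
        pl = phase_resource(res, PhasingSettings(
            partition_len=5, overlap=1, cutoff=0.0, buffer=10**9,
            tol=1e-10, max_iter=5000,
        ))
        keys = set(full.freqs.freqs) | set(pl.freqs.freqs)
        for h in keys:
            assert pl.freqs[h] == pytest.approx(full.freqs[h], abs=1e-6)

    def test_default_pruning_runs_at_fifteen_loci(self):
        rng = np.random.default_rng(6)
        from hapmc.sim import default_pool

        n = 15
        res = hap_resource(rng, default_pool(n), n, 80, miss=0.05)
        ph = phase_resource(res)  # defaults: 5/1/1e-6/25
        assert ph.converged
        assert sum(f for _, f in ph.freqs.items()) == pytest.approx(1.0, abs=1e-9)


class TestMLEPairs:
    def test_unambiguous_individual_has_posterior_one(self):
        res = singleton_resource([geno_from_haps(0b01, 0b01, 2)], 2)
        ph = phase_resource(res)
        ((key, pair),) = ph.mle.items()
        assert pair == (0b01, 0b01)
        assert ph.mle_posterior[key] == pytest.approx(1.0)

    def test_tie_breaks_to_lexicographically_smallest(self):
        """12/12 singleton: both phases tie; the sorted-smallest pair wins."""
        res = singleton_resource([np.array([[1, 2], [1, 2]], dtype=np.int8)], 2)
        ph = phase_resource(res)
        ((_, pair),) = ph.mle.items()
        assert pair == (0b00, 0b11)

    def test_pedigree_informed_beats_naive_on_ambiguous_pool(self, dense_pool):
        """With real phase ambiguity, trio structure strictly improves MLE accuracy."""
        pool, risk = dense_pool
        rng = np.random.default_rng(8)
        model = DiseaseModel(risk_hap=risk, q=0.1, grr=1.0)
        spec = DesignSpec.asp(n_families=60, missing_rate=0.05)
        res, truth = simulate_design(spec, model, pool, rng)
        coded = threshold_code(res, 0.5)
        informed = phase_resource(coded, PhasingSettings())
        naive = phase_resource(coded, PhasingSettings(naive=True))
        acc_i = phasing_accuracy(informed.mle, truth)
        acc_n = phasing_accuracy(naive.mle, truth)
        assert acc_i > acc_n


class TestEventWeights:
    def test_events_reproduce_elston_stewart_priors(self):
        """Summed event weights equal the configuration prior exactly.

        For random pedigrees and random frequency tables, aggregating the
        enumerated events (founder HWE terms x transmission selectors) per
        canonical configuration must reproduce the Elston-Stewart prior
        computed directly from that configuration.
        """
        from hapmc.phaseprep import split_pedigree, run_preprocessing
        from conftest import random_consistent_pedigree

        rng = np.random.default_rng(303)
        checked = 0
        for trial in range(150):
            n = int(rng.integers(2, 5))
            ped = random_consistent_pedigree(rng, n, [0.0, 0.15, 0.3][trial % 3])
            subs = split_pedigree(ped, 0.0)
            if len(subs) != 1 or set(subs[0].members) != set(ped.members):
                continue
            table = substructure_configs(run_preprocessing(subs[0]))
            w = rng.dirichlet(np.ones(1 << n))
            freqs = FrequencyTable(
                n_loci=n, freqs={h: float(w[h]) for h in range(1 << n)}
            )
            logf = np.log(w)
            fh = table.founder_haps()
            ev = np.exp(logf[fh].sum(axis=1) + table.logmult)
            ev *= 0.25 ** table.n_children
            uniq, inv = table.canonical()
            agg = np.bincount(inv, weights=ev, minlength=uniq.shape[0])
            for k, cfg in enumerate(uniq):
                assert agg[k] == pytest.approx(
                    config_prior(cfg, table, freqs), rel=1e-9
                )
            checked += 1
        assert checked > 100
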
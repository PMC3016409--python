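"""Bit-vector loading, deduction rules, splitting, and soundness."""
import numpy as np
import pytest

from hapmc.model import MendelianInconsistencyError, Pedigree
from hapmc.phaseprep import (
    PhaseState,
    load_phase_state,
    run_preprocessing,
    split_pedigree,
    SubStructure,
)
from hapmc.configs import substructure_configs

from conftest import (
    make_individual,
    geno_from_haps,
    oracle_configurations,
    random_consistent_pedigree,
)


def bits(s: str) -> list[int]:
    return [int(c) for c in s]


class TestLoadPhaseState:
    def test_worked_example_six_variables(self):
        """Genotypes 12 00 11 12 22 load to the canonical six bit vectors."""
        g = np.array([[1, 2], [0, 0], [1, 1], [1, 2], [2, 2]], dtype=np.int8)
        st = load_phase_state(g)
        assert st.hom.astype(int).tolist() == bits("00101")
        assert st.het.astype(int).tolist() == bits("10010")
        assert st.unphased.astype(int).tolist() == bits("10010")
        for k in (0, 1):
            assert st.hset[k].astype(int).tolist() == bits("00101")
            assert st.miss[k].astype(int).tolist() == bits("01000")
            assert st.val[k].astype(int).tolist() == bits("00001")

    def test_all_missing(self):
        st = load_phase_state(np.zeros((4, 2), dtype=np.int8))
        assert not st.hom.any() and not st.het.any() and not st.unphased.any()
        assert st.miss.all() and not st.hset.any()

    def test_all_homozygous_major(self):
        st = load_phase_state(np.ones((2, 2), dtype=np.int8))
        assert not st.unphased.any()
        assert st.hset.all() and not st.val.any()


class TestSplitting:
    def test_fully_typed_trio_is_retained(self):
        g = np.ones((4, 2), dtype=np.int8)
        ped = Pedigree(family="P", members={
            "F": make_individual("P", "F", None, None, g),
            "M": make_individual("P", "M", None, None, g, sex=2),
            "C": make_individual("P", "C", "F", "M", g),
        })
        subs = split_pedigree(ped, 0.5)
        assert len(subs) == 1 and not subs[0].detached
        assert sorted(subs[0].members) == ["C", "F", "M"]

    def test_untyped_parents_detach_typed_child(self):
        g = np.ones((4, 2), dtype=np.int8)
        z = np.zeros((4, 2), dtype=np.int8)
        ped = Pedigree(family="P", members={
            "F": make_individual("P", "F", None, None, z),
            "M": make_individual("P", "M", None, None, z, sex=2),
            "C": make_individual("P", "C", "F", "M", g),
        })
        subs = split_pedigree(ped, 0.5)
        assert len(subs) == 1 and subs[0].detached
        assert subs[0].members == ["C"]

    def test_untyped_top_generations_keep_lower_units_connected(self):
        """Grandparents untyped: the two linked lower nuclear families survive."""
        g = np.ones((4, 2), dtype=np.int8)
        z = np.zeros((4, 2), dtype=np.int8)
        members = {
            "GF": make_individual("P", "GF", None, None, z),
            "GM": make_individual("P", "GM", None, None, z, sex=2),
            "F": make_individual("P", "F", "GF", "GM", g),
            "M": make_individual("P", "M", None, None, g, sex=2),
            "C": make_individual("P", "C", "F", "M", g),
            "S": make_individual("P", "S", None, None, g, sex=2),
            "G": make_individual("P", "G", "C", "S", g),
        }
        ped = Pedigree(family="P", members=members)
        subs = split_pedigree(ped, 0.5)
        frags = [s for s in subs if not s.detached]
        assert len(frags) == 1
        assert sorted(frags[0].members) == ["C", "F", "G", "M", "S"]
        assert len(frags[0].families) == 2


class TestDeductionRules:
    def test_parent_homozygous_resolves_offspring_positions(self):
        """A homozygous parent phases exactly the offspring's open positions."""
        n = 9
        # parent homozygous everywhere; offspring het at 3 loci
        pg = geno_from_haps(0b000000000, 0b000000000, n)
        ch = 0b000110010
        cg = geno_from_haps(0b000000000, ch, n)
        m = make_individual("P", "M", None, None, pg, sex=2)
        f_hap = (0b111111111, ch)
        fg = geno_from_haps(*f_hap, n)
        f = make_individual("P", "F", None, None, fg)
        c = make_individual("P", "C", "F", "M", cg)
        sub = SubStructure(
            family="P", members=["F", "M", "C"],
            families=[("F", "M", ["C"])],
            individuals={"F": f, "M": m, "C": c},
        )
        prep = run_preprocessing(sub)
        st = prep.states["C"]
        assert not st.unphased.any()          # all het loci phased via parent
        assert st.hset.all()

    def test_fully_heterozygous_parent_gives_no_update(self):
        n = 3
        pg = geno_from_haps(0b000, 0b111, n)
        cg = geno_from_haps(0b000, 0b111, n)
        f = make_individual("P", "F", None, None, pg)
        m = make_individual("P", "M", None, None, pg, sex=2)
        c = make_individual("P", "C", "F", "M", cg)
        sub = SubStructure(
            family="P", members=["F", "M", "C"],
            families=[("F", "M", ["C"])],
            individuals={"F": f, "M": m, "C": c},
        )
        prep = run_preprocessing(sub)
        assert prep.states["C"].unphased.astype(int).tolist() == [1, 1, 1]

    def test_offspring_homozygotes_phase_parent(self):
        """Two children homozygous for different alleles phase the het parent."""
        n = 1
        f = make_individual("P", "F", None, None, np.array([[1, 2]], dtype=np.int8))
        m = make_individual("P", "M", None, None, np.array([[1, 2]], dtype=np.int8), sex=2)
        c1 = make_individual("P", "C1", "F", "M", np.array([[1, 1]], dtype=np.int8))
        c2 = make_individual("P", "C2", "F", "M", np.array([[2, 2]], dtype=np.int8))
        sub = SubStructure(
            family="P", members=["F", "M", "C1", "C2"],
            families=[("F", "M", ["C1", "C2"])],
            individuals={"F": f, "M": m, "C1": c1, "C2": c2},
        )
        prep = run_preprocessing(sub)
        table = substructure_configs(prep)
        # both parents forced to carry one '1' and one '2' haplotype
        uniq, _ = table.canonical()
        assert uniq.shape[0] == 1

    def test_mendelian_conflict_raises(self):
        f = make_individual("P", "F", None, None, np.array([[1, 1]], dtype=np.int8))
        m = make_individual("P", "M", None, None, np.array([[1, 1]], dtype=np.int8), sex=2)
        c = make_individual("P", "C", "F", "M", np.array([[2, 2]], dtype=np.int8))
        sub = SubStructure(
            family="P", members=["F", "M", "C"],
            families=[("F", "M", ["C"])],
            individuals={"F": f, "M": m, "C": c},
        )
        with pytest.raises(MendelianInconsistencyError):
            run_preprocessing(sub)

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ped = random_consistent_pedigree(rng, 4, 0.15)
            subs = split_pedigree(ped, 0.0)
            for sub in subs:
                p1 = run_preprocessing(sub)
                p2 = run_preprocessing(sub)
                # rerun from the fixed point: states identical
                for iid in sub.members:
                    a, b = p1.states[iid], p2.states[iid]
                    assert np.array_equal(a.hset, b.hset)
                    assert np.array_equal(a.val, b.val)
                    assert np.array_equal(a.unphased, b.unphased)


class TestSoundness:
    def test_preprocessing_preserves_configuration_set(self):
        """Deductions never add or remove a Mendelian-consistent configuration.

        The canonical configuration set after preprocessing + enumeration
        must equal brute-force expansion-and-filter on the raw genotypes.
        """
        rng = np.random.default_rng(7)
        checked = 0
        for trial in range(150):
            n = int(rng.integers(2, 5))
            ped = random_consistent_pedigree(rng, n, [0.0, 0.1, 0.25][trial % 3])
            bf = oracle_configurations(ped, n)
            subs = split_pedigree(ped, 0.0)
            if len(subs) != 1 or set(subs[0].members) != set(ped.members):
                continue
            prep = run_preprocessing(subs[0])
            table = substructure_configs(prep)
            uniq, _ = table.canonical()
            idx = [table.members.index(i) for i in ped.members]
            got = {
                tuple(tuple(int(x) for x in cfg[j]) for j in idx) for cfg in uniq
            }
            assert got == bf
            checked += 1
        assert checked > 100
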
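"""Association statistics: coding, trend, chi-square, OR, TDT, controls."""
import numpy as np
import pytest

from hapmc.em import PhasingSettings, phase_resource
from hapmc.mc import threshold_code
from hapmc.sim import DesignSpec, default_pool, simulate_design
from hapmc.experiments import null_model
from hapmc.stats import (
    Exposure,
    chi_square,
    diploid_table,
    extract_subhaplotype,
    generate_pseudocontrol,
    haploid_table,
    odds_ratio,
    select_controls,
    tdt,
    trend_test,
)


class TestSubhaplotypeExtraction:
    def test_positional_projection(self):
        pair = (int("10101", 2), int("01010", 2))  # bit i = locus i
        # loci {0,2,4} of 12122/21211-style pair
        full = (0b01010, 0b10101)
        assert extract_subhaplotype(full, (0, 2, 4)) == (0b000, 0b111)

    def test_full_set_is_identity(self):
        pair = (0b01101, 0b11010)
        assert extract_subhaplotype(pair, range(5)) == pair

    def test_single_locus(self):
        assert extract_subhaplotype((0b100, 0b011), (2,)) == (1, 0)


class TestPseudocontrol:
    def test_untransmitted_complement(self):
        A, B, C, D = 1, 2, 3, 4
        assert generate_pseudocontrol((A, B), (C, D), (C, A), oriented=True) == (2, 4)

    def test_homozygous_father(self):
        A, C, D = 1, 3, 4
        assert generate_pseudocontrol((A, A), (C, D), (C, A), oriented=True) == (1, 4)

    def test_unresolvable_case_returns_none(self):
        # case haplotypes not derivable from the parents (e.g. phased in a
        # different substructure): no pseudocontrol
        assert generate_pseudocontrol((1, 2), (3, 4), (5, 6), oriented=False) is None

    def test_unoriented_pair_is_still_unambiguous(self):
        # both orientations of (A, B) yield the same complement multiset
        A, B = 1, 2
        assert generate_pseudocontrol((A, B), (A, B), (A, B), oriented=False) == (1, 2)

    def test_conservation_property(self):
        """case pair + pseudocontrol pair = all four parental haplotypes."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            fa = tuple(rng.integers(0, 8, size=2))
            mo = tuple(rng.integers(0, 8, size=2))
            case = (mo[rng.integers(2)], fa[rng.integers(2)])
            pc = generate_pseudocontrol(fa, mo, case, oriented=True)
            assert pc is not None
            assert sorted(case + pc) == sorted(fa + mo)


class TestClosedFormStatistics:
    def test_trend_identical_distributions_is_zero(self):
        t = np.array([[10, 20, 5], [10, 20, 5]])
        assert trend_test(t) == pytest.approx(0.0)

    def test_trend_reduces_to_two_by_two_pearson(self):
        """Cases 5/15 at 0/1 copies vs controls 15/5: statistic exactly 10."""
        t = np.array([[5, 15, 0], [15, 5, 0]])
        assert trend_test(t) == pytest.approx(10.0, abs=1e-12)

    def test_trend_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 3)).astype(float)
            got = trend_test(t)
            # independent direct formula
            s = np.array([0.0, 1.0, 2.0])
            N = t.sum()
            R = t[0].sum()
            n = t.sum(axis=0)
            if N == 0 or R == 0 or R == N:
                assert got == 0.0
                continue
            num = np.sum(s * (t[0] - n * R / N))
            den = R * (1 - R / N) * (np.sum(s * s * n) - np.sum(s * n) ** 2 / N)
            expected = 0.0 if den <= 0 else N * num**2 / den
            assert got == pytest.approx(expected, abs=1e-10)

    def test_monomorphic_trend_is_zero_with_warning(self):
        t = np.array([[10, 0, 0], [12, 0, 0]])
        assert trend_test(t) == 0.0

    def test_odds_ratio_arithmetic(self):
        assert odds_ratio(np.array([[20, 10], [10, 20]])) == pytest.approx(4.0)

    def test_symmetric_table(self):
        t = np.array([[15, 15], [15, 15]])
        assert odds_ratio(t) == pytest.approx(1.0)
        assert chi_square(t) == pytest.approx(0.0)

    def test_zero_cell_gets_haldane_correction(self):
        t = np.array([[10, 0], [5, 5]])
        assert odds_ratio(t) == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_chi_square_pearson(self):
        t = np.array([[5, 15], [15, 5]])
        assert chi_square(t) == pytest.approx(40 * (5 * 5 - 15 * 15) ** 2 / (20**4))


class TestExposureTables:
    def test_margins_conserved_over_targets(self):
        rng = np.random.default_rng(1)
        exposures = [
            Exposure(pair=(int(rng.integers(4)), int(rng.integers(4))),
                     is_case=bool(rng.integers(2)), role="case")
            for _ in range(100)
        ]
        total_copies = np.zeros(2)
        for target in range(4):
            t = diploid_table(exposures, target)
            assert t.sum() == 100
            total_copies += t @ np.array([0, 1, 2])
            h = haploid_table(exposures, target)
            assert h.sum() == 200
        assert total_copies.sum() == 200  # every chromosome counted once


class TestTDT:
    def _trio_resource(self, n_fam, rng, pool_n=5):
        spec = DesignSpec.trio(n_families=n_fam)
        model = null_model(q=0.10, n_markers=pool_n)
        res, _ = simulate_design(spec, model, default_pool(pool_n), rng)
        return res, model

    def test_closed_form_from_counts(self):
        assert (10 - 5) ** 2 / (10 + 5) == pytest.approx(25 / 15)

    def test_hand_enumerated_asp_fixture(self):
        """Both affected sibs counted; each parent contributes per offspring."""
        from hapmc.model import Pedigree, Resource, Marker
        from conftest import make_individual
        import numpy as np

        n = 1
        # father het 1|2, mother hom 1|1, both children affected hom 1
        g = {
            "F": [[1, 2]], "M": [[1, 1]], "C1": [[1, 1]], "C2": [[1, 1]],
        }
        members = {
            "F": make_individual("P", "F", None, None, np.array(g["F"], dtype=np.int8)),
            "M": make_individual("P", "M", None, None, np.array(g["M"], dtype=np.int8), sex=2),
            "C1": make_individual("P", "C1", "F", "M", np.array(g["C1"], dtype=np.int8), aff=2),
            "C2": make_individual("P", "C2", "F", "M", np.array(g["C2"], dtype=np.int8), aff=2),
        }
        res = Resource(markers=[Marker("M1", 0)], pedigrees=[Pedigree("P", members)])
        ph = phase_resource(res, PhasingSettings())
        # target = allele-1 haplotype (encoding 0): father transmits it twice
        stat, b, c = tdt(res, ph, target=0)
        assert (b, c) == (2, 0)
        assert stat == pytest.approx((b - c) ** 2 / (b + c))

    def test_balanced_transmissions_give_zero(self):
        rng = np.random.default_rng(2)
        res, model = self._trio_resource(80, rng)
        ph = phase_resource(threshold_code(res, 0.5))
        stat, b, c = tdt(res, ph, target=model.risk_hap)
        if b == c:
            assert stat == 0.0
        else:
            assert stat == pytest.approx((b - c) ** 2 / (b + c))


class TestControlSelection:
    def test_pc_on_case_control_equals_ec(self):
        rng = np.random.default_rng(4)
        model = null_model(q=0.10, n_markers=5)
        res, _ = simulate_design(
            DesignSpec.cc(n_cases=30, n_controls=30), model, default_pool(5), rng
        )
        ph = phase_resource(threshold_code(res, 0.5))
        ec = select_controls(res, ph, "EC")
        pc = select_controls(res, ph, "PC")
        assert len(ec) == len(pc) == 60
        assert all(e.role != "pseudo" for e in pc)

    def test_trio_pc_counts_and_invariant(self):
        rng = np.random.default_rng(5)
        model = null_model(q=0.10, n_markers=5)
        res, _ = simulate_design(DesignSpec.trio(n_families=60), model,
                                 default_pool(5), rng)
        ph = phase_resource(threshold_code(res, 0.5))
        ec = select_controls(res, ph, "EC")
        pc = select_controls(res, ph, "PC")
        cases_ec = sum(e.is_case for e in ec)
        cases_pc = sum(e.is_case for e in pc)
        n_pseudo = sum(e.role == "pseudo" for e in pc)
        ctrl_ec = sum(not e.is_case for e in ec)
        ctrl_pc = sum(not e.is_case for e in pc)
        assert cases_ec == cases_pc
        assert ctrl_pc == ctrl_ec - 2 * n_pseudo + n_pseudo
        assert n_pseudo > 0

    def test_case_with_untyped_parent_contributes_no_pseudocontrol(self):
        from hapmc.model import Pedigree, Resource, Marker
        from conftest import make_individual, geno_from_haps

        n = 2
        z = np.zeros((n, 2), dtype=np.int8)
        members = {
            "F": make_individual("P", "F", None, None, z),
            "M": make_individual("P", "M", None, None, geno_from_haps(0, 0, n), sex=2),
            "C": make_individual("P", "C", "F", "M", geno_from_haps(0, 0, n), aff=2),
            "U": make_individual("P", "U", "F", "M", geno_from_haps(0, 0, n)),
        }
        res = Resource(markers=[Marker("M1", 0), Marker("M2", 1)],
                       pedigrees=[Pedigree("P", members)])
        ph = phase_resource(threshold_code(res, 0.5))
        pc = select_controls(res, ph, "PC")
        assert sum(e.role == "pseudo" for e in pc) == 0
        # unaffected relatives stay explicit
        assert sum(e.role == "explicit" for e in pc) >= 1
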
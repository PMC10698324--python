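"""Full GP-map tables, phenotypic frequencies and phi rows."""
import numpy as np
import pytest

from boltzmap.core import UNFOLDED, EmptyNeutralSetError
from boltzmap.gpmap import (build_full_gpmap, count_folding_structures,
                            mutant_codes, phenotypic_frequencies, phi_row,
                            phi_row_sampled, point_mutants)
from boltzmap.hp_thermo import assign_mfe
from boltzmap.lattice import build_catalogue, canonicalize, reverse_moves

from oracles import all_hp_sequences, fold_direct, phi_direct


class TestBuildFullGPMap:
    def test_single_structure_lattice_all_fold(self, suite):
        cat, gp = suite[(2, 2)]
        assert cat.n == 1
        assert np.all(gp.assignment == 0)

    def test_2x3_matches_per_sequence_oracle(self, cat_2x3, gp_2x3):
        for code, seq in enumerate(all_hp_sequences(6)):
            # oracle iterates P/H lexicographically; map to the code convention
            code = sum((1 << i) for i, s in enumerate(seq) if s == "H")
            assert gp_2x3.assignment[code] == fold_direct(seq, cat_2x3)

    @pytest.mark.parametrize("grid", [(2, 3), (3, 3), (2, 4), (4, 4)])
    def test_kernel_and_numpy_paths_agree(self, grid, suite):
        cat, gp = suite[grid]
        kern = build_full_gpmap(cat, method="kernel")
        assert np.array_equal(kern.assignment, gp.assignment)

    def test_homopolymers_unfold_when_multiple_structures(self, gp_2x3, gp_2x4):
        for gp in (gp_2x3, gp_2x4):
            assert gp.assignment[0] == UNFOLDED  # all-P
            assert gp.assignment[-1] == UNFOLDED  # all-H

    def test_size_ceiling_guard(self, cat_2x3):
        with pytest.raises(ValueError, match="ceiling"):
            build_full_gpmap(cat_2x3, size_ceiling=32)


class TestPhenotypicFrequencies:
    def test_single_structure_lattice(self, suite):
        _, gp = suite[(2, 2)]
        fq = phenotypic_frequencies(gp)
        assert fq.scores[0] == 1.0
        assert fq.f_unfolded == 0.0

    @pytest.mark.parametrize("grid", [(2, 3), (3, 3), (2, 4), (4, 4)])
    def test_partition_of_unity(self, grid, suite):
        _, gp = suite[grid]
        fq = phenotypic_frequencies(gp)
        assert sum(fq.scores.values()) + fq.f_unfolded == pytest.approx(1.0, abs=1e-12)

    def test_2x3_counts_match_oracle(self, cat_2x3, gp_2x3):
        fq = phenotypic_frequencies(gp_2x3)
        counts = {}
        for seq in all_hp_sequences(6):
            counts[fold_direct(seq, cat_2x3)] = counts.get(fold_direct(seq, cat_2x3), 0) + 1
        for q in range(cat_2x3.n):
            assert fq.scores[q] == pytest.approx(counts.get(q, 0) / 64)


class TestPointMutants:
    def test_hp_sequence_has_L_mutants(self):
        muts = point_mutants("P" * 25, ("P", "H"))
        assert len(muts) == 25

    def test_rna_sequence_has_3L_mutants(self):
        muts = point_mutants("A" * 30, ("A", "C", "G", "U"))
        assert len(muts) == 90

    def test_hamming_distance_one_and_order(self):
        seq = "ACGU"
        muts = point_mutants(seq, ("A", "C", "G", "U"))
        assert len(muts) == len(set(muts)) == 12
        for m in muts:
            assert sum(a != b for a, b in zip(m, seq)) == 1
        assert muts[:3] == ["CCGU", "GCGU", "UCGU"]  # position-major, symbol order

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            point_mutants("AXGU", ("A", "C", "G", "U"))

    def test_mutant_codes_match_string_mutants(self):
        from boltzmap.core import code_to_seq, seq_to_code

        alphabet = ("A", "C", "G", "U")
        codes = np.array([seq_to_code("GAUC", alphabet)])
        mc = mutant_codes(codes, 4, 4)[0]
        expected = [seq_to_code(m, alphabet) for m in point_mutants("GAUC", alphabet)]
        assert list(mc) == expected


class TestPhiRow:
    def test_single_structure_robustness_is_one(self, suite):
        _, gp = suite[(2, 2)]
        row = phi_row(gp, 0)
        assert row.phi[0] == 1.0
        assert row.x == 16 and row.y == 4

    @pytest.mark.parametrize("grid", [(2, 3), (3, 3), (2, 4)])
    def test_rows_sum_to_one(self, grid, suite):
        _, gp = suite[grid]
        for p in gp.folding_phenotypes():
            row = phi_row(gp, int(p))
            assert row.total() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("grid", [(2, 3), (3, 3)])
    def test_matches_mutate_and_fold_oracle(self, grid, suite):
        cat, gp = suite[grid]
        for p in gp.folding_phenotypes():
            p = int(p)
            expected, x = phi_direct(p, cat)
            row = phi_row(gp, p)
            assert row.x == x
            for q, v in expected.items():
                assert row[q] == pytest.approx(v, abs=1e-12)

    def test_empty_neutral_set_raises(self, cat_2x3, gp_2x3):
        empty = [p for p in range(cat_2x3.n)
                 if p not in set(gp_2x3.folding_phenotypes())]
        assert empty  # 2x3 has a structure with an empty neutral set
        with pytest.raises(EmptyNeutralSetError):
            phi_row(gp_2x3, empty[0])

    def test_reversal_symmetry_on_2x4(self, cat_2x4, gp_2x4):
        """phi(p->q) equals phi between the reversal images of p and q."""
        rev = cat_2x4.reversal_map()
        for p in gp_2x4.folding_phenotypes():
            p = int(p)
            row = phi_row(gp_2x4, p)
            row_rev = phi_row(gp_2x4, int(rev[p]))
            for q, v in row.phi.items():
                q_img = q if q == UNFOLDED else int(rev[q])
                assert row_rev[q_img] == pytest.approx(v, abs=1e-12)


class TestPhiRowSampled:
    @staticmethod
    def _fold(cat):
        return lambda s: int(assign_mfe(s, cat))

    def test_full_neutral_set_equals_exact(self, cat_2x3, gp_2x3):
        from boltzmap.core import code_to_seq

        p = int(gp_2x3.folding_phenotypes()[0])
        sample = [code_to_seq(int(c), 6, ("P", "H")) for c in gp_2x3.neutral_set(p)]
        row = phi_row_sampled(sample, self._fold(cat_2x3), p, ("P", "H"))
        exact = phi_row(gp_2x3, p)
        for q, v in exact.phi.items():
            assert row[q] == pytest.approx(v, abs=1e-12)

    def test_500_draws_within_five_binomial_se(self, cat_2x3, gp_2x3):
        from boltzmap.core import code_to_seq

        rng = np.random.default_rng(11)
        p = int(gp_2x3.folding_phenotypes()[0])
        ns = gp_2x3.neutral_set(p)
        draw = rng.choice(ns, size=500, replace=True)
        sample = [code_to_seq(int(c), 6, ("P", "H")) for c in draw]
        row = phi_row_sampled(sample, self._fold(cat_2x3), p, ("P", "H"))
        exact = phi_row(gp_2x3, p)
        n = 500 * row.y
        for q, v in exact.phi.items():
            se = np.sqrt(max(v * (1 - v) / n, 1e-12))
            assert abs(row[q] - v) <= 5 * se + 1e-9

    def test_duplicated_sample_identical_row(self, cat_2x3, gp_2x3):
        from boltzmap.core import code_to_seq

        p = int(gp_2x3.folding_phenotypes()[0])
        sample = [code_to_seq(int(c), 6, ("P", "H")) for c in gp_2x3.neutral_set(p)]
        once = phi_row_sampled(sample, self._fold(cat_2x3), p, ("P", "H"))
        twice = phi_row_sampled(sample * 2, self._fold(cat_2x3), p, ("P", "H"))
        assert once.phi == twice.phi

    def test_foreign_sequence_rejected(self, cat_2x3, gp_2x3):
        p = int(gp_2x3.folding_phenotypes()[0])
        with pytest.raises(ValueError, match="does not fold"):
            phi_row_sampled(["P" * 6], self._fold(cat_2x3), p, ("P", "H"))


class TestCountFoldingStructures:
    def test_small_lattices(self, suite):
        assert count_folding_structures(suite[(2, 2)][1]) == 1
        cat, gp = suite[(2, 3)]
        oracle = len({fold_direct(s, cat) for s in all_hp_sequences(6)} - {-1})
        assert count_folding_structures(gp) == oracle
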
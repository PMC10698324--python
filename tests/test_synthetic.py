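"""Toy random-field landscapes, mock engines and the small-lattice suite."""
import numpy as np
import pytest

from boltzmap.core import UNFOLDED, PredictorScores
from boltzmap.compare import compare_predictors, summarize
from boltzmap.gpmap import phenotypic_frequencies, phi_row
from boltzmap.rna import EngineError
from boltzmap.synthetic import (make_mock_rna_engine, make_toy_landscape,
                                small_lattice_suite)


class TestToyLandscape:
    def test_zero_sigma_everything_unfolds(self):
        land = make_toy_landscape(2, 6, 5, sigma=0.0, kBT=0.5, seed=1)
        gp = land.build_gpmap()
        assert np.all(gp.assignment == UNFOLDED)
        f = land.frequency_matrix(np.arange(2**6))
        np.testing.assert_allclose(f, 1 / 5, atol=1e-12)

    def test_low_kbt_concentrates_on_mfe(self):
        land = make_toy_landscape(2, 6, 5, sigma=1.0, kBT=1e-3, seed=2)
        gp = land.build_gpmap()
        f = land.frequency_matrix(np.arange(2**6))
        for code in range(2**6):
            p = gp.assignment[code]
            if p != UNFOLDED:
                assert f[code, p] > 0.999

    def test_exact_stats_match_brute_force(self):
        """phi, pqp and fq on an (a=2, n=8, S=20) landscape agree with
        plain nested loops over sequences and structures."""
        land = make_toy_landscape(2, 8, 20, sigma=1.0, kBT=0.5, seed=3)
        gp = land.build_gpmap()
        codes = np.arange(2**8)

        # brute-force fold: per-sequence argmin with tie scan
        e = land.energy_matrix(codes)
        for code in codes:
            row = e[code]
            winners = np.flatnonzero(row == row.min())
            expected = int(winners[0]) if len(winners) == 1 else UNFOLDED
            assert gp.assignment[code] == expected

        # fq
        fq = phenotypic_frequencies(gp)
        for q in range(20):
            assert fq.scores[q] == pytest.approx(
                np.mean(gp.assignment == q), abs=1e-15)

        # phi for the largest neutral set, by explicit mutate-and-fold
        p = int(np.argmax(gp.neutral_set_sizes()))
        row = phi_row(gp, p)
        counts = {}
        for code in gp.neutral_set(p):
            for i in range(8):
                q = int(gp.assignment[int(code) ^ (1 << i)])
                counts[q] = counts.get(q, 0) + 1
        denom = len(gp.neutral_set(p)) * 8
        for q, c in counts.items():
            assert row[q] == pytest.approx(c / denom, abs=1e-12)

        # pqp by explicit loop
        f = land.frequency_matrix(gp.neutral_set(p))
        pqp_vec = f.mean(axis=0)
        ns = gp.neutral_set(p)
        manual = np.zeros(20)
        for code in ns:
            w = np.exp(-(e[code] - e[code].min()) / 0.5)
            manual += w / w.sum()
        manual /= len(ns)
        np.testing.assert_allclose(pqp_vec, manual, rtol=1e-12)

    def test_bit_identical_regeneration(self):
        a = make_toy_landscape(3, 5, 12, sigma=0.7, kBT=0.4, seed=9)
        b = make_toy_landscape(3, 5, 12, sigma=0.7, kBT=0.4, seed=9)
        np.testing.assert_array_equal(a.eps, b.eps)
        assert np.array_equal(a.build_gpmap().assignment, b.build_gpmap().assignment)

    def test_ceiling_enforced(self):
        with pytest.raises(ValueError, match="ceiling"):
            make_toy_landscape(4, 12, 5, sigma=1.0, kBT=0.5, seed=1)

    def test_congruence_gap_shrinks_toward_rugged(self):
        """The pqp predictor's capture advantage over fq is positive on a
        plastic landscape and decays as sigma/kBT grows (frozen, rugged limit)."""
        gaps = []
        for sigma in (2.0, 8.0, 32.0):
            land = make_toy_landscape(2, 10, 30, sigma=sigma, kBT=1.0, seed=20)
            gp = land.build_gpmap()
            fq = phenotypic_frequencies(gp)
            freq = land.frequency_matrix(np.arange(2**10))
            results = []
            for p in gp.folding_phenotypes():
                p = int(p)
                row = phi_row(gp, p)
                vec = freq[gp.neutral_set(p)].mean(axis=0)
                pqp = PredictorScores({int(q): float(v) for q, v in enumerate(vec)},
                                      "pqp", context=p)
                results.append(compare_predictors(row, fq, pqp, k=5))
            s = summarize(results)
            gaps.append(s["mean_capture_pqp"] - s["mean_capture_fq"])
        assert gaps[0] > 0
        assert gaps[0] > gaps[1] > gaps[2]


class TestMockEngine:
    TABLE = {
        "GGGAAACCCA": [("(((...))).", -3.0), (".((...))..", -1.4),
                       ("..........", 0.0)],
    }

    def test_window_filters_by_row_minimum(self):
        eng = make_mock_rna_engine(self.TABLE)
        assert eng.subopt("GGGAAACCCA", 0.02) == [("(((...))).", -3.0)]
        assert len(eng.subopt("GGGAAACCCA", 2.0)) == 2
        assert len(eng.subopt("GGGAAACCCA", 15.0)) == 3

    def test_unknown_sequence_distinct_error(self):
        eng = make_mock_rna_engine(self.TABLE)
        with pytest.raises(EngineError, match="no fixture"):
            eng.subopt("AAAAAAAAAA", 1.0)

    def test_pipeline_smoke_reproduces_hand_computed_phi(self):
        """A 2-letter, length-3 mock world where phi can be worked out by hand."""
        from boltzmap.gpmap import phi_row_sampled

        hairpin, open_ = "(.)", "..."  # toy labels; engine rows need no validation
        table = {}
        for seq in ("AAA", "AAG", "AGA", "AGG", "GAA", "GAG", "GGA", "GGG"):
            # fold by majority letter: >=2 G -> hairpin else open
            if seq.count("G") >= 2:
                table[seq] = [(hairpin, -2.0), (open_, 0.0)]
            else:
                table[seq] = [(open_, -1.0), (hairpin, 0.0)]
        eng = make_mock_rna_engine(table, validate=False)

        from boltzmap.rna import mfe_unique

        fold = lambda s: mfe_unique(s, eng)[0]
        neutral = [s for s in table if fold(s) == open_]
        row = phi_row_sampled(neutral, fold, open_, ("A", "G"))
        # by hand: the 4 sequences with <=1 G; of their 12 mutants, those
        # reaching 2 Gs switch: AAA -> 0/3; each single-G seq -> 2/3
        assert row.x == 4 and row.y == 3
        assert row[hairpin] == pytest.approx((0 + 2 + 2 + 2) / 12)
        assert row[open_] == pytest.approx(6 / 12)
        assert row.total() == pytest.approx(1.0)


class TestSmallLatticeSuite:
    def test_2x2_entry(self, suite):
        cat, gp = suite[(2, 2)]
        assert cat.n == 1
        assert gp.n_sequences == 16
        assert (gp.assignment != UNFOLDED).all()

    def test_frozen_counts(self, suite):
        """Regression freeze of catalogue sizes and folding-structure counts."""
        expected = {  # (grid) -> (catalogue size, structures with nonempty neutral set)
            (1, 2): (1, 1),
            (2, 2): (1, 1),
            (2, 3): (4, 3),
            (3, 3): (5, 5),
            (2, 4): (7, 6),
            (4, 4): (69, 69),
        }
        for grid, (n_cat, n_fold) in expected.items():
            cat, gp = suite[grid]
            assert cat.n == n_cat
            assert len(gp.folding_phenotypes()) == n_fold

    def test_disk_cache_round_trip(self, tmp_path):
        first = small_lattice_suite([(2, 3)], cache_dir=tmp_path)
        again = small_lattice_suite([(2, 3)], cache_dir=tmp_path)
        np.testing.assert_array_equal(first[(2, 3)][1].assignment,
                                      again[(2, 3)][1].assignment)
        assert (tmp_path / "gpmap_2x3.npy").exists()

    def test_corrupted_cache_rebuilt(self, tmp_path):
        import json

        small_lattice_suite([(2, 3)], cache_dir=tmp_path)
        meta = tmp_path / "gpmap_2x3.json"
        data = json.loads(meta.read_text())
        data["sha256"] = "0" * 64
        meta.write_text(json.dumps(data))
        rebuilt = small_lattice_suite([(2, 3)], cache_dir=tmp_path)
        ref = small_lattice_suite([(2, 3)])
        np.testing.assert_array_equal(rebuilt[(2, 3)][1].assignment,
                                      ref[(2, 3)][1].assignment)
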
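import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panmap import genome_stats as gs
from panmap import simulate
from panmap.io_formats import Hit, ValidationError


class TestWindowCounts:
    SEQ = {"c1": 5_000_000}
    CEN = {"c1": 2_500_000}

    def test_no_svs_all_zero(self):
        table = gs.window_sv_counts([], self.SEQ, self.CEN)
        assert (table["count"] == 0).all() and len(table) == 5

    def test_counts_conserved(self, rng):
        svs = [gs.SVRecord("c1", int(s), int(s) + 2000)
               for s in rng.integers(0, 4_900_000, 50)]
        table = gs.window_sv_counts(svs, self.SEQ, self.CEN)
        assert table["count"].sum() == 50

    def test_short_sv_excluded(self):
        svs = [gs.SVRecord("c1", 0, 999)]
        table = gs.window_sv_counts(svs, self.SEQ, self.CEN, min_len=1000)
        assert table["count"].sum() == 0

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValidationError):
            gs.window_sv_counts([gs.SVRecord("cX", 0, 5000)], self.SEQ,
                                self.CEN)

    def test_clustered_svs_give_negative_rho(self, rng):
        svs = simulate.simulate_clustered_svs(self.SEQ, self.CEN, 300, rng,
                                              decay_scale=1_000_000)
        table = gs.window_sv_counts(svs, self.SEQ, self.CEN, window=250_000)
        rho, p = gs.spearman(table["centromere_distance"], table["count"])
        assert rho < -0.5 and p < 0.01


def _rank_oracle(v):
    """Average ranks, coded independently of scipy."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert gs.spearman(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert gs.spearman(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tied_vectors_match_rank_formula_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0]
        y = [3.0, 3.0, 1.0, 5.0, 2.0, 6.0, 6.0]
        rho, _ = gs.spearman(x, y)
        rx, ry = _rank_oracle(x), _rank_oracle(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-9)

    def test_sign_flips_with_negated_y(self, rng):
        x, y = rng.random(20), rng.random(20)
        assert gs.spearman(x, y)[0] == pytest.approx(-gs.spearman(x, -y)[0])

    def test_constant_vector_undefined(self):
        rho, p = gs.spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)


class TestAssemblyGaps:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGTACGT", []),
        ("AC" + "N" * 12 + "GT", [(2, 14)]),
        ("N" * 5, []),
        ("N" * 10, [(0, 10)]),
        ("NNNNNNNNNNNNacgtnnnnnnnnnnnn", [(0, 12), (16, 28)]),
    ])
    def test_gap_detection(self, seq, expected):
        assert gs.find_assembly_gaps(seq, min_run=10) == expected


class TestGapHomologs:
    def test_forward_scenario_recovers_enclosed_interval(self):
        sc = simulate.simulate_gap_scenario(n_gaps=3,
                                            rng=np.random.default_rng(3))
        gaps = {f"gap{i}": ("ref1", 0, 100) for i in range(3)}
        homologs, rejected = gs.extract_gap_homologs(gaps, sc.flank_hits,
                                                     sc.target)
        assert rejected == {} and len(homologs) == 3
        for h in homologs:
            tgt_seq, lo, hi = sc.enclosed_intervals[h.gap_id]
            assert (h.target_seq, h.target_start, h.target_end) == \
                (tgt_seq, lo, hi)
            assert h.sequence == sc.target[tgt_seq][lo:hi]

    @staticmethod
    def _flank_hit(qid, subject, start, end):
        return Hit(query_id=qid, subject_id=subject, percent_identity=99,
                   align_len=abs(end - start) + 1, mismatches=0, gap_opens=0,
                   query_start=1, query_end=abs(end - start) + 1,
                   subject_start=start, subject_end=end, evalue=0.0,
                   bitscore=1000.0)

    def test_flanks_on_different_contigs_rejected(self):
        hits = [self._flank_hit("g_left", "t1", 1, 100),
                self._flank_hit("g_right", "t2", 1, 100)]
        homologs, rejected = gs.extract_gap_homologs(
            {"g": ("ref", 0, 10)}, hits, {"t1": "A" * 200, "t2": "A" * 200})
        assert homologs == [] and "different sequences" in rejected["g"]

    def test_span_exceeding_max_rejected(self):
        hits = [self._flank_hit("g_left", "t1", 1, 100),
                self._flank_hit("g_right", "t1", 1000, 1100)]
        _, rejected = gs.extract_gap_homologs({"g": ("ref", 0, 10)}, hits,
                                              {"t1": "A" * 1100},
                                              max_span=500)
        assert "exceeds max" in rejected["g"]

    def test_minus_strand_homolog_reverse_complemented(self):
        target = "G" * 100 + "ACGTTT" + "C" * 100
        # minus-strand flank hits: right flank upstream, left downstream
        hits = [self._flank_hit("g_left", "t1", 206, 107),
                self._flank_hit("g_right", "t1", 100, 1)]
        homologs, rejected = gs.extract_gap_homologs({"g": ("ref", 0, 10)},
                                                     hits, {"t1": target})
        assert rejected == {}
        (h,) = homologs
        assert (h.target_start, h.target_end) == (100, 106)
        assert h.sequence == "AAACGT"

    def test_inconsistent_order_rejected(self):
        hits = [self._flank_hit("g_left", "t1", 1000, 1100),
                self._flank_hit("g_right", "t1", 1, 100)]
        _, rejected = gs.extract_gap_homologs({"g": ("ref", 0, 10)}, hits,
                                              {"t1": "A" * 1100})
        assert "inconsistent order" in rejected["g"]


class TestHomotetramers:
    @pytest.mark.parametrize("seq,count", [
        ("ACGTACGT", 0),
        ("AAAA", 1),
        ("CAAAAAG", 2),      # run of 5 contributes 5 - 3 = 2
        ("NNNN", 0),
        ("aaaa", 1),         # case-insensitive
        ("AAAACCCC", 2),
    ])
    def test_overlapping_count(self, seq, count):
        assert gs.homotetramer_count(seq) == count

    def test_run_mode_counts_runs_once(self):
        assert gs.homotetramer_count("CAAAAAG", mode="runs") == 1
        assert gs.homotetramer_count("AAAACCCC", mode="runs") == 2

    def test_frequency_per_kbp(self):
        assert gs.homotetramer_frequency("AAAA" + "CGTA" * 249) == \
            pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            gs.homotetramer_frequency("")

    @settings(deadline=None, max_examples=100)
    @given(st.text(alphabet="ACGTN", max_size=60))
    def test_count_matches_brute_force_scan(self, seq):
        brute = sum(1 for i in range(max(0, len(seq) - 3))
                    if seq[i] != "N" and seq[i] == seq[i + 1] == seq[i + 2]
                    == seq[i + 3])
        assert gs.homotetramer_count(seq) == brute


def _mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumeration over all labelings (no ties)."""
    pooled = sorted(a + b)
    n_a = len(a)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    u_obs = u_stat(a, b)
    center = len(a) * len(b) / 2
    us = [u_stat(list(comb), [v for v in pooled if v not in comb])
          for comb in itertools.combinations(pooled, n_a)]
    p = np.mean([abs(u - center) >= abs(u_obs - center) for u in us])
    return u_obs, float(p)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = gs.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_p_near_one(self):
        _, p = gs.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p > 0.99

    def test_exact_p_matches_enumeration(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0]
        u, p = gs.mann_whitney_u(a, b)
        u_o, p_o = _mwu_enumeration_oracle(a, b)
        assert u == pytest.approx(u_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_exact_p_matches_enumeration_separated(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]
        u, p = gs.mann_whitney_u(a, b)
        u_o, p_o = _mwu_enumeration_oracle(a, b)
        assert u == pytest.approx(u_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_u_sum_identity_without_ties(self, rng):
        a = list(rng.permutation(40)[:15].astype(float))
        b = [v + 0.5 for v in rng.permutation(40)[:12].astype(float)]
        u_a, _ = gs.mann_whitney_u(a, b)
        u_b, _ = gs.mann_whitney_u(b, a)
        assert u_a + u_b == len(a) * len(b)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            gs.mann_whitney_u([], [1.0])


class TestControlSequences:
    ASSEMBLY = {"c1": "ACGT" * 2500, "c2": "TTTTTTTTGG" * 500 + "N" * 50
                + "ACGT" * 1000}

    def test_empty_lengths(self, rng):
        assert gs.sample_control_sequences(self.ASSEMBLY, [], rng) == []

    def test_deterministic_under_seed(self):
        picks1 = gs.sample_control_sequences(self.ASSEMBLY, [100, 200, 300],
                                             np.random.default_rng(9))
        picks2 = gs.sample_control_sequences(self.ASSEMBLY, [100, 200, 300],
                                             np.random.default_rng(9))
        assert picks1 == picks2

    def test_picks_avoid_n_runs(self, rng):
        picks = gs.sample_control_sequences(self.ASSEMBLY, [500] * 20, rng)
        assert all("N" not in p for p in picks)

    def test_picks_avoid_excluded_intervals(self, rng):
        exclude = {"c1": [(0, 9000)], "c2": [(0, 11000)]}
        picks = gs.sample_control_sequences(self.ASSEMBLY, [400] * 10, rng,
                                            exclude=exclude)
        # only c1's tail [9000, 10000) and c2's tail are available: verify by
        # content (c1 tail is ACGT-periodic, c2 tail too)
        assert all(set(p) <= set("ACGT") for p in picks)

    def test_impossible_length_rejected(self, rng):
        with pytest.raises(ValidationError):
            gs.sample_control_sequences({"c1": "ACGT"}, [1000], rng,
                                        max_tries=20)
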
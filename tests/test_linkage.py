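import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panmap import linkage, simulate
from panmap.io_formats import read_agp, write_agp
from panmap.linkage import GenotypeMatrix, Marker


# --- independent oracle: grid search over the 9-class F2 likelihood --------

def _f2_class_probs_oracle(r):
    """3x3 genotype-pair probabilities by gamete enumeration."""
    gametes = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2,
               (0, 1): r / 2, (1, 0): r / 2}
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in gametes.items():
        for (a2, b2), p2 in gametes.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


def _grid_search_rf(calls_1, calls_2, grid=None):
    calls_1, calls_2 = np.asarray(calls_1), np.asarray(calls_2)
    ok = (calls_1 != -1) & (calls_2 != -1)
    counts = np.zeros((3, 3))
    np.add.at(counts, (calls_1[ok], calls_2[ok]), 1)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 1001)
    best_r, best_ll = 0.0, -np.inf
    for r in grid:
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(_f2_class_probs_oracle(r))
        mask = counts > 0
        ll = -np.inf if np.any(np.isneginf(lp[mask])) else \
            float((counts[mask] * lp[mask]).sum())
        if ll > best_ll:
            best_r, best_ll = r, ll
    # fold a repulsion-phase maximum into [0, 0.5]
    return min(best_r, 1.0 - best_r)


def _random_calls(rng, n, missing=0.0):
    c = rng.integers(0, 3, size=n).astype(np.int8)
    if missing:
        c[rng.random(n) < missing] = -1
    return c


class TestEstimateRF:
    def test_cosegregating_markers_give_zero(self):
        calls = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2], dtype=np.int8)
        est = linkage.estimate_rf(calls, calls)
        assert est.r_hat == 0.0 and not est.degenerate

    def test_unlinked_markers_near_half(self, rng):
        markers = [Marker("m1", "c1", 0, "LG1", 0.0),
                   Marker("m2", "c2", 0, "LG2", 0.0)]
        gm, _ = simulate.simulate_f2_population(markers, 2000, 0.0, rng)
        est = linkage.estimate_rf(gm.codes[:, 0], gm.codes[:, 1])
        se = np.sqrt(0.25 / (2 * 2000))
        assert est.r_hat >= 0.5 - 3 * se   # clamped at 0.5 from below

    def test_toy_table_matches_grid_search(self):
        c1 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 1], dtype=np.int8)
        c2 = np.array([0, 0, 1, 1, 1, 2, 2, 2, 1, 0], dtype=np.int8)
        est = linkage.estimate_rf(c1, c2)
        assert abs(est.r_hat - _grid_search_rf(c1, c2)) <= 1e-3

    def test_monomorphic_marker_degenerate(self):
        mono = np.zeros(20, dtype=np.int8)
        poly = np.array([0, 1, 2] * 6 + [0, 1], dtype=np.int8)
        est = linkage.estimate_rf(mono, poly)
        assert est.degenerate and est.r_hat == 0.0 and est.n_informative == 20

    def test_missing_calls_excluded(self):
        c1 = np.array([0, 0, 2, -1], dtype=np.int8)
        c2 = np.array([0, 0, 2, 1], dtype=np.int8)
        assert linkage.estimate_rf(c1, c2).n_informative == 3

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_em_matches_grid_search_and_allele_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = _random_calls(rng, 60, 0.1), _random_calls(rng, 60, 0.1)
        est = linkage.estimate_rf(c1, c2)
        assert 0.0 <= est.r_hat <= 0.5
        if not est.degenerate:
            assert abs(est.r_hat - _grid_search_rf(c1, c2)) <= 1e-3
        swapped = np.where(c1 == -1, -1, 2 - c1).astype(np.int8)
        # agreement is bounded by the EM convergence tolerance (1e-6)
        assert linkage.estimate_rf(swapped, c2).r_hat == \
            pytest.approx(est.r_hat, abs=2e-6)

    def test_phase_unambiguous_counting_statistics(self):
        # 4 plants: (0,0) no rec; (0,1) one rec gamete; (1,1) ambiguous; (0,2)
        c1 = np.array([0, 0, 1, 0], dtype=np.int8)
        c2 = np.array([0, 1, 1, 2], dtype=np.int8)
        est = linkage.estimate_rf(c1, c2)
        assert est.rec_gametes == 3           # 0 + 1 + 2
        assert est.n_gametes_unambiguous == 6
        assert est.rec_plants == 2


class TestRFMatrix:
    def test_symmetric_zero_diagonal_consistent(self, rng):
        markers = simulate.simulate_marker_map(
            n_linkage_groups=1, contigs_per_group=2,
            rng=np.random.default_rng(0)).markers
        gm, _ = simulate.simulate_f2_population(markers, 300, 0.05, rng)
        rf = linkage.rf_matrix(gm)
        np.testing.assert_array_equal(rf.values, rf.values.T)
        assert np.all(np.diag(rf.values) == 0)
        est = linkage.estimate_rf(gm.codes[:, 0], gm.codes[:, 3])
        assert rf.iloc[0, 3] == pytest.approx(est.r_hat)

    def test_identical_markers_off_diagonal_zero(self):
        codes = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        gm = GenotypeMatrix(["p1", "p2", "p3", "p4"],
                            [Marker("m1", "c1", 0), Marker("m2", "c1", 5)],
                            codes)
        assert linkage.rf_matrix(gm).iloc[0, 1] == 0.0


def _as_order(placements):
    out = {}
    for p in sorted(placements, key=lambda p: (p.linkage_group, p.order_index)):
        out.setdefault(p.linkage_group, []).append((p.contig_id, p.orientation))
    return out


def _mirror(order):
    return [(c, {"+": "-", "-": "+"}.get(o, o)) for c, o in reversed(order)]


class TestGroupingOrdering:
    def test_unlinked_contigs_separate_groups(self):
        import pandas as pd
        ids = ["m1", "m2", "m3"]
        rf = pd.DataFrame(0.5 * (1 - np.eye(3)), index=ids, columns=ids)
        groups, unplaced = linkage.cluster_linkage_groups(
            rf, {"m1": "c1", "m2": "c2", "m3": "c3"})
        assert groups == [["c1"], ["c2"], ["c3"]] and unplaced == []

    def test_single_linkage_chains(self):
        import pandas as pd
        ids = ["m1", "m2", "m3"]
        mat = np.array([[0, 0.05, 0.5], [0.05, 0, 0.05], [0.5, 0.05, 0]])
        rf = pd.DataFrame(mat, index=ids, columns=ids)
        groups, _ = linkage.cluster_linkage_groups(
            rf, {"m1": "c1", "m2": "c2", "m3": "c3"})
        assert groups == [["c1", "c2", "c3"]]

    def test_contig_without_marker_reported_unplaced(self):
        import pandas as pd
        rf = pd.DataFrame([[0.0]], index=["m1"], columns=["m1"])
        _, unplaced = linkage.cluster_linkage_groups(
            rf, {"m1": "c1", "mX": "cX"})
        # cX's marker is absent from the rf matrix (never genotyped)
        assert unplaced == ["cX"]

    def test_minimal_path_order(self):
        import pandas as pd
        ids = ["m1", "m2", "m3"]
        mat = np.array([[0, 0.05, 0.15], [0.05, 0, 0.05], [0.15, 0.05, 0]])
        rf = pd.DataFrame(mat, index=ids, columns=ids)
        markers = [Marker("m1", "c1", 0), Marker("m2", "c2", 0),
                   Marker("m3", "c3", 0)]
        placements = linkage.order_and_orient(["c1", "c2", "c3"], rf, markers)
        assert [p.contig_id for p in placements] == ["c1", "c2", "c3"]

    def test_single_marker_contig_orientation_unknown(self, rng):
        mt = simulate.simulate_marker_map(n_linkage_groups=1,
                                          contigs_per_group=3,
                                          markers_per_contig=1,
                                          rng=np.random.default_rng(2))
        gm, _ = simulate.simulate_f2_population(mt.markers, 400, 0.0, rng)
        placements, _, _ = linkage.anchor_contigs(gm)
        assert all(p.orientation == "?" for p in placements)

    def test_simulated_map_recovered_up_to_mirror(self, rng):
        mt = simulate.simulate_marker_map(rng=np.random.default_rng(42))
        gm, _ = simulate.simulate_f2_population(mt.markers, 1000, 0.05, rng)
        placements, unplaced, _ = linkage.anchor_contigs(gm)
        assert unplaced == []
        got = _as_order(placements)
        assert len(got) == len(mt.contig_order)
        matched = 0
        for order in got.values():
            contigs = {c for c, _ in order}
            truth = next(t for t in mt.contig_order.values()
                         if {c for c, _ in t} == contigs)
            assert order == truth or order == _mirror(truth)
            matched += 1
        assert matched == 3


class TestPseudochromosomes:
    def _placement(self, cid, idx, orient, lg="LG1"):
        return linkage.ContigPlacement(cid, lg, idx, orient)

    def test_single_plus_contig_unchanged(self):
        fasta, _ = linkage.build_pseudochromosomes(
            [self._placement("c1", 0, "+")], {"c1": "ACGTT"})
        assert fasta == {"LG1": "ACGTT"}

    def test_single_minus_contig_reverse_complemented(self):
        fasta, _ = linkage.build_pseudochromosomes(
            [self._placement("c1", 0, "-")], {"c1": "ACGTT"})
        assert fasta == {"LG1": "AACGT"}

    def test_two_contigs_gap_arithmetic(self):
        seqs = {"c1": "A" * 1000, "c2": "C" * 1000}
        fasta, agp = linkage.build_pseudochromosomes(
            [self._placement("c1", 0, "+"), self._placement("c2", 1, "+")],
            seqs)
        assert len(fasta["LG1"]) == 2100
        assert fasta["LG1"][1000:1100] == "N" * 100

    def test_reference_polarity_mirrors_group(self):
        seqs = {"c1": "AAAA", "c2": "CCCC"}
        plc = [self._placement("c1", 0, "+"), self._placement("c2", 1, "+")]
        fasta, _ = linkage.build_pseudochromosomes(
            plc, seqs, gap_length=2, reference_polarity={"LG1": "-"})
        assert fasta["LG1"] == "GGGG" + "NN" + "TTTT"

    def test_agp_reconstructs_fasta_byte_identical(self, rng):
        seqs = {f"c{i}": simulate.random_sequence(200, rng) for i in range(4)}
        plc = [self._placement(f"c{i}", i, o)
               for i, o in enumerate("+-+-")]
        fasta, agp = linkage.build_pseudochromosomes(plc, seqs, gap_length=37)
        assert linkage.reconstruct_from_agp(agp, seqs) == fasta
        buf = io.StringIO()
        write_agp(agp, buf)
        buf.seek(0)
        assert linkage.reconstruct_from_agp(read_agp(buf), seqs) == fasta

    def test_missing_contig_sequence_rejected(self):
        with pytest.raises(Exception, match="missing sequence"):
            linkage.build_pseudochromosomes([self._placement("c9", 0, "+")],
                                            {})


def _yates_chi2_oracle(x1, n1, x2, n2):
    """Independently coded 2x2 Yates chi-square (classic a,b,c,d formula)."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n = a + b + c + d
    num = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    from scipy.stats import chi2
    stat = num / den
    return stat, float(chi2.sf(stat, 1))


class TestProportionTest:
    def test_equal_proportions_without_correction(self):
        chi2, p = linkage.compare_recombination_rates(10, 100, 20, 200,
                                                      correction=False)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_identical_counts_p_one_with_correction(self):
        chi2, p = linkage.compare_recombination_rates(5, 100, 5, 100)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_independent_yates_oracle(self):
        stat, p = linkage.compare_recombination_rates(1, 60, 16, 108)
        stat_o, p_o = _yates_chi2_oracle(1, 60, 16, 108)
        assert stat == pytest.approx(stat_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)
        # reference values from R 4.3.3: prop.test(c(1,16), c(60,108))
        assert stat == pytest.approx(5.957, abs=5e-4)
        assert p == pytest.approx(0.01466, abs=5e-6)

    def test_matches_scipy_contingency_cross_check(self):
        from scipy.stats import chi2_contingency
        res = chi2_contingency(np.array([[1, 59], [16, 92]]), correction=True)
        stat, p = linkage.compare_recombination_rates(1, 60, 16, 108)
        assert stat == pytest.approx(res.statistic, abs=1e-9)
        assert p == pytest.approx(res.pvalue, abs=1e-9)

    def test_zero_n_rejected(self):
        with pytest.raises(Exception):
            linkage.compare_recombination_rates(0, 0, 1, 10)


class TestGenotypeMatrixIO:
    def test_tsv_round_trip(self, rng):
        markers = [Marker("m1", "c1", 0, "LG1", 0.0),
                   Marker("m2", "c1", 50, "LG1", 12.0)]
        gm, _ = simulate.simulate_f2_population(markers, 30, 0.2, rng)
        buf = io.StringIO()
        gm.write_tsv(buf)
        buf.seek(0)
        back = GenotypeMatrix.read_tsv(buf, markers)
        np.testing.assert_array_equal(back.codes, gm.codes)
        assert back.plants == gm.plants
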
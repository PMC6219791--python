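import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from erclust.reads_io import GenomeModel, build_bins, shift_reads
from erclust.window_engine import (
    CallerParams,
    build_initial_windows,
    by_qvalues,
    call_ers,
    compute_summit,
    max_allowed_candidates,
    merged_significant_windows,
    optimize_max_allowed_length,
    poisson_p,
    report_region,
    select_final_window,
    step_windows,
    training_chromosomes,
    window_background,
    window_stats,
)

from conftest import make_readset
from _oracle import bf_call_ers


class TestPoissonP:
    def test_zero_count(self):
        assert poisson_p(0, 5.0) == 1.0

    def test_one_count_closed_form(self):
        assert poisson_p(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_pmf_sum_oracle(self):
        # P(X >= 20 | lam=10) by summing pmf terms upward
        expected = sum(stats.poisson.pmf(k, 10.0) for k in range(20, 200))
        assert poisson_p(20, 10.0) == pytest.approx(expected, rel=1e-9)
        assert poisson_p(20, 10.0) == pytest.approx(3.45e-3, rel=0.01)

    @given(st.integers(0, 100), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_sf(self, r, lam):
        assert poisson_p(r, lam) == pytest.approx(
            float(stats.poisson.sf(r - 1, lam)), rel=1e-9, abs=1e-300
        )


class TestWindowBackground:
    def test_forced_max(self):
        assert window_background(5, 1000, 0.01, 2.0) == 10.0

    def test_no_control(self):
        assert window_background(0, 1000, 0.01, None) == 10.0

    def test_control_dominates(self):
        assert window_background(50, 1000, 0.01, 2.0) == 100.0


class TestByQvalues:
    def test_single(self):
        assert by_qvalues([0.01])[0] == pytest.approx(0.01)

    def test_two_manual(self):
        # q_i = p_(i) * m * c(m) / i with monotone enforcement, c(2)=1.5
        np.testing.assert_allclose(by_qvalues([0.01, 0.04]), [0.03, 0.06])

    @given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels_and_dominates_p(self, ps):
        q = by_qvalues(ps)
        np.testing.assert_allclose(q, multipletests(ps, method="fdr_by")[1], rtol=1e-10)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)


class TestInitialWindows:
    def test_enumeration_25_bins(self):
        pos = list(np.cumsum([10] * 26))
        rs = make_readset({"chr1": [(p, 1) for p in pos]})
        wins = list(build_initial_windows(build_bins(rs), n_bins=20))
        # one window per start bin; the first 6 are full 20-bin windows
        assert len(wins) == 25
        full = [w for w in wins if w[2] - w[1] + 1 == 20]
        assert [w[1] for w in full] == list(range(6))
        # trailing windows keep their actual span
        assert wins[-1] == ("chr1", 24, 24)

    def test_single_bin_chromosome_skipped(self):
        rs = make_readset({"chr1": [(0, 1), (5, 1)]})
        assert list(build_initial_windows(build_bins(rs), 20)) == []

    def test_bad_n_bins(self):
        rs = make_readset({"chr1": [(0, 1), (5, 1), (9, 1)]})
        with pytest.raises(ValueError):
            list(build_initial_windows(build_bins(rs), 1))


class TestStepWindows:
    def test_count(self):
        lengths = [5] * 10
        assert len(step_windows(0, 9, lengths, max_allowed=100)) == 10

    def test_interior_oversized_bin(self):
        lengths = [5, 5, 5, 200, 5, 5]
        out = step_windows(0, 5, lengths, max_allowed=100)
        assert out == [(4, 5), (5, 5)]

    def test_all_retained(self):
        lengths = [5, 6, 7]
        assert len(step_windows(0, 2, lengths, max_allowed=100)) == 3

    def test_boundary_equal_excluded(self):
        lengths = [100]
        assert step_windows(0, 0, lengths, max_allowed=100) == []


class TestSelectFinalWindow:
    def _rec(self, first, last, p, pos):
        return window_stats("chr1", first, last, pos, None, 0.001, None)

    def test_single(self):
        pos = np.array([0, 10, 20], dtype=np.int64)
        w = self._rec(0, 1, 0.5, pos)
        assert select_final_window([w]) is w

    def test_min_p_wins(self):
        # dense suffix vs sparse full window
        pos = np.array([0, 500, 502, 504, 506], dtype=np.int64)
        wins = [
            window_stats("chr1", s, 3, pos, None, 0.001, None) for s in range(4)
        ]
        best = select_final_window(wins)
        assert best.first_bin == 1  # starts at the dense run

    def test_tie_longer_wins(self):
        pos = np.array([0, 10, 20, 30], dtype=np.int64)
        wins = [window_stats("chr1", s, 2, pos, None, 0.001, None) for s in (0, 1)]
        wins[1].p = wins[0].p  # force a tie
        assert select_final_window(wins).first_bin == 0


class TestMaxAllowedCandidates:
    def test_first_candidate_fifth_of_shift(self):
        assert max_allowed_candidates(100)[0] == 20

    def test_ten_candidates_to_double_shift(self):
        cands = max_allowed_candidates(100)
        assert len(cands) == 10
        assert cands[-1] == 200

    def test_optimizer_returned_param_satisfies_criterion(self, peak_sim):
        config, case, control, _ = peak_sim
        genome = GenomeModel(config.chrom_sizes)
        cs = shift_reads(case, 100, genome)
        xs = shift_reads(control, 100, genome)
        ma = optimize_max_allowed_length(cs, xs, genome, 100)
        scan = merged_significant_windows(
            cs, xs, genome, 20, ma, chroms=training_chromosomes(genome, cs.chroms)
        )
        lens = scan.merged_lengths
        assert float(np.mean(lens > 200)) >= 0.80

    def test_pure_background_exhausts(self, five_chrom_genome):
        rng = np.random.default_rng(5)
        reads = make_readset(
            {
                c: [(int(p), 1) for p in rng.integers(0, 500_000, 4000)]
                for c in five_chrom_genome.chrom_sizes
            }
        )
        assert optimize_max_allowed_length(reads, None, five_chrom_genome, 100) == 200


class TestComputeSummit:
    def test_single_read_leftmost(self):
        pos = np.array([100], dtype=np.int64)
        assert compute_summit(0, 300, pos, 50) == 50

    def test_symmetric_cluster_center(self):
        pos = np.array([90, 95, 100, 105, 110], dtype=np.int64)
        s = compute_summit(0, 300, pos, 50)
        assert abs(s - 60) <= 1  # leftmost point where all five overlap

    def test_empty_region_midpoint(self):
        pos = np.array([], dtype=np.int64)
        assert compute_summit(100, 300, pos, 50) == 200


class TestReportRegion:
    def _genome(self):
        return GenomeModel(chrom_sizes={"chr1": 1_000_000})

    def _setup(self, l_er, d_er, d_1kb, d_10kb):
        """Place control reads to realize the requested densities exactly."""
        genome = self._genome()
        start = 500_000
        end = start + l_er
        center = (start + end) // 2
        reads = []
        n_er = int(round(d_er * l_er))
        reads += list(np.linspace(start, end - 1, n_er).astype(int))
        # extra reads outside the region but inside the 1kb / 10kb windows
        n_1kb = int(round(d_1kb * 1000))
        n_10kb = int(round(d_10kb * 10_000))
        w1_lo, w1_hi = center - 500, center + 500
        w10_lo, w10_hi = center - 5000, center + 5000
        placed = n_er

        def fill(n, lo, hi, avoid):
            out = []
            span = np.linspace(lo, hi - 1, max(n, 1)).astype(int)
            for p in span[:n]:
                if not (avoid[0] <= p < avoid[1]):
                    out.append(p)
            return out

        reads += fill(max(0, n_1kb - placed), w1_lo, w1_hi, (start, end))
        reads += fill(max(0, n_10kb - len(reads)), w10_lo, w10_hi, (start, end))
        ctrl = make_readset({"chr1": [(int(p), 1) for p in sorted(reads)]})
        case = make_readset({"chr1": [(start + 5, 1), (start + 10, 1)]})
        return genome, case, ctrl, start, end

    def test_piecewise_small_region(self):
        genome = self._genome()
        case = make_readset({"chr1": [(500_100, 1)]})
        ctrl_reads = [(500_000 + i * 50, 1) for i in range(10)]  # dense near region
        ctrl = make_readset({"chr1": ctrl_reads})
        er = report_region("chr1", 500_000, 500_500, case, ctrl, genome, 50)
        # l <= 1kb: all three densities participate
        assert er.d_local == max(er.d_er, er.d_1kb, er.d_10kb)

    def test_piecewise_mid_region(self):
        genome = self._genome()
        case = make_readset({"chr1": [(500_100, 1)]})
        ctrl = make_readset({"chr1": [(500_000 + i * 100, 1) for i in range(30)]})
        er = report_region("chr1", 500_000, 505_000, case, ctrl, genome, 50)
        assert math.isnan(er.d_1kb)
        assert er.d_local == max(er.d_er, er.d_10kb)

    def test_piecewise_large_region(self):
        genome = self._genome()
        case = make_readset({"chr1": [(500_100, 1)]})
        ctrl = make_readset({"chr1": [(500_000 + i * 100, 1) for i in range(150)]})
        er = report_region("chr1", 500_000, 520_000, case, ctrl, genome, 50)
        assert er.d_local == er.d_er

    def test_fc_definition(self):
        genome = self._genome()
        case = make_readset({"chr1": [(500_000 + i, 1) for i in range(40)]})
        er = report_region("chr1", 500_000, 500_100, case, None, genome, 50)
        assert er.fc == pytest.approx(er.r_case / er.background)

    def test_monotone_in_added_reads(self):
        # adding case reads inside a fixed region never increases its p
        genome = self._genome()
        base = [(500_000 + 7 * i, 1) for i in range(30)]
        last_p = 1.1
        for extra in (0, 10, 20, 40):
            reads = base + [(500_050 + i, 1) for i in range(extra)]
            case = make_readset({"chr1": reads})
            er = report_region("chr1", 500_000, 500_300, case, None, genome, 50)
            assert er.p <= last_p + 1e-15
            last_p = er.p


class TestCallErs:
    def test_recall_precision_on_sim(self, peak_sim):
        from erclust.synthetic_data import truth_eval

        config, case, control, truth = peak_sim
        genome = GenomeModel(config.chrom_sizes)
        cs = shift_reads(case, 100, genome)
        xs = shift_reads(control, 100, genome)
        ma = optimize_max_allowed_length(cs, xs, genome, 100)
        ers = call_ers(cs, xs, genome, CallerParams(maximum_allowed_length=ma), 100)
        precision, recall = truth_eval(ers, truth.labeled("peak"))
        assert recall >= 0.9
        assert precision >= 0.9

    def test_reported_ers_sorted_disjoint_significant(self, peak_sim):
        config, case, control, _ = peak_sim
        genome = GenomeModel(config.chrom_sizes)
        cs = shift_reads(case, 100, genome)
        xs = shift_reads(control, 100, genome)
        params = CallerParams(maximum_allowed_length=40)
        ers = call_ers(cs, xs, genome, params, 100)
        assert all(e.q < params.q_threshold for e in ers)
        by_chrom = {}
        for e in ers:
            by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
            assert e.start <= e.summit < e.end
        for regions in by_chrom.values():
            assert regions == sorted(regions)
            assert all(a[1] <= b[0] for a, b in zip(regions, regions[1:]))

    def test_case_equals_control_no_calls(self, peak_sim):
        config, _, control, _ = peak_sim
        genome = GenomeModel(config.chrom_sizes)
        xs = shift_reads(control, 100, genome)
        scan = merged_significant_windows(xs, xs, genome, 20, 200)
        assert scan.n_significant <= max(1, 0.001 * scan.n_final_windows)

    def test_null_calibration(self, peak_sim):
        # case drawn from the control (background) distribution
        config, _, control, _ = peak_sim
        genome = GenomeModel(config.chrom_sizes)
        rng = np.random.default_rng(123)
        null_case = make_readset(
            {
                c: [(int(p), 1) for p in rng.integers(0, s, 15_000)]
                for c, s in config.chrom_sizes.items()
            }
        )
        xs = shift_reads(control, 100, genome)
        scan = merged_significant_windows(null_case, xs, genome, 20, 200)
        assert scan.n_significant / max(scan.n_final_windows, 1) <= 0.05

    def test_unset_max_allowed_raises(self, small_genome):
        rs = make_readset({"chr1": [(i * 10, 1) for i in range(50)]})
        with pytest.raises(ValueError):
            call_ers(rs, None, small_genome, CallerParams(), 100)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_instances_match_bruteforce(self, seed, small_genome):
        rng = np.random.default_rng(seed)
        reads = []
        # a couple of dense clumps + background, <= 200 reads total
        for center in rng.integers(10_000, 90_000, size=3):
            reads += [int(center + x) for x in rng.integers(-150, 150, size=40)]
        reads += [int(p) for p in rng.integers(0, 100_000, size=60)]
        case = make_readset({"chr1": [(p, 1) for p in sorted(reads)]})
        ctrl = make_readset(
            {"chr1": [(int(p), 1) for p in sorted(rng.integers(0, 100_000, size=150))]}
        )
        params = CallerParams(maximum_allowed_length=120, initial_window_bins=10)
        ours = [
            (e.chrom, e.start, e.end)
            for e in call_ers(case, ctrl, small_genome, params, 50)
        ]
        theirs = bf_call_ers(case, ctrl, small_genome, n_bins=10, max_allowed=120)
        assert ours == theirs

    def test_no_control_matches_bruteforce(self, small_genome):
        rng = np.random.default_rng(9)
        reads = [int(50_000 + x) for x in rng.integers(-100, 100, size=80)]
        reads += [int(p) for p in rng.integers(0, 100_000, size=100)]
        case = make_readset({"chr1": [(p, 1) for p in sorted(reads)]})
        params = CallerParams(maximum_allowed_length=150, initial_window_bins=20)
        ours = [
            (e.chrom, e.start, e.end)
            for e in call_ers(case, None, small_genome, params, 50)
        ]
        theirs = bf_call_ers(case, None, small_genome, n_bins=20, max_allowed=150)
        assert ours == theirs
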
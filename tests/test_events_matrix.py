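"""Event filtering, fragment assignment, binning and subsampling."""
import numpy as np
import pandas as pd
import pytest

from hicforge.contacts import (
    FragmentMap,
    assign_fragments,
    bin_matrix,
    filter_events,
    filter_outliers,
    rebin,
    subsample,
)


def ev(rows, extra_cols=()):
    cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", *extra_cols]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def two_fragment_map():
    return FragmentMap({"chr1": np.array([0, 400, 800])})


class TestAssignFragments:
    def test_basic_assignment(self, two_fragment_map):
        events = ev([("chr1", 100, "+", "chr1", 500, "-")])
        out = assign_fragments(events, two_fragment_map)
        assert (out.frag1[0], out.frag2[0]) == (0, 1)
        assert not out.intra_fragment[0]

    def test_intra_fragment_flagged(self, two_fragment_map):
        events = ev([("chr1", 10, "+", "chr1", 390, "+")])
        out = assign_fragments(events, two_fragment_map)
        assert out.intra_fragment[0]

    def test_out_of_bounds_rejected(self, two_fragment_map):
        events = ev([("chr1", 100, "+", "chr1", 900, "-")])
        with pytest.raises(ValueError, match="outside"):
            assign_fragments(events, two_fragment_map)

    def test_multinomial_proportions(self, two_fragment_map, rng):
        """Uniform pairs over two equal fragments land on (0,0)/(0,1)/(1,1)
        with probabilities 1/4, 1/2, 1/4."""
        n = 40_000
        p1, p2 = rng.integers(0, 800, n), rng.integers(0, 800, n)
        events = ev(
            list(zip(["chr1"] * n, np.minimum(p1, p2), ["+"] * n,
                     ["chr1"] * n, np.maximum(p1, p2), ["+"] * n))
        )
        out = assign_fragments(events, two_fragment_map)
        combos = out.groupby(["frag1", "frag2"]).size() / n
        assert combos[(0, 0)] == pytest.approx(0.25, abs=0.02)
        assert combos[(0, 1)] == pytest.approx(0.50, abs=0.02)
        assert combos[(1, 1)] == pytest.approx(0.25, abs=0.02)


class TestFilterEvents:
    def test_short_outward_dropped_both_modes(self):
        e = ev([("chr1", 100, "-", "chr1", 900, "+")])
        assert len(filter_events(e, "matrix")) == 0
        assert len(filter_events(e, "ps")) == 0

    def test_short_tandem_kept_matrix_dropped_ps(self):
        e = ev([("chr1", 100, "+", "chr1", 900, "+")])
        assert len(filter_events(e, "matrix")) == 1
        assert len(filter_events(e, "ps")) == 0

    def test_long_inward_kept_matrix_dropped_ps(self):
        e = ev([("chr1", 100, "+", "chr1", 9000, "-")])
        assert len(filter_events(e, "matrix")) == 1
        assert len(filter_events(e, "ps")) == 0

    def test_trans_always_kept(self):
        e = ev([("chr1", 100, "-", "chr2", 200, "+")])
        assert len(filter_events(e, "matrix")) == 1
        assert len(filter_events(e, "ps")) == 1

    def test_intra_fragment_dropped_in_matrix_mode(self, two_fragment_map):
        e = assign_fragments(ev([("chr1", 10, "+", "chr1", 40, "+")]),
                             two_fragment_map)
        assert len(filter_events(e, "matrix")) == 0


class TestBinMatrix:
    def test_positions_to_bins(self):
        e = ev([("chr1", 100, "+", "chr1", 7000, "+")] * 3)
        mat = bin_matrix(e, bin_size=5000, chroms=[("chr1", 10_000)])
        assert mat.counts[0, 1] == 3 and mat.counts[1, 0] == 3
        assert mat.total_contacts == 3

    def test_empty_events_zero_matrix(self):
        e = ev([])
        mat = bin_matrix(e, bin_size=1000, chroms=[("chr1", 5000)])
        assert mat.counts.sum() == 0 and mat.n == 5

    def test_symmetry_and_total_conservation(self, rng):
        n = 5000
        p1 = rng.integers(0, 50_000, n)
        p2 = rng.integers(0, 50_000, n)
        e = ev(list(zip(["c"] * n, np.minimum(p1, p2), ["+"] * n,
                        ["c"] * n, np.maximum(p1, p2), ["+"] * n)))
        mat = bin_matrix(e, bin_size=1000, chroms=[("c", 50_000)])
        assert np.allclose(mat.counts, mat.counts.T)
        assert np.triu(mat.counts).sum() == n

    def test_rebin_equals_block_sum(self, rng):
        n = 3000
        p1 = rng.integers(0, 40_000, n)
        p2 = rng.integers(0, 40_000, n)
        e = ev(list(zip(["c"] * n, np.minimum(p1, p2), ["+"] * n,
                        ["c"] * n, np.maximum(p1, p2), ["+"] * n)))
        fine = bin_matrix(e, bin_size=1000, chroms=[("c", 40_000)])
        coarse = bin_matrix(e, bin_size=2000, chroms=[("c", 40_000)])
        assert np.allclose(rebin(fine, 2).counts, coarse.counts)

    def test_fragment_midpoint_binning(self, two_fragment_map):
        # fragment 1 spans [400, 800): its midpoint 600 puts the event in
        # bin 1 at 500-bp bins even for a position at 401
        e = assign_fragments(ev([("chr1", 10, "+", "chr1", 401, "+")]),
                             two_fragment_map)
        mat = bin_matrix(e, bin_size=500, fragment_map=two_fragment_map)
        assert mat.counts[0, 1] == 1

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            bin_matrix(ev([]), bin_size=0, chroms=[("c", 100)])


class TestFilterOutliers:
    def test_constructed_percentile(self):
        """999 ones and a single 1000: the top-5 permille threshold is 1, so
        the 1000 is removed as > 20x."""
        from hicforge.contacts import ContactMatrix

        n = 46  # 46*45/2 + 46 = 1081 pairs; use first 1000
        M = np.zeros((n, n))
        iu = np.triu_indices(n)
        vals = np.ones(len(iu[0]))
        vals[:81] = 0  # keep exactly 1000 nonzero
        vals[81] = 1000.0
        M[iu] = vals
        M = M + M.T
        M[np.diag_indices(n)] /= 2
        mat = ContactMatrix(M, None, [("c", n)])
        out, report = filter_outliers(mat)
        assert report.threshold == 1.0
        assert len(report.removed) == 1 and report.removed[0][2] == 1000.0
        assert out.counts.max() <= 20.0

    def test_all_equal_untouched(self):
        from hicforge.contacts import ContactMatrix

        M = np.full((10, 10), 3.0)
        out, report = filter_outliers(ContactMatrix(M, None, [("c", 10)]))
        assert report.removed == [] and np.array_equal(out.counts, M)

    def test_empty_matrix_unchanged(self):
        from hicforge.contacts import ContactMatrix

        M = np.zeros((4, 4))
        out, report = filter_outliers(ContactMatrix(M, None, [("c", 4)]))
        assert report.removed == [] and out.counts.sum() == 0


class TestSubsample:
    def test_identity_and_empty(self, rng):
        e = ev([("c", 1, "+", "c", 5000, "+")] * 10)
        assert len(subsample(e, 10, 0)) == 10
        assert len(subsample(e, 0, 0)) == 0
        with pytest.raises(ValueError):
            subsample(e, 11, 0)

    def test_seed_reproducible(self):
        e = ev([("c", i, "+", "c", i + 5000, "+") for i in range(100)])
        a = subsample(e, 40, seed=7)
        b = subsample(e, 40, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_matrix_binomial_thinning(self, rng):
        """Expected per-pair counts scale by N/total."""
        from hicforge.contacts import ContactMatrix

        M = np.array([[0.0, 100.0, 60.0], [100.0, 0.0, 40.0], [60.0, 40.0, 0.0]])
        mat = ContactMatrix(M, None, [("c", 3)], total_contacts=200)
        reps = [subsample(mat, 100, seed=s).counts for s in range(300)]
        mean = np.mean(reps, axis=0)
        assert np.allclose(mean, M / 2, atol=1.5)
        totals = {np.triu(r).sum() for r in reps}
        assert totals == {100.0}
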
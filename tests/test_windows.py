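import numpy as np
import pandas as pd
import pytest

from twindhmr.windows import (
    CandidateRegion,
    GenomicInterval,
    SignalWindow,
    WindowCountMatrix,
    aggregate_region_counts,
    bin_fragments,
    estimate_size_factors,
    filter_noise_windows,
    join_candidate_regions,
    sample_cutoffs,
    surviving_windows,
    tile_windows,
)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, strand="x")

    def test_len_midpoint_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        assert len(a) == 100
        assert a.midpoint == 150
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestTileWindows:
    def test_truncated_last_window(self):
        df = tile_windows({"c": 120}, 50)
        assert df.to_dict("list") == {
            "chrom": ["c", "c", "c"],
            "start": [0, 50, 100],
            "end": [50, 100, 120],
        }

    def test_sorted_multi_chrom(self):
        df = tile_windows({"b": 100, "a": 100}, 50)
        assert list(df["chrom"]) == ["a", "a", "b", "b"]

    def test_bad_length(self):
        with pytest.raises(ValueError):
            tile_windows({"c": 0}, 50)


class TestBinFragments:
    def test_one_fragment_counts_every_overlapped_window(self):
        frags = {"s1": pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200]})}
        m = bin_fragments(frags, {"c": 400}, window_size=50)
        # 200 bp fragment spans windows 0..3 of width 50
        assert m.counts[:, 0].tolist() == [1, 1, 1, 1, 0, 0, 0, 0]

    def test_boundary_overlap_by_one_bp(self):
        frags = {"s1": pd.DataFrame({"chrom": ["c"], "start": [49], "end": [51]})}
        m = bin_fragments(frags, {"c": 200}, window_size=50)
        assert m.counts[:, 0].tolist() == [1, 1, 0, 0]

    def test_starts_extended_to_fragment_size(self):
        frags = {"s1": pd.DataFrame({"chrom": ["c"], "start": [10]})}
        m = bin_fragments(frags, {"c": 400}, window_size=50, fragment_size=200)
        assert m.counts[:, 0].tolist() == [1, 1, 1, 1, 1, 0, 0, 0]

    def test_unknown_chromosome_errors(self):
        frags = {"s1": pd.DataFrame({"chrom": ["nope"], "start": [0], "end": [10]})}
        with pytest.raises(ValueError, match="unknown chromosome"):
            bin_fragments(frags, {"c": 100})

    def test_matches_quadratic_overlap_count(self, rng):
        lengths = {"cA": 2000, "cB": 1500}
        n = 300
        chroms = rng.choice(list(lengths), n)
        starts = np.array([rng.integers(0, lengths[c] - 10) for c in chroms])
        ends = starts + rng.integers(5, 400, n)
        ends = np.minimum(ends, [lengths[c] for c in chroms])
        frags = {"s": pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})}
        m = bin_fragments(frags, lengths, window_size=50)
        expected = np.zeros(m.n_windows, dtype=int)
        for i in range(m.n_windows):
            iv = m.interval(i)
            for c, s, e in zip(chroms, starts, ends):
                if c == iv.chrom and s < iv.end and iv.start < e:
                    expected[i] += 1
        assert m.counts[:, 0].tolist() == expected.tolist()


class TestWindowCountMatrix:
    def test_shape_and_negativity_validation(self):
        w = tile_windows({"c": 100}, 50)
        with pytest.raises(ValueError, match="shape"):
            WindowCountMatrix(w, ["a"], np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError, match="non-negative"):
            WindowCountMatrix(w, ["a"], np.array([[-1], [0]]))

    def test_frame_round_trip(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["a", "b"], np.array([[1, 2], [3, 4]]))
        back = WindowCountMatrix.from_frame(m.to_frame())
        assert back.sample_ids == ["a", "b"]
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_subset_samples(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(
            w, ["a", "b"], np.array([[1, 2], [3, 4]]),
            size_factors=np.array([1.0, 2.0]),
        )
        sub = m.subset_samples(["b"])
        assert sub.counts[:, 0].tolist() == [2, 4]
        assert sub.size_factors.tolist() == [2.0]

    def test_normalized_requires_size_factors(self):
        w = tile_windows({"c": 50}, 50)
        m = WindowCountMatrix(w, ["a"], np.array([[4]]))
        with pytest.raises(ValueError, match="size factors"):
            m.normalized()


class TestSizeFactors:
    def test_recovers_library_scaling(self, rng):
        base = rng.poisson(50, size=500).astype(float)
        counts = np.column_stack(
            [rng.poisson(base), rng.poisson(2 * base), rng.poisson(0.5 * base)]
        )
        w = tile_windows({"c": 500 * 50}, 50)
        m = WindowCountMatrix(w, ["a", "b", "c"], counts)
        f = estimate_size_factors(m)
        ratio = f / f[0]
        assert ratio == pytest.approx([1.0, 2.0, 0.5], rel=0.1)

    def test_identical_columns_give_unit_factors(self):
        w = tile_windows({"c": 150}, 50)
        col = np.array([5, 10, 20])
        m = WindowCountMatrix(w, ["a", "b"], np.column_stack([col, col]))
        np.testing.assert_allclose(estimate_size_factors(m), [1.0, 1.0])

    def test_no_reference_window_errors(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["a", "b"], np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="positive counts"):
            estimate_size_factors(m)


class TestSampleCutoffs:
    def test_poisson_background_oracle(self, rng):
        # cutoff must satisfy the expected/observed <= fdr rule, and be the
        # smallest such integer (checked against a brute-force scan)
        n = 20000
        col = rng.poisson(2.0, n)
        w = tile_windows({"c": n * 50}, 50)
        m = WindowCountMatrix(w, ["s"], col[:, None])
        c = int(sample_cutoffs(m, cutoff_fdr=0.05)[0])
        from scipy import stats as ss

        lam = col.sum() / n

        def ratio(k):
            return n * ss.poisson.sf(k - 1, lam) / max(int((col >= k).sum()), 1)

        assert ratio(c) <= 0.05
        assert all(ratio(k) > 0.05 for k in range(1, c))

    def test_zero_count_sample_warns(self, caplog):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["s"], np.zeros((2, 1), dtype=int))
        with caplog.at_level("WARNING"):
            c = sample_cutoffs(m)
        assert c.tolist() == [1]
        assert "no counts" in caplog.text

    def test_surviving_windows_any_sample(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["a", "b"], np.array([[5, 0], [0, 0]]))
        mask = surviving_windows(m, np.array([3, 3]))
        assert mask.tolist() == [True, False]


class TestFilterNoiseWindows:
    def _matrix(self, counts, n_case, n_ctrl):
        nw = counts.shape[0]
        w = tile_windows({"c": nw * 50}, 50)
        ids = [f"case{i}" for i in range(n_case)] + [
            f"ctrl{i}" for i in range(n_ctrl)
        ]
        return WindowCountMatrix(w, ids, counts), ids[:n_case], ids[n_case:]

    def test_identical_groups_no_signal(self, rng):
        half = rng.poisson(50, size=(200, 12))
        counts = np.hstack([half, half])
        m, case, ctrl = self._matrix(counts, 12, 12)
        assert filter_noise_windows(m, case, ctrl) == []

    def test_spiked_windows_flagged_hyper(self, rng):
        # 10 windows at 8-fold case excess among 5000 nulls
        n, pairs = 5000, 12
        mu = np.full((n, 2 * pairs), 50.0)
        mu[:10, :pairs] *= 8.0
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu))
        m, case, ctrl = self._matrix(counts, pairs, pairs)
        flagged = filter_noise_windows(m, case, ctrl)
        spiked = [sw for sw in flagged if sw.index < 10]
        assert len(spiked) >= 9
        assert all(sw.pattern == "hyper" for sw in spiked)

    def test_null_false_flag_rate(self, rng):
        n, pairs = 5000, 12
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + 50.0), size=(n, 2 * pairs))
        m, case, ctrl = self._matrix(counts, pairs, pairs)
        flagged = filter_noise_windows(m, case, ctrl, signal_fdr=0.10)
        # <= 2 x signal_fdr with a 95% binomial margin
        bound = 0.20 + 1.96 * np.sqrt(0.20 * 0.80 / n)
        assert len(flagged) / n <= bound

    def test_requires_two_per_group(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["a", "b"], np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError, match="2 samples"):
            filter_noise_windows(m, ["a"], ["b"])


def _signal(matrix, idx, pattern="hyper"):
    return SignalWindow(index=idx, pattern=pattern, p_value=0.001,
                        mean_level=10.0)


class TestJoinCandidateRegions:
    def _matrix(self, length=5000):
        w = tile_windows({"c": length}, 50)
        return WindowCountMatrix(
            w, ["s"], np.zeros((len(w), 1), dtype=int)
        )

    def test_gap_exactly_join_gap_joins(self):
        m = self._matrix()
        # windows [0,50) and [250,300): gap = 250 - 50 = 200 -> joined
        regions = join_candidate_regions(
            [_signal(m, 0), _signal(m, 5)], m, join_gap=200,
            min_region_size=150,
        )
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 300)
        assert regions[0].member_windows == (0, 5)

    def test_gap_above_join_gap_splits(self):
        m = self._matrix()
        # windows [0,50) and [300,350): gap = 250 > 200 -> two runs, both
        # shorter than 150 bp -> dropped
        regions = join_candidate_regions(
            [_signal(m, 0), _signal(m, 6)], m, join_gap=200,
            min_region_size=150,
        )
        assert regions == []

    def test_min_region_size_boundary(self):
        m = self._matrix()
        # three adjacent windows span exactly 150 bp -> kept
        kept = join_candidate_regions(
            [_signal(m, 0), _signal(m, 1), _signal(m, 2)], m,
            min_region_size=150,
        )
        assert len(kept) == 1 and len(kept[0].interval) == 150
        # two adjacent windows span 100 bp -> dropped
        dropped = join_candidate_regions(
            [_signal(m, 0), _signal(m, 1)], m, min_region_size=150
        )
        assert dropped == []

    def test_pattern_breaks_run(self):
        m = self._matrix()
        regions = join_candidate_regions(
            [
                _signal(m, 0, "hyper"),
                _signal(m, 1, "hyper"),
                _signal(m, 2, "hypo"),
                _signal(m, 3, "hypo"),
                _signal(m, 4, "hyper"),
            ],
            m,
            min_region_size=100,
        )
        assert [r.pattern for r in regions] == ["hyper", "hypo"]
        assert regions[0].member_windows == (0, 1)
        assert regions[1].member_windows == (2, 3)


class TestAggregateRegionCounts:
    def test_sums_member_windows(self):
        w = tile_windows({"c": 200}, 50)
        counts = np.arange(8).reshape(4, 2)
        m = WindowCountMatrix(w, ["a", "b"], counts)
        region = CandidateRegion(
            GenomicInterval("c", 0, 100), "hyper", (0, 1)
        )
        out = aggregate_region_counts(m, [region])
        assert out.tolist() == [[0 + 2, 1 + 3]]

    def test_unknown_window_index_errors(self):
        w = tile_windows({"c": 100}, 50)
        m = WindowCountMatrix(w, ["a"], np.zeros((2, 1), dtype=int))
        region = CandidateRegion(GenomicInterval("c", 0, 100), "hyper", (5,))
        with pytest.raises(ValueError, match="unknown window"):
            aggregate_region_counts(m, [region])
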
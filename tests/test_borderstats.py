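import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import (brute_interval_intersection_bp, brute_nearest_border,
                     brute_trimmed_mean)
from padseg.borderstats import (GenomeBins, aggregate_feature_per_bin,
                                border_profile, build_feature_heatmap,
                                circular_shift_borders,
                                distance_to_nearest_border)
from padseg.domains import BorderSet
from padseg.io import IntervalSet, ScoreTrack


def borders_from(positions, pad_sides, chrom="chr1", length=10_000_000):
    df = pd.DataFrame({"chrom": chrom, "pos": positions, "pad_side": pad_sides})
    return BorderSet(df, {chrom: length})


class TestGenomeBins:
    def test_tiling(self):
        gb = GenomeBins.tile({"chr1": 65_000}, width=20_000)
        assert list(gb.df["start"]) == [0, 20_000, 40_000, 60_000]
        assert list(gb.df["end"])[-1] == 65_000  # last bin truncated

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            GenomeBins.tile({"chr1": 100}, width=0)


class TestAggregateFeature:
    def test_fully_covered_bin(self):
        gb = GenomeBins.tile({"chr1": 20_000}, 20_000)
        iv = IntervalSet.from_arrays(["chr1"], [0], [20_000])
        out = aggregate_feature_per_bin(gb, iv, "fraction_bp")
        assert out.df.loc[0, "value"] == 1.0

    def test_quarter_covered_bin(self):
        gb = GenomeBins.tile({"chr1": 20_000}, 20_000)
        iv = IntervalSet.from_arrays(["chr1"], [10_000], [15_000])
        out = aggregate_feature_per_bin(gb, iv, "fraction_bp")
        assert out.df.loc[0, "value"] == 0.25

    def test_fraction_matches_bruteforce(self, rng):
        gb = GenomeBins.tile({"chr1": 200_000}, 20_000)
        starts = np.sort(rng.integers(0, 190_000, size=100))
        ends = starts + rng.integers(1, 15_000, size=100)
        ends = np.minimum(ends, 200_000)
        iv = IntervalSet.from_arrays(["chr1"] * 100, starts, ends)
        out = aggregate_feature_per_bin(gb, iv, "fraction_bp")
        merged = iv.per_chrom()["chr1"]
        for row in out.df.itertuples(index=False):
            bp = brute_interval_intersection_bp(
                [(row.start, row.end)], list(zip(*merged)))
            assert row.value == pytest.approx(bp / (row.end - row.start))

    def test_fraction_conservation(self, rng):
        gb = GenomeBins.tile({"chr1": 100_000}, 10_000)
        iv = IntervalSet.from_arrays(["chr1"] * 3, [5_000, 30_000, 71_000],
                                     [15_000, 42_000, 90_000])
        out = aggregate_feature_per_bin(gb, iv, "fraction_bp")
        assert (out.df["value"] * 10_000).sum() == pytest.approx(iv.total_bp())

    def test_mean_score_missing_bins_dropped(self):
        gb = GenomeBins.tile({"chr1": 60_000}, 20_000)
        st = ScoreTrack(pd.DataFrame({"chrom": ["chr1", "chr1"],
                                      "start": [0, 5_000], "end": [4_000, 9_000],
                                      "value": [2.0, 4.0]}))
        out = aggregate_feature_per_bin(gb, st, "mean_score")
        assert len(out) == 1  # only the first bin overlaps anything
        assert out.df.loc[0, "value"] == pytest.approx(3.0)

    def test_incompatible_mode_rejected(self):
        gb = GenomeBins.tile({"chr1": 20_000}, 20_000)
        iv = IntervalSet.from_arrays(["chr1"], [0], [100])
        with pytest.raises(ValueError):
            aggregate_feature_per_bin(gb, iv, "mean_score")


class TestDistanceToBorder:
    def test_point_on_border(self):
        b = borders_from([1_000_000], ["left"])
        pts = pd.DataFrame({"chrom": ["chr1"], "center": [1_000_000]})
        assert distance_to_nearest_border(pts, b)[0] == 0.0

    def test_nearest_of_two(self):
        b = borders_from([900_000, 1_200_000], ["left", "right"])
        pts = pd.DataFrame({"chrom": ["chr1"], "center": [1_000_000]})
        d = distance_to_nearest_border(pts, b, signed=False)
        assert d[0] == 100_000

    def test_signed_sides(self):
        # pad on the left of the border: points below are PAD side (negative)
        b = borders_from([1_000_000], ["left"])
        pts = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "center": [900_000, 1_100_000]})
        d = distance_to_nearest_border(pts, b, signed=True)
        np.testing.assert_array_equal(d, [-100_000, 100_000])
        b2 = borders_from([1_000_000], ["right"])
        d2 = distance_to_nearest_border(pts, b2, signed=True)
        np.testing.assert_array_equal(d2, [100_000, -100_000])

    def test_matches_allpairs_bruteforce(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), 40, replace=False))
        sides = ["left" if i % 2 == 0 else "right" for i in range(40)]
        b = borders_from(pos, sides)
        centers = rng.integers(0, 10_000_000, size=1000)
        pts = pd.DataFrame({"chrom": "chr1", "center": centers})
        d = distance_to_nearest_border(pts, b, signed=False)
        expected = [brute_nearest_border(int(c), pos.tolist()) for c in centers]
        np.testing.assert_array_equal(d, expected)

    def test_chromosome_without_borders_missing(self):
        b = borders_from([500], ["left"])
        pts = pd.DataFrame({"chrom": ["chrX"], "center": [100]})
        assert np.isnan(distance_to_nearest_border(pts, b)[0])


class TestBorderProfile:
    def score_track(self, values, bin_width=40_000, chrom="chr1"):
        n = len(values)
        starts = np.arange(n) * bin_width
        return ScoreTrack(pd.DataFrame({"chrom": chrom, "start": starts,
                                        "end": starts + bin_width,
                                        "value": values}))

    def test_constant_track_flat_curve(self):
        st = self.score_track([3.0] * 100)
        b = borders_from([1_000_000, 2_500_000], ["left", "right"],
                         length=4_000_000)
        curve = border_profile(st, b, bin_width=80_000, max_distance=800_000)
        vals = curve.values[np.isfinite(curve.values)]
        np.testing.assert_allclose(vals, 3.0)

    def test_trimmed_mean_matches_sort_slice_oracle(self):
        vals = np.arange(1.0, 21.0)
        assert brute_trimmed_mean(vals, 0.05) == pytest.approx(10.5)
        st = self.score_track(vals, bin_width=1000)
        # single border far away so all values land in few bins; use one
        # wide bin to group everything
        b = borders_from([0], ["left"], length=100_000)
        curve = border_profile(st, b, bin_width=30_000, aggregate="trimmed_mean",
                               trim=0.05, max_distance=30_000)
        grouped = curve.values[np.isfinite(curve.values)]
        assert grouped[-1] == pytest.approx(brute_trimmed_mean(vals[:20], 0.05))

    def test_trim_zero_equals_mean(self, rng):
        vals = rng.normal(size=200)
        st = self.score_track(vals, bin_width=10_000)
        b = borders_from([500_000], ["left"], length=3_000_000)
        c1 = border_profile(st, b, bin_width=100_000, aggregate="trimmed_mean",
                            trim=0.0, max_distance=1_000_000)
        c2 = border_profile(st, b, bin_width=100_000, aggregate="mean",
                            max_distance=1_000_000)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-12, equal_nan=True)

    def test_absolute_flag(self):
        st = self.score_track([-2.0] * 50)
        b = borders_from([500_000], ["left"], length=2_000_000)
        c = border_profile(st, b, bin_width=200_000, absolute=True,
                           max_distance=1_000_000)
        vals = c.values[np.isfinite(c.values)]
        np.testing.assert_allclose(vals, 2.0)

    def test_invalid_trim_rejected(self):
        st = self.score_track([1.0] * 10)
        b = borders_from([100], ["left"])
        with pytest.raises(ValueError):
            border_profile(st, b, aggregate="trimmed_mean", trim=0.6)


class TestCircularShift:
    def test_zero_shift_identity(self):
        # max_shift=1 forces a shift of 0, equivalent to a full-length
        # rotation: borders unchanged (modulo identity)
        b = borders_from([100, 500, 900], ["left", "right", "left"], length=1000)
        shifted = circular_shift_borders(b, max_shift=1, n_iter=1, seed=0)[0]
        np.testing.assert_array_equal(shifted.df["pos"], b.df["pos"])

    def test_full_length_shift_wraps_to_identity(self):
        L = 1000
        pos = np.array([100, 500, 900])
        np.testing.assert_array_equal((pos + L) % L, pos)

    def test_wraps_past_chromosome_end(self):
        # border 1 Mb from the 3' end, shifted 2.5 Mb on a 10-Mb chromosome,
        # re-enters 1.5 Mb from the 5' start
        L = 10_000_000
        b = borders_from([L - 1_000_000], ["left"], length=L)
        per = b.per_chrom()["chr1"]
        new = (per[0] + 2_500_000) % L
        assert new[0] == 1_500_000

    def test_circular_gap_multiset_invariant(self, rng):
        L = 5_000_000
        pos = np.sort(rng.choice(np.arange(1, L), 20, replace=False))
        b = borders_from(pos, ["left", "right"] * 10, length=L)

        def circular_gaps(p):
            p = np.sort(p)
            gaps = np.diff(np.concatenate([p, [p[0] + L]]))
            return np.sort(gaps)

        for shifted in circular_shift_borders(b, max_shift=L, n_iter=5, seed=4):
            np.testing.assert_array_equal(
                circular_gaps(shifted.df["pos"].to_numpy()), circular_gaps(pos))

    def test_reproducible_under_seed(self):
        b = borders_from([100, 900], ["left", "right"], length=1000)
        a = circular_shift_borders(b, 500, n_iter=3, seed=42)
        c = circular_shift_borders(b, 500, n_iter=3, seed=42)
        for x, y in zip(a, c):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_randomized_average_curve_is_flat(self, rng):
        """Averaged border profiles over circular shifts of a fixed track have
        slope within 2 SE of zero (rotation invariance)."""
        n = 500
        vals = rng.normal(5.0, 1.0, size=n)
        starts = np.arange(n) * 40_000
        st = ScoreTrack(pd.DataFrame({"chrom": "chr1", "start": starts,
                                      "end": starts + 40_000, "value": vals}))
        L = int(n * 40_000)
        pos = np.sort(rng.choice(np.arange(1, L), 12, replace=False))
        b = borders_from(pos, ["left", "right"] * 6, length=L)
        # full-circle shifts: rotation invariance is exact only when every
        # rotation of the chromosome is reachable
        shifted = circular_shift_borders(b, max_shift=L, n_iter=200, seed=9)
        centers = (np.arange(40) + 0.5) * 80_000 - 1_600_000
        slopes = []
        for s in shifted:
            curve = border_profile(st, s, bin_width=80_000,
                                   max_distance=1_600_000).values
            okbins = np.isfinite(curve)
            slopes.append(sps.linregress(centers[okbins], curve[okbins]).slope)
        slopes = np.asarray(slopes)
        # mean slope over independent rotations, against its own sampling SE
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) <= 2 * se


class TestFeatureHeatmap:
    def bins_track(self, values, bin_width=20_000):
        n = len(values)
        starts = np.arange(n) * bin_width
        return ScoreTrack(pd.DataFrame({"chrom": "chr1", "start": starts,
                                        "end": starts + bin_width,
                                        "value": values}))

    def test_constant_feature_degenerate_row_zero(self):
        st = self.bins_track([7.0] * 200)
        b = borders_from([2_000_000], ["left"], length=4_000_000)
        hm = build_feature_heatmap({"const": st}, b, distance_bin=125_000,
                                   max_distance=1_000_000)
        np.testing.assert_allclose(hm.matrix.loc["const"].to_numpy(), 0.0)

    def test_minmax_normalization(self):
        # row values min 2 max 10: value 6 -> 0.5
        raw = np.array([2.0, 6.0, 10.0])
        lo, hi = raw.min(), raw.max()
        np.testing.assert_allclose((raw - lo) / (hi - lo), [0.0, 0.5, 1.0])

    def test_pad_enriched_feature_steps_across_border(self):
        # feature painted only on the PAD side (below a left-PAD border)
        vals = np.where(np.arange(400) * 20_000 < 4_000_000, 1.0, 0.0)
        st = self.bins_track(vals)
        b = borders_from([4_000_000], ["left"], length=8_000_000)
        hm = build_feature_heatmap({"padded": st}, b, distance_bin=125_000,
                                   max_distance=2_000_000)
        row = hm.matrix.loc["padded"]
        neg = row[row.index < -200_000].mean()
        pos = row[row.index > 200_000].mean()
        assert neg > 0.9 and pos < 0.1

    def test_rows_within_unit_interval(self, rng):
        st = self.bins_track(rng.normal(size=300))
        b = borders_from([3_000_000], ["left"], length=6_000_000)
        hm = build_feature_heatmap({"x": st}, b)
        vals = hm.matrix.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0
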
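import numpy as np
import pandas as pd
import pytest

from oracles import brute_interval_intersection_bp
from padseg.domains import DomainSet, calls_to_domains
from padseg.hsmm import StateCalls
from padseg.io import FragmentEndMap, IntervalSet
from padseg.overlap import (_pad_intervals_from_calls, _rotate_calls,
                            circular_permutation_null,
                            classify_constitutive_facultative, genomic_overlap,
                            pairwise_domain_overlap,
                            partition_features_by_domain, top_n_by_score)
from padseg.simulate import SimConfig, simulate_fragends, simulate_truth


def domain_set(intervals, chrom="chr1", length=10_000):
    """Alternating PAD/nonPAD tiling from PAD intervals within [0, length)."""
    rows = []
    pos = 0
    for s, e in intervals:
        if s > pos:
            rows.append((chrom, pos, s, "nonPAD"))
        rows.append((chrom, s, e, "PAD"))
        pos = e
    if pos < length:
        rows.append((chrom, pos, length, "nonPAD"))
    return DomainSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
                     {chrom: length})


class TestGenomicOverlap:
    def test_identical_sets_full_overlap(self):
        dom = domain_set([(100, 400), (600, 900)])
        iv = IntervalSet.from_arrays(["chr1", "chr1"], [100, 600], [400, 900])
        res = genomic_overlap(dom, iv)
        assert res.bp == 600
        assert res.percent == pytest.approx(100.0)

    def test_disjoint_sets_zero(self):
        dom = domain_set([(0, 100)])
        iv = IntervalSet.from_arrays(["chr1"], [500], [600])
        assert genomic_overlap(dom, iv).bp == 0

    def test_hand_intersection(self):
        dom = domain_set([(0, 100), (200, 300)])
        iv = IntervalSet.from_arrays(["chr1"], [50], [250])
        assert genomic_overlap(dom, iv).bp == 100  # 50 + 50

    def test_symmetric_in_bp(self, rng):
        a_starts = np.sort(rng.choice(np.arange(0, 5000, 10), 20, replace=False))
        a = IntervalSet.from_arrays(["chr1"] * 20, a_starts, a_starts + 8)
        b_starts = np.sort(rng.choice(np.arange(0, 5000, 7), 30, replace=False))
        b = IntervalSet.from_arrays(["chr1"] * 30, b_starts, b_starts + 5)
        assert genomic_overlap(a, b).bp == genomic_overlap(b, a).bp

    def test_matches_per_bp_oracle(self, rng):
        a_iv = [(int(s), int(s) + int(rng.integers(5, 50)))
                for s in np.sort(rng.choice(np.arange(0, 3000, 60), 25,
                                            replace=False))]
        b_iv = [(int(s), int(s) + int(rng.integers(5, 80)))
                for s in np.sort(rng.choice(np.arange(0, 3000, 90), 20,
                                            replace=False))]
        a = IntervalSet.from_arrays(["chr1"] * len(a_iv), *zip(*a_iv))
        b = IntervalSet.from_arrays(["chr1"] * len(b_iv), *zip(*b_iv))
        assert genomic_overlap(a, b).bp == brute_interval_intersection_bp(a_iv, b_iv)

    def test_unknown_denominator_rejected(self):
        dom = domain_set([(0, 100)])
        iv = IntervalSet.from_arrays(["chr1"], [0], [100])
        with pytest.raises(ValueError):
            genomic_overlap(dom, iv, denominator="nope")


class TestCircularPermutationNull:
    def make_calls(self, rng, n_chrom=2, n_ends=200):
        cfg = SimConfig(n_chromosomes=n_chrom, n_ends_per_chromosome=n_ends,
                        seed=int(rng.integers(0, 2**31)))
        fe = simulate_fragends(cfg)
        truth = simulate_truth(fe, cfg)
        return fe, truth.labels

    def test_identity_rotation_reproduces_observed(self, rng):
        fe, calls = self.make_calls(rng)
        n = calls.is_pad.size
        rotated = _rotate_calls(calls.is_pad, n)
        np.testing.assert_array_equal(rotated, calls.is_pad)

    def test_rotation_spec_order(self):
        # rotated vector = (n-k+1 .. n, 1 .. n-k) of the original (1-based)
        v = np.arange(6)
        np.testing.assert_array_equal(_rotate_calls(v, 2), [4, 5, 0, 1, 2, 3])

    def test_rotation_preserves_pad_count(self, rng):
        fe, calls = self.make_calls(rng)
        n_pad = calls.is_pad.sum()
        for k in rng.integers(1, calls.is_pad.size, 10):
            assert _rotate_calls(calls.is_pad, int(k)).sum() == n_pad

    def test_fast_pad_intervals_agree_with_domains(self, rng):
        fe, calls = self.make_calls(rng)
        fast = _pad_intervals_from_calls(calls.is_pad, fe)
        dom = calls_to_domains(calls, fe).label_intervals("PAD").per_chrom()
        assert set(fast) >= set(dom)
        for chrom in dom:
            np.testing.assert_array_equal(fast[chrom][0], dom[chrom][0])
            np.testing.assert_array_equal(fast[chrom][1], dom[chrom][1])

    def test_null_contains_stored_values(self, rng):
        fe, calls = self.make_calls(rng)
        lads = IntervalSet.from_arrays(["chr1"], [1000], [200_000])
        null = circular_permutation_null(calls, fe, lads, n_iter=50, seed=1)
        assert null.values.size == 50
        assert null.lower <= null.mean <= null.upper
        assert null.shifts.min() >= 1 and null.shifts.max() <= calls.is_pad.size

    def test_empty_calls_rejected(self):
        fe = FragmentEndMap(starts={}, ends={})
        calls = StateCalls(fe, np.empty(0, bool))
        lads = IntervalSet.from_arrays(["chr1"], [0], [10])
        with pytest.raises(ValueError, match="empty"):
            circular_permutation_null(calls, fe, lads, n_iter=5)


class TestPairwiseOverlap:
    def test_diagonal_is_100(self):
        sets = {"a": domain_set([(0, 100)]), "b": domain_set([(50, 150)])}
        mat = pairwise_domain_overlap(sets)
        assert mat.loc["a", "a"] == 100.0
        assert mat.loc["b", "b"] == 100.0

    def test_nested_sets(self):
        sets = {"small": domain_set([(100, 200)]),
                "big": domain_set([(0, 400)])}
        mat = pairwise_domain_overlap(sets)
        # % of the *column* set's bp
        assert mat.loc["big", "small"] == pytest.approx(100.0)
        assert mat.loc["small", "big"] == pytest.approx(25.0)

    def test_matches_bruteforce_matrix(self, rng):
        def rand_domains(seed):
            r = np.random.default_rng(seed)
            cuts = np.sort(r.choice(np.arange(100, 9900, 100), 6, replace=False))
            ivs = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 6, 2)]
            return ivs

        named = {f"t{i}": rand_domains(i) for i in range(3)}
        sets = {k: domain_set(v) for k, v in named.items()}
        mat = pairwise_domain_overlap(sets)
        for i in named:
            for j in named:
                bp = brute_interval_intersection_bp(named[i], named[j])
                denom = sum(e - s for s, e in named[j])
                expected = 100.0 if i == j else 100.0 * bp / denom
                assert mat.loc[i, j] == pytest.approx(expected)

    def test_entries_bounded(self, rng):
        sets = {"a": domain_set([(0, 5000)]), "b": domain_set([(2500, 7000)])}
        mat = pairwise_domain_overlap(sets).to_numpy(float)
        assert (mat >= 0).all() and (mat <= 100).all()


class TestConstitutiveFacultative:
    def test_identical_sets_all_constitutive(self):
        sets = {t: domain_set([(100, 500)]) for t in ("esc", "npc", "ac", "thy")}
        out = classify_constitutive_facultative(sets, "esc", "thy")
        assert out["constitutive_pad"].total_bp() == 400
        assert out["esc_specific_pad"].total_bp() == 0
        assert out["thy_specific_pad"].total_bp() == 0

    def test_reference_specific(self):
        sets = {"esc": domain_set([(0, 100)]), "thy": domain_set([(500, 600)])}
        out = classify_constitutive_facultative(sets, "esc", "thy")
        df = out["esc_specific_pad"].df
        assert len(df) == 1
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (0, 100)

    def test_unknown_name_rejected(self):
        sets = {"esc": domain_set([(0, 100)])}
        with pytest.raises(ValueError, match="unknown"):
            classify_constitutive_facultative(sets, "esc", "npc")

    def test_matches_per_bp_vote_oracle(self, rng):
        L = 10_000
        tilings = {}
        for t in range(4):
            r = np.random.default_rng(100 + t)
            cuts = np.sort(r.choice(np.arange(500, L - 500, 250), 5,
                                    replace=False))
            ivs = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 4, 2)]
            tilings[f"t{t}"] = ivs
        sets = {k: domain_set(v, length=L) for k, v in tilings.items()}
        out = classify_constitutive_facultative(sets, "t0", "t1")

        def in_pad(name, bp):
            return any(s <= bp < e for s, e in tilings[name])

        # per-bp oracle
        classes = {"constitutive_pad": set(), "constitutive_nonpad": set(),
                   "t0_specific_pad": set(), "t1_specific_pad": set()}
        for bp in range(L):
            pads = {name: in_pad(name, bp) for name in tilings}
            if all(pads.values()):
                classes["constitutive_pad"].add(bp)
            if not any(pads.values()):
                classes["constitutive_nonpad"].add(bp)
            if pads["t0"] and not pads["t1"]:
                classes["t0_specific_pad"].add(bp)
            if pads["t1"] and not pads["t0"]:
                classes["t1_specific_pad"].add(bp)
        for key, expected_bps in classes.items():
            got = set()
            for row in out[key].df.itertuples(index=False):
                got.update(range(row.start, row.end))
            assert got == expected_bps, key

    def test_classes_disjoint(self):
        sets = {"a": domain_set([(0, 3000), (6000, 8000)]),
                "b": domain_set([(2000, 7000)])}
        out = classify_constitutive_facultative(sets, "a", "b")
        covered = []
        for iv in out.values():
            for row in iv.df.itertuples(index=False):
                covered.append((row.start, row.end))
        total = sum(e - s for s, e in covered)
        merged_bp = len({bp for s, e in covered for bp in range(s, e)})
        assert total == merged_bp  # no double counting


class TestPartitionFeatures:
    def test_midpoint_assignment(self):
        dom = domain_set([(0, 1000)], length=2000)
        feats = IntervalSet.from_arrays(["chr1", "chr1"], [400, 1500],
                                        [600, 1600])
        out = partition_features_by_domain(feats, dom)
        assert out.loc["PAD", "count"] == 1
        assert out.loc["nonPAD", "count"] == 1

    def test_empty_features(self):
        dom = domain_set([(0, 1000)])
        feats = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        out = partition_features_by_domain(feats, dom)
        assert out["count"].sum() == 0

    def test_uniform_scatter_matches_bp_fraction(self, rng):
        # 30% PAD by bp; uniformly scattered features land in PADs ~30%
        L = 100_000
        dom = domain_set([(0, 30_000)], length=L)
        n = 2000
        pos = rng.integers(0, L - 1, size=n)
        feats = IntervalSet.from_arrays(["chr1"] * n, pos, pos + 1)
        out = partition_features_by_domain(feats, dom)
        frac = out.loc["PAD", "count"] / n
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) <= 3 * se

    def test_top_n_by_score(self):
        feats = IntervalSet.from_arrays(["chr1"] * 4, [0, 10, 20, 30],
                                        [5, 15, 25, 35],
                                        scores=[1.0, 9.0, 3.0, 7.0])
        top2 = top_n_by_score(feats, 2)
        assert sorted(top2.df["score"]) == [7.0, 9.0]
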
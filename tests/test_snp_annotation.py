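import itertools

import numpy as np
import pytest

from bgscan.io_formats import (Individual, IntervalSet, RecombinationMap,
                               SnpRecord, SnpTable, read_recombination_map)
from bgscan.snp_annotation import (AnnotatedSnpTable, annotate_rates,
                                   assign_recombination_bins,
                                   classify_mutation, detect_hotspots,
                                   distance_to_nearest, neutral_filter)


def make_table(positions, rates=None, pairs=None, chrom="chr1"):
    pairs = pairs or [("A", "G")] * len(positions)
    recs = [SnpRecord(chrom, p, a, d, np.array([1, 0]))
            for p, (a, d) in zip(positions, pairs)]
    t = AnnotatedSnpTable.from_table(
        SnpTable(recs, [Individual("s1"), Individual("s2")]))
    if rates is not None:
        t.annotations["rr_cMMb"] = np.asarray(rates, dtype=float)
    return t


class TestClassify:
    @pytest.mark.parametrize("anc,der,expected", [
        ("A", "G", "WS"), ("T", "C", "WS"), ("A", "C", "WS"), ("T", "G", "WS"),
        ("C", "T", "SW"), ("G", "A", "SW"), ("C", "A", "SW"), ("G", "T", "SW"),
        ("A", "T", "WWSS"), ("T", "A", "WWSS"),
        ("G", "C", "WWSS"), ("C", "G", "WWSS"),
    ])
    def test_class_definitions(self, anc, der, expected):
        assert classify_mutation(anc, der) == expected

    def test_partition_of_all_ordered_pairs(self):
        counts = {"WS": 0, "SW": 0, "WWSS": 0}
        for a, d in itertools.permutations("ACGT", 2):
            counts[classify_mutation(a, d)] += 1
        assert counts == {"WS": 4, "SW": 4, "WWSS": 4}

    def test_invalid_bases_error(self):
        with pytest.raises(ValueError):
            classify_mutation("A", "A")
        with pytest.raises(ValueError):
            classify_mutation("N", "G")


class TestBinning:
    def test_equal_split_distinct_rates(self, rng):
        rates = rng.permutation(np.linspace(0.1, 10, 40))
        t = make_table(np.arange(1, 41) * 10, rates)
        summary = assign_recombination_bins(t, 20)
        sizes = np.bincount(t.bins, minlength=21)[1:]
        assert set(sizes.tolist()) == {2}
        assert (np.diff(summary["mean_rr"]) >= 0).all()

    def test_remainder_rule(self, rng):
        rates = rng.permutation(np.linspace(0.1, 10, 41))
        t = make_table(np.arange(1, 42) * 10, rates)
        assign_recombination_bins(t, 20)
        sizes = np.bincount(t.bins, minlength=21)[1:]
        assert sizes.max() - sizes.min() == 1
        assert sizes.sum() == 41

    def test_tied_rates_positional_order(self):
        t = make_table(np.arange(1, 11) * 10, np.full(10, 2.5))
        summary = assign_recombination_bins(t, 5)
        # positional tie-break: first two sites in bin 1, etc.
        assert t.bins.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        assert summary["mean_rr"].nunique() == 1

    def test_partition_property(self, rng):
        rates = np.where(rng.random(50) < 0.2, np.nan,
                         rng.uniform(0, 5, 50))
        t = make_table(np.arange(1, 51) * 7, rates)
        if np.sum(~np.isnan(rates)) < 7:
            pytest.skip("degenerate draw")
        assign_recombination_bins(t, 7)
        defined = ~np.isnan(rates)
        assert (t.bins[defined] > 0).all()
        assert (t.bins[~defined] == 0).all()
        # concatenating bins in order recovers the rate-sorted multiset,
        # and bin rate ranges do not interleave
        per_bin = [np.sort(rates[t.bins == b]) for b in range(1, 8)]
        assert np.array_equal(np.concatenate(per_bin),
                              np.sort(rates[defined]))
        for left, right in zip(per_bin[:-1], per_bin[1:]):
            assert left.max() <= right.min()

    def test_too_few_snps_errors(self):
        t = make_table([10, 20], [1.0, 2.0])
        with pytest.raises(ValueError, match="need >= 5"):
            assign_recombination_bins(t, 5)


class TestDistances:
    def test_inside_feature_zero(self, simple_map):
        rmap = read_recombination_map(simple_map)
        feats = IntervalSet({"chr1": [(50, 150)]})
        t = make_table([100])
        assert distance_to_nearest(t, feats, units="bp")[0] == 0
        assert distance_to_nearest(t, feats, rmap, units="cM")[0] == 0

    def test_bp_and_cm_distance(self, simple_map):
        rmap = read_recombination_map(simple_map)
        feats = IntervalSet({"chr1": [(50, 150)]})
        t = make_table([200])
        # nearest included bp is 149; uniform 2 cM/Mb
        assert distance_to_nearest(t, feats, units="bp")[0] == 51
        assert distance_to_nearest(t, feats, rmap, units="cM")[0] == \
            pytest.approx(51 * 2.0 / 1e6)

    def test_brute_force_oracle(self, rng):
        for _ in range(25):
            n_feat = rng.integers(1, 5)
            starts = np.sort(rng.choice(np.arange(1, 500), size=n_feat,
                                        replace=False))
            feats = [(int(s), int(s + rng.integers(1, 30))) for s in starts]
            fs = IntervalSet({"chr1": feats})
            pos = int(rng.integers(1, 600))
            t = make_table([pos])
            got = distance_to_nearest(t, fs, units="bp")[0]
            # exhaustive scan over all included bp of the merged set
            best = min(abs(pos - b) for s, e in fs.intervals("chr1")
                       for b in (s, e - 1)) \
                if not fs.contains("chr1", pos) else 0
            assert got == best

    def test_empty_features_warn_missing(self):
        t = make_table([100])
        with pytest.warns(UserWarning, match="empty feature set"):
            d = distance_to_nearest(t, IntervalSet({}), units="bp")
        assert np.isnan(d).all()


class TestHotspots:
    def map_from(self, rates, width=1000):
        pos = np.arange(len(rates) + 1) * width + 1
        return RecombinationMap({"chr1": (pos,
                                          np.append(rates, 0.0),
                                          np.zeros(len(rates) + 1))})

    def test_adjacent_hot_intervals_merge(self):
        hs = detect_hotspots(self.map_from([2.0, 12.0, 11.0, 3.0]))
        assert len(hs) == 1
        ivs = hs.intervals("chr1")
        assert (ivs[0] == [1001, 3001]).all()

    def test_all_cold_empty(self):
        assert len(detect_hotspots(self.map_from([1.0, 9.9, 10.0]))) == 0

    def test_threshold_is_strict(self):
        assert len(detect_hotspots(self.map_from([10.0]))) == 0
        assert len(detect_hotspots(self.map_from([10.0 + 1e-9]))) == 1


class TestNeutralFilter:
    def test_class_and_rate_rules(self):
        t = make_table([10, 20, 30],
                       rates=[2.0, 2.0, 1.0],
                       pairs=[("A", "T"), ("A", "G"), ("G", "C")])
        kept = neutral_filter(t)
        assert [r.pos for r in kept.records] == [10]

    def test_threshold_inclusive(self):
        t = make_table([10, 20], rates=[1.5, 1.5 - 1e-9],
                       pairs=[("A", "T"), ("A", "T")])
        kept = neutral_filter(t, rr_min=1.5)
        assert [r.pos for r in kept.records] == [10]

    def test_all_missing_rr_empty_with_warning(self):
        t = make_table([10, 20], pairs=[("A", "T"), ("T", "A")])
        with pytest.warns(UserWarning, match="retained no sites"):
            kept = neutral_filter(t)
        assert len(kept) == 0

    def test_subset_and_idempotent(self):
        t = make_table(np.arange(1, 21) * 5,
                       rates=np.linspace(0.5, 3.0, 20),
                       pairs=[("A", "T")] * 10 + [("A", "G")] * 10)
        once = neutral_filter(t)
        twice = neutral_filter(once)
        assert len(once) <= len(t)
        assert [r.pos for r in twice.records] == \
            [r.pos for r in once.records]
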
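"""Multi-map groups: compilation, counting, filtering, collapsing, rescue."""

import math

import numpy as np
import pandas as pd
import pytest

from mmgkit.counting import FragmentFate, Verdict
from mmgkit.groups import (
    MmgFilterParams,
    MultiMapGroup,
    collapse_mmgs,
    count_mmgs,
    filter_mmgs,
    fragment_to_group,
    group_sizes,
    rescue_stats,
)


def fate(fid, verdict, sets):
    return FragmentFate(
        fragment_id=fid,
        verdict=verdict,
        overlap_gene_sets=tuple(frozenset(s) for s in sets),
    )


class TestMultiMapGroup:
    def test_canonical_sorted_deduplicated(self):
        g = MultiMapGroup.from_genes(["B", "A", "B"])
        assert g.gene_ids == ("A", "B")
        assert g.group_id == "A|B"
        assert MultiMapGroup.from_id("A|B") == g

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            MultiMapGroup.from_genes([])


class TestFragmentToGroup:
    def test_union_of_loci(self):
        f = fate("f", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, {"B"}])
        assert fragment_to_group(f).group_id == "A|B"

    def test_all_loci_same_gene_gives_size_one(self):
        f = fate("f", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, {"A"}])
        g = fragment_to_group(f)
        assert g.group_id == "A" and len(g) == 1

    def test_intergenic_locus_ignored(self):
        f = fate("f", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, set()])
        assert fragment_to_group(f).group_id == "A"

    def test_no_overlap_anywhere_stays_discarded(self):
        f = fate("f", Verdict.NO_FEATURE, [])
        assert fragment_to_group(f) is None

    def test_assigned_fragment_is_never_regrouped(self):
        f = FragmentFate("f", Verdict.ASSIGNED, gene_id="A")
        assert fragment_to_group(f) is None


class TestCountMmgs:
    def test_single_group_counts_all(self):
        fates = [fate(f"f{i}", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, {"B"}])
                 for i in range(2000)]
        m = count_mmgs({"s1": fates})
        assert m.loc["A|B", "s1"] == 2000

    def test_two_samples_disjoint_groups(self):
        m = count_mmgs({
            "s1": [fate("f", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, {"B"}])],
            "s2": [fate("g", Verdict.ALIGNMENT_NOT_UNIQUE, [{"C"}, {"D"}])],
        })
        assert m.shape == (2, 2)
        assert m.loc["A|B"].tolist() == [1, 0]
        assert m.loc["C|D"].tolist() == [0, 1]

    def test_supersets_not_merged_at_counting_time(self):
        fates = [fate(f"f{i}", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A"}, {"B"}])
                 for i in range(3)]
        fates += [fate(f"g{i}", Verdict.ALIGNMENT_NOT_UNIQUE, [{"A", "B", "C"}])
                  for i in range(2)]
        m = count_mmgs({"s1": fates})
        assert m.loc["A|B", "s1"] == 3
        assert m.loc["A|B|C", "s1"] == 2


class TestFilterMmgs:
    def _matrix(self, per_sample_counts, n_samples=27):
        row = per_sample_counts + [0] * (n_samples - len(per_sample_counts))
        return pd.DataFrame([row], index=["A|B"],
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_100_reads_in_exactly_13_of_27_kept(self):
        m = self._matrix([100] * 13)
        assert filter_mmgs(m, MmgFilterParams()).shape[0] == 1

    def test_99_reads_everywhere_dropped(self):
        m = self._matrix([99] * 27)
        assert filter_mmgs(m, MmgFilterParams()).empty

    def test_100_reads_in_only_12_dropped(self):
        m = self._matrix([100] * 12)
        assert filter_mmgs(m, MmgFilterParams()).empty

    def test_min_samples_beyond_dataset_is_an_error(self):
        m = self._matrix([100] * 5, n_samples=5)
        with pytest.raises(ValueError, match="min_samples"):
            filter_mmgs(m, MmgFilterParams(min_samples=13))


def _naive_collapse(sets_counts, min_size=5):
    """Independent restatement of the collapse rule: one merge at a time.

    Repeatedly take the first (by size, then id) group of size >= min_size
    that is a strict subset of some surviving group, and merge it into its
    smallest (then lexicographically first) superset.
    """
    groups = dict(sets_counts)  # id -> (frozenset, np.ndarray counts)
    while True:
        order = sorted(
            (g for g in groups if len(groups[g][0]) >= min_size),
            key=lambda g: (len(groups[g][0]), g),
        )
        merged = False
        for gid in order:
            gset = groups[gid][0]
            cands = sorted(
                (h for h in groups if gset < groups[h][0]),
                key=lambda h: (len(groups[h][0]), h),
            )
            if cands:
                tgt = cands[0]
                groups[tgt] = (groups[tgt][0], groups[tgt][1] + groups[gid][1])
                del groups[gid]
                merged = True
                break
        if not merged:
            return groups


def _random_matrix(rng, max_groups=12, max_samples=27):
    universe = [f"g{i}" for i in range(10)]
    n_samples = int(rng.integers(1, max_samples + 1))
    n_groups = int(rng.integers(1, max_groups + 1))
    seen = set()
    for _ in range(n_groups):
        size = int(rng.integers(1, 9))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        seen.add(genes)
    idx = sorted(MultiMapGroup.from_genes(g).group_id for g in seen)
    counts = rng.integers(0, 500, size=(len(idx), n_samples))
    return pd.DataFrame(counts, index=idx,
                        columns=[f"s{i}" for i in range(n_samples)])


class TestCollapseMmgs:
    def _m(self, rows):
        return pd.DataFrame(
            {"s1": list(rows.values())},
            index=[MultiMapGroup.from_genes(k).group_id for k in rows],
        )

    def test_contained_large_group_merges_counts_summed(self):
        m = self._m({("A", "B", "C", "D", "E"): 10,
                     ("A", "B", "C", "D", "E", "F"): 5})
        out = collapse_mmgs(m, MmgFilterParams())
        assert list(out.index) == ["A|B|C|D|E|F"]
        assert out.loc["A|B|C|D|E|F", "s1"] == 15

    def test_small_subset_not_merged(self):
        m = self._m({("A", "B", "C", "D"): 10,
                     ("A", "B", "C", "D", "E", "F"): 5})
        out = collapse_mmgs(m, MmgFilterParams())
        assert sorted(out.index) == ["A|B|C|D", "A|B|C|D|E|F"]

    def test_disjoint_groups_unchanged(self):
        m = self._m({("A", "B", "C", "D", "E"): 10,
                     ("F", "G", "H", "I", "J"): 5})
        out = collapse_mmgs(m, MmgFilterParams())
        pd.testing.assert_frame_equal(out.sort_index(), m.sort_index())

    def test_multiple_supersets_smallest_wins(self):
        m = self._m({("A", "B", "C", "D", "E"): 10,
                     ("A", "B", "C", "D", "E", "F"): 5,
                     ("A", "B", "C", "D", "E", "F", "G"): 2})
        out = collapse_mmgs(m, MmgFilterParams())
        # chain: 5-set -> 6-set, then 6-set (now size >= 5) -> 7-set
        assert list(out.index) == ["A|B|C|D|E|F|G"]
        assert out.iloc[0, 0] == 17

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(200):
            m = _random_matrix(rng)
            out = collapse_mmgs(m, MmgFilterParams())
            oracle = _naive_collapse(
                {gid: (MultiMapGroup.from_id(gid).gene_set,
                       m.loc[gid].to_numpy())
                 for gid in m.index}
            )
            assert sorted(out.index) == sorted(oracle)
            for gid in out.index:
                assert (out.loc[gid].to_numpy() == oracle[gid][1]).all()

    def test_idempotent_and_count_conserving(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = _random_matrix(rng)
            once = collapse_mmgs(m, MmgFilterParams())
            twice = collapse_mmgs(once, MmgFilterParams())
            pd.testing.assert_frame_equal(once, twice)
            assert (once.sum(axis=0) == m.sum(axis=0)).all()

    def test_group_sizes_reported(self):
        m = self._m({("A",): 3, ("A", "B"): 4})
        assert group_sizes(m).to_dict() == {"A": 1, "A|B": 2}


class TestRescueStats:
    class _FakeResult:
        def __init__(self, total, assigned):
            from collections import Counter

            self.tallies = Counter({Verdict.ASSIGNED: assigned})
            self.total_fragments = total
            self.unassigned = total - assigned

    def test_half_rescued(self):
        kept = pd.DataFrame({"s1": [500]}, index=["A|B"])
        stats = rescue_stats({"s1": self._FakeResult(2000, 1000)}, kept)
        assert stats.loc["s1", "rescued_pct"] == 50.0
        assert stats.loc["s1", "unassigned_pct"] == 50.0

    def test_all_rescued(self):
        kept = pd.DataFrame({"s1": [1000]}, index=["A|B"])
        stats = rescue_stats({"s1": self._FakeResult(2000, 1000)}, kept)
        assert stats.loc["s1", "rescued_pct"] == 100.0

    def test_zero_unassigned_is_undefined_not_an_error(self):
        kept = pd.DataFrame({"s1": [0]}, index=["A|B"])
        stats = rescue_stats({"s1": self._FakeResult(1000, 1000)}, kept)
        assert math.isnan(stats.loc["s1", "rescued_pct"])
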
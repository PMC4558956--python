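"""Stage-1 overlap resolution: per-base mode semantics and fragment fates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fragment, make_gene, make_mate
from mmgkit.annotation import build_index
from mmgkit.counting import (
    CountingMode,
    Strandedness,
    Verdict,
    count_stage1,
    gene_sets_for_mate,
    read_fates,
    resolve_fragment,
    write_fates,
)

ALL_MODES = list(CountingMode)


class TestGeneSetsForMate:
    def test_fully_inside_one_gene(self, disjoint_index):
        u, s, ne = gene_sets_for_mate(make_mate(120), disjoint_index)
        assert u == s == ne == {"A"}

    def test_half_exonic_half_intergenic(self, disjoint_index):
        """Overhanging reads: union and nonempty keep the gene, strict
        requires complete containment and drops it."""
        u, s, ne = gene_sets_for_mate(make_mate(250), disjoint_index)
        assert u == {"A"}
        assert s == frozenset()
        assert ne == {"A"}

    def test_span_of_two_genes_at_every_base(self):
        idx = build_index([make_gene("A", [(0, 300)]), make_gene("B", [(0, 300)])])
        u, s, ne = gene_sets_for_mate(make_mate(50), idx)
        assert u == s == ne == {"A", "B"}

    def test_read_across_overlap_boundary(self, two_gene_index):
        # [120,220) covers A-only, A∩B, and B-only bases
        u, s, ne = gene_sets_for_mate(make_mate(120), two_gene_index)
        assert u == {"A", "B"}
        assert s == frozenset()  # no gene covers every base
        assert ne == frozenset()

    def test_n_skips_reference_and_d_does_not(self, disjoint_index):
        # 50M then N over the intergenic gap, then 50M inside B
        spliced = make_mate(250, cigar=(("M", 50), ("N", 250), ("M", 50)))
        u, s, ne = gene_sets_for_mate(spliced, disjoint_index)
        assert u == {"A", "B"}
        # deletion consumes reference: a D over intergenic bases breaks strict
        deleted = make_mate(295, cigar=(("M", 5), ("D", 200), ("M", 50)))
        u2, s2, _ = gene_sets_for_mate(deleted, disjoint_index)
        assert u2 == {"A", "B"} and s2 == frozenset()

    def test_soft_clips_and_insertions_consume_no_reference(self, disjoint_index):
        m = make_mate(150, cigar=(("S", 20), ("M", 50), ("I", 5), ("M", 50)))
        u, s, ne = gene_sets_for_mate(m, disjoint_index)
        assert u == s == ne == {"A"}


class TestResolveFragment:
    @pytest.mark.parametrize("mode", ALL_MODES)
    def test_unique_fragment_inside_gene_assigned(self, mode, disjoint_index):
        f = make_fragment("f", [(make_mate(110), make_mate(180))])
        fate = resolve_fragment(f, mode, disjoint_index)
        assert fate.verdict == Verdict.ASSIGNED and fate.gene_id == "A"

    @pytest.mark.parametrize("mode", ALL_MODES)
    def test_multimapped_never_assigned(self, mode, disjoint_index):
        f = make_fragment(
            "f",
            [(make_mate(110), make_mate(180)), (make_mate(510), make_mate(580))],
        )
        fate = resolve_fragment(f, mode, disjoint_index)
        assert fate.verdict == Verdict.ALIGNMENT_NOT_UNIQUE
        assert fate.overlap_gene_sets == ({"A"}, {"B"})

    def test_mates_in_different_genes_union_is_ambiguous(self, disjoint_index):
        f = make_fragment("f", [(make_mate(150), make_mate(550))])
        fate = resolve_fragment(f, CountingMode.UNION, disjoint_index)
        assert fate.verdict == Verdict.AMBIGUOUS

    def test_intronic_fragment_is_no_feature(self, disjoint_index):
        f = make_fragment("f", [(make_mate(320), make_mate(380))])
        fate = resolve_fragment(f, CountingMode.UNION, disjoint_index)
        assert fate.verdict == Verdict.NO_FEATURE
        assert fate.overlap_gene_sets == ()  # nothing for stage 2

    def test_overhanging_no_feature_still_feeds_stage2(self, disjoint_index):
        # strict mode refuses the overhang, but the locus does touch gene A
        f = make_fragment("f", [(make_mate(250), make_mate(250))])
        fate = resolve_fragment(f, CountingMode.INTERSECTION_STRICT, disjoint_index)
        assert fate.verdict == Verdict.NO_FEATURE
        assert fate.overlap_gene_sets == ({"A"},)

    def test_single_end_fragment_resolves(self, disjoint_index):
        f = make_fragment("f", [(make_mate(110), None)])
        fate = resolve_fragment(f, CountingMode.UNION, disjoint_index)
        assert fate.verdict == Verdict.ASSIGNED and fate.gene_id == "A"

    def test_stranded_counting_respects_gene_strand(self):
        idx = build_index([make_gene("A", [(100, 300)], strand="+")])
        fwd = make_fragment("f", [(make_mate(110), make_mate(180, reverse=True))])
        rev = make_fragment(
            "r", [(make_mate(110, reverse=True), make_mate(180))]
        )
        for frag, expect in ((fwd, Verdict.ASSIGNED), (rev, Verdict.NO_FEATURE)):
            fate = resolve_fragment(frag, CountingMode.UNION, idx,
                                    stranded=Strandedness.YES)
            assert fate.verdict == expect
        # reverse protocol flips the expectation
        fate = resolve_fragment(rev, CountingMode.UNION, idx,
                                stranded=Strandedness.REVERSE)
        assert fate.verdict == Verdict.ASSIGNED


class TestCountStage1:
    def test_empty_stream_all_zero(self, disjoint_index):
        res = count_stage1([], CountingMode.UNION, disjoint_index)
        assert res.total_fragments == 0
        assert res.tallies_series().sum() == 0

    def test_counts_and_conservation(self, disjoint_index):
        frags = (
            [make_fragment(f"a{i}", [(make_mate(110), make_mate(180))])
             for i in range(5)]
            + [make_fragment("amb", [(make_mate(150), make_mate(550))])]
            + [make_fragment("nf", [(make_mate(320), make_mate(380))])]
            + [make_fragment("mm", [(make_mate(110), make_mate(180)),
                                    (make_mate(510), make_mate(580))])]
        )
        res = count_stage1(frags, CountingMode.UNION, disjoint_index,
                           not_aligned=2)
        assert res.counts["A"] == 5
        t = res.tallies_series()
        assert t.sum() == len(frags) + 2
        assert (t["assigned"], t["ambiguous"], t["no_feature"],
                t["alignment_not_unique"], t["not_aligned"]) == (5, 1, 1, 1, 2)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_mode_ordering_strict_within_nonempty(self, seed):
        """Strict can only lose assignments relative to nonempty."""
        rng = np.random.default_rng(seed)
        genes = [make_gene("A", [(100, 400)]), make_gene("B", [(300, 700)]),
                 make_gene("C", [(900, 1200)])]
        idx = build_index(genes)
        frags = []
        for i in range(30):
            p1 = int(rng.integers(0, 1200))
            p2 = min(p1 + int(rng.integers(0, 150)), 1300)
            frags.append(make_fragment(f"f{i}", [(make_mate(p1), make_mate(p2))]))
        assigned = {}
        for mode in (CountingMode.INTERSECTION_STRICT,
                     CountingMode.INTERSECTION_NONEMPTY):
            res = count_stage1(frags, mode, idx)
            assigned[mode] = {
                f.fragment_id for f in res.fates if f.verdict == Verdict.ASSIGNED
            }
        assert assigned[CountingMode.INTERSECTION_STRICT] <= assigned[
            CountingMode.INTERSECTION_NONEMPTY
        ]

    def test_fate_file_roundtrip(self, disjoint_index, tmp_path):
        frags = [
            make_fragment("u", [(make_mate(110), make_mate(180))]),
            make_fragment("m", [(make_mate(110), make_mate(180)),
                                (make_mate(510), make_mate(580))]),
            make_fragment("n", [(make_mate(320), make_mate(380))]),
        ]
        res = count_stage1(frags, CountingMode.UNION, disjoint_index)
        p = tmp_path / "fates.tsv"
        write_fates(res.fates, p)
        assert read_fates(p) == res.fates
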
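"""Stage 1: assign uniquely-mapped fragments to single genes.

Implements the three htseq-style overlap-resolution modes. For every aligned
base of a mate there is a set of genes whose exon union covers it; the modes
combine those per-base sets into one decision set per mate:

* union — the union over all aligned bases;
* intersection_strict — the intersection over *all* aligned bases, where a
  base covered by no feature contributes the empty set (a read is only
  assigned if completely contained within a single feature);
* intersection_nonempty — the intersection over only those aligned bases that
  overlap at least one feature.

For a pair, each mate's mode-level set is computed and the two are unioned
before the cardinality decision: one gene -> assigned, none -> no_feature,
several -> ambiguous. Multi-mapped fragments (NH > 1, or more than one
reported locus) are never assigned — they become ``alignment_not_unique`` and
their per-locus overlap sets are carried forward to stage 2.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .annotation import IntervalIndex
from .formats import AlignedFragment, MateAlignment

__all__ = [
    "CountingMode",
    "Strandedness",
    "Verdict",
    "FragmentFate",
    "Stage1Result",
    "gene_sets_for_mate",
    "resolve_fragment",
    "count_stage1",
    "write_fates",
    "read_fates",
]


class CountingMode(str, enum.Enum):
    UNION = "union"
    INTERSECTION_STRICT = "intersection-strict"
    INTERSECTION_NONEMPTY = "intersection-nonempty"


class Strandedness(str, enum.Enum):
    """Library strand protocol. Unstranded is the permissive default."""

    NO = "no"
    YES = "yes"
    REVERSE = "reverse"


class Verdict(str, enum.Enum):
    ASSIGNED = "assigned"
    NO_FEATURE = "no_feature"
    AMBIGUOUS = "ambiguous"
    ALIGNMENT_NOT_UNIQUE = "alignment_not_unique"
    NOT_ALIGNED = "not_aligned"


@dataclass(frozen=True)
class FragmentFate:
    """Stage-1 verdict for one fragment.

    ``overlap_gene_sets`` holds, per reported locus, the set of genes that
    locus overlaps by >= 1 base (both mates pooled) — the raw material stage 2
    builds multi-map groups from. Present only for fates that stage 2 may
    rescue.
    """

    fragment_id: str
    verdict: Verdict
    gene_id: str | None = None
    overlap_gene_sets: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if (self.verdict == Verdict.ASSIGNED) != (self.gene_id is not None):
            raise ValueError("gene_id must be present iff verdict is 'assigned'")


def _aligned_blocks(mate: MateAlignment) -> Iterator[tuple[int, int]]:
    """Reference intervals covered by M/=/X/D; N skips, I/S/H consume none."""
    pos = mate.pos
    for op, length in mate.cigar:
        if op in "M=XD":
            yield pos, pos + length
            pos += length
        elif op == "N":
            pos += length


def gene_sets_for_mate(
    mate: MateAlignment,
    index: IntervalIndex,
    allowed_strand: str | None = None,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Per-base gene-set summary of one mate: (union, strict, nonempty).

    ``allowed_strand`` restricts features to one strand (stranded protocols);
    None means unstranded.
    """
    union: set[str] = set()
    strict: frozenset[str] | None = None
    nonempty: frozenset[str] | None = None
    saw_uncovered = False
    for bs, be in _aligned_blocks(mate):
        for _s, _e, genes in index.segments(mate.ref_name, bs, be):
            if allowed_strand is not None:
                genes = frozenset(
                    g for g in genes if index.strand.get(g, ".") in (allowed_strand, ".")
                )
            if genes:
                union |= genes
                strict = genes if strict is None else strict & genes
                nonempty = genes if nonempty is None else nonempty & genes
            else:
                saw_uncovered = True
    u = frozenset(union)
    i_strict = frozenset() if (saw_uncovered or strict is None) else strict
    i_nonempty = frozenset() if nonempty is None else nonempty
    return u, i_strict, i_nonempty


def _mode_set(
    mate: MateAlignment,
    mode: CountingMode,
    index: IntervalIndex,
    allowed_strand: str | None = None,
) -> frozenset[str]:
    u, i_strict, i_nonempty = gene_sets_for_mate(mate, index, allowed_strand)
    if mode == CountingMode.UNION:
        return u
    if mode == CountingMode.INTERSECTION_STRICT:
        return i_strict
    return i_nonempty


def _expected_strand(
    mate: MateAlignment, is_read2: bool, stranded: Strandedness
) -> str | None:
    if stranded == Strandedness.NO:
        return None
    # fragment strand inferred from this mate's orientation
    frag_strand = ("-" if mate.reverse else "+") if not is_read2 else (
        "+" if mate.reverse else "-"
    )
    if stranded == Strandedness.REVERSE:
        frag_strand = "+" if frag_strand == "-" else "-"
    return frag_strand


def _locus_overlap_set(locus, index: IntervalIndex) -> frozenset[str]:
    genes: set[str] = set()
    for mate in locus.mates:
        for bs, be in _aligned_blocks(mate):
            genes |= index.query_range(mate.ref_name, bs, be)
    return frozenset(genes)


def resolve_fragment(
    fragment: AlignedFragment,
    mode: CountingMode,
    index: IntervalIndex,
    stranded: Strandedness = Strandedness.NO,
) -> FragmentFate:
    """Decide the fate of one fragment under the given mode."""
    overlap_sets = tuple(_locus_overlap_set(l, index) for l in fragment.loci)
    if fragment.is_multimapped:
        return FragmentFate(
            fragment.fragment_id,
            Verdict.ALIGNMENT_NOT_UNIQUE,
            overlap_gene_sets=overlap_sets,
        )
    locus = fragment.loci[0]
    decision: frozenset[str] = frozenset()
    for mate, is_read2 in ((locus.mate1, False), (locus.mate2, True)):
        if mate is None:
            continue
        decision |= _mode_set(
            mate, mode, index, _expected_strand(mate, is_read2, stranded)
        )
    if len(decision) == 1:
        return FragmentFate(fragment.fragment_id, Verdict.ASSIGNED,
                            gene_id=next(iter(decision)))
    if len(decision) == 0:
        # forward to stage 2 only if some locus overlaps some gene at all
        carried = overlap_sets if any(overlap_sets) else ()
        return FragmentFate(fragment.fragment_id, Verdict.NO_FEATURE,
                            overlap_gene_sets=carried)
    return FragmentFate(fragment.fragment_id, Verdict.AMBIGUOUS,
                        overlap_gene_sets=overlap_sets)


@dataclass
class Stage1Result:
    """Per-gene counts, fate tallies, and the full fate list of one sample."""

    counts: Counter = field(default_factory=Counter)
    tallies: Counter = field(default_factory=Counter)
    fates: list[FragmentFate] = field(default_factory=list)

    @property
    def total_fragments(self) -> int:
        return sum(self.tallies.values())

    @property
    def unassigned(self) -> int:
        """Fragments not uniquely assigned to a single gene."""
        return self.total_fragments - self.tallies[Verdict.ASSIGNED]

    def counts_series(self, gene_ids: Iterable[str] | None = None) -> pd.Series:
        """Counts as a Series; ``gene_ids`` fixes the universe (zeros filled)."""
        if gene_ids is None:
            return pd.Series(dict(self.counts), dtype="int64").sort_index()
        return pd.Series({g: self.counts.get(g, 0) for g in gene_ids},
                         dtype="int64")

    def tallies_series(self) -> pd.Series:
        return pd.Series({v.value: self.tallies.get(v, 0) for v in Verdict},
                         dtype="int64")


def count_stage1(
    fragments: Iterable[AlignedFragment],
    mode: CountingMode,
    index: IntervalIndex,
    stranded: Strandedness = Strandedness.NO,
    not_aligned: int = 0,
    keep_fates: bool = True,
) -> Stage1Result:
    """Run stage 1 over a fragment stream.

    Counts are fragment-level: a read pair counts once. ``not_aligned`` adds
    unmapped records (which never form fragments) to the tallies so the
    conservation identity — the five tallies sum to the total number of
    fragments — holds for real SAM input too.
    """
    result = Stage1Result()
    result.tallies[Verdict.NOT_ALIGNED] = not_aligned
    for frag in fragments:
        fate = resolve_fragment(frag, mode, index, stranded)
        result.tallies[fate.verdict] += 1
        if fate.verdict == Verdict.ASSIGNED:
            result.counts[fate.gene_id] += 1
        if keep_fates:
            result.fates.append(fate)
    # reader objects expose unmapped-record tallies only after iteration
    if hasattr(fragments, "not_aligned"):
        result.tallies[Verdict.NOT_ALIGNED] += fragments.not_aligned
    return result


# ---------------------------------------------------------------------------
# Fate files (the per-read fate export that feeds stage 2)

_SET_SEP = ";"
_GENE_SEP = ","


def write_fates(fates: Iterable[FragmentFate], path) -> None:
    """Write fates as TSV: fragment_id, verdict, gene_id, per-locus gene sets.

    Loci are ';'-separated, genes within a locus ','-separated and sorted.
    """
    with open(path, "w") as fh:
        fh.write("fragment_id\tverdict\tgene_id\toverlap_gene_sets\n")
        for fate in fates:
            sets = _SET_SEP.join(
                _GENE_SEP.join(sorted(s)) for s in fate.overlap_gene_sets
            )
            fh.write(
                f"{fate.fragment_id}\t{fate.verdict.value}\t"
                f"{fate.gene_id or ''}\t{sets}\n"
            )


def read_fates(path) -> list[FragmentFate]:
    """Read a fate TSV written by :func:`write_fates`."""
    fates: list[FragmentFate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["fragment_id", "verdict"]:
            raise ValueError(f"{path}: not a fate file")
        for line in fh:
            fid, verdict, gene_id, sets = (line.rstrip("\n").split("\t") + [""])[:4]
            overlap = tuple(
                frozenset(g for g in chunk.split(_GENE_SEP) if g)
                for chunk in sets.split(_SET_SEP)
                if chunk
            ) if sets else ()
            fates.append(
                FragmentFate(
                    fragment_id=fid,
                    verdict=Verdict(verdict),
                    gene_id=gene_id or None,
                    overlap_gene_sets=overlap,
                )
            )
    return fates
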
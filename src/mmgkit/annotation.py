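"""Queryable gene models and per-gene characteristic statistics.

Gene models are built from annotation records; all internal coordinates are
0-based half-open. Overlap, for both counting and multi-map-group purposes, is
measured against a gene's *exon union* (the merged exons of all its
transcripts), never the gene body: intronic alignments are "no_feature".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .formats import AlignedFragment, AnnotationRecord

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "GeneCharacteristics",
    "IntervalIndex",
    "build_gene_models",
    "build_index",
    "select_reference_transcript",
    "characterize_gene",
    "filter_genes",
    "gc_percent",
]


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    @property
    def length(self) -> int:
        """Summed exon length in bp."""
        return sum(e - s for s, e in self.exons)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A gene with its transcripts and exons on one reference sequence."""

    gene_id: str
    seq_id: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = ""

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        """Disjoint sorted intervals covering all exons of all transcripts."""
        return _merge_intervals(
            (s, e) for t in self.transcripts for s, e in t.exons
        )

    @property
    def span(self) -> tuple[int, int]:
        union = self.exon_union
        return union[0][0], union[-1][1]


def build_gene_models(records: Iterable[AnnotationRecord]) -> list[GeneModel]:
    """Assemble exon records into :class:`GeneModel` objects.

    Gene/transcript rows contribute strand and biotype metadata; exon rows
    define the structure. Order of first appearance is preserved.
    """
    genes: dict[str, GeneModel] = {}
    tx: dict[tuple[str, str], TranscriptModel] = {}
    for rec in records:
        if not rec.gene_id:
            continue
        gene = genes.get(rec.gene_id)
        if gene is None:
            gene = GeneModel(
                gene_id=rec.gene_id,
                seq_id=rec.seq_id,
                strand=rec.strand,
                biotype=rec.attributes.get("gene_biotype", ""),
            )
            genes[rec.gene_id] = gene
        if not gene.biotype and rec.attributes.get("gene_biotype"):
            gene.biotype = rec.attributes["gene_biotype"]
        if rec.feature_type != "exon":
            continue
        key = (rec.gene_id, rec.transcript_id)
        t = tx.get(key)
        if t is None:
            t = TranscriptModel(transcript_id=rec.transcript_id, exons=[])
            tx[key] = t
            gene.transcripts.append(t)
        t.exons.append((rec.start0, rec.end0))
    for t in tx.values():
        t.exons.sort()
    return list(genes.values())


class IntervalIndex:
    """Searchable map from reference positions to gene_ids (exon unions).

    Queries use half-open semantics: ``query_point(p)`` returns exactly the
    genes whose exon union covers ``p``.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.strand: dict[str, str] = {}
        seen: set[str] = set()
        for gene in genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {gene.gene_id}")
            seen.add(gene.gene_id)
            self.strand[gene.gene_id] = gene.strand
            tree = self._trees.setdefault(gene.seq_id, IntervalTree())
            for s, e in gene.exon_union:
                tree.addi(s, e, gene.gene_id)

    def query_point(self, seq_id: str, pos: int) -> frozenset[str]:
        tree = self._trees.get(seq_id)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.at(pos))

    def query_range(self, seq_id: str, start: int, end: int) -> frozenset[str]:
        """Genes whose exon union overlaps [start, end) by >= 1 base."""
        tree = self._trees.get(seq_id)
        if tree is None or start >= end:
            return frozenset()
        return frozenset(iv.data for iv in tree.overlap(start, end))

    def segments(
        self, seq_id: str, start: int, end: int
    ) -> list[tuple[int, int, frozenset[str]]]:
        """Partition [start, end) at exon boundaries.

        Returns (seg_start, seg_end, genes) triples covering the whole range in
        order; ``genes`` is the set covering every base of the segment. This is
        the per-base gene-set view used by the counting modes, without a
        per-base loop.
        """
        tree = self._trees.get(seq_id)
        if start >= end:
            return []
        if tree is None:
            return [(start, end, frozenset())]
        hits = sorted(tree.overlap(start, end))
        bounds = {start, end}
        for iv in hits:
            if start < iv.begin < end:
                bounds.add(iv.begin)
            if start < iv.end < end:
                bounds.add(iv.end)
        edges = sorted(bounds)
        out: list[tuple[int, int, frozenset[str]]] = []
        for s, e in zip(edges, edges[1:]):
            covering = frozenset(iv.data for iv in hits if iv.begin <= s and iv.end >= e)
            out.append((s, e, covering))
        return out


def build_index(genes: Iterable[GeneModel]) -> IntervalIndex:
    """Build an :class:`IntervalIndex` over validated gene models."""
    return IntervalIndex(genes)


def select_reference_transcript(gene: GeneModel) -> TranscriptModel:
    """The single longest transcript (summed exon length).

    Ties break to the lexicographically smallest transcript_id so the choice
    is deterministic.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(gene.transcripts, key=lambda t: (-t.length, t.transcript_id))


def gc_percent(seq: str) -> float:
    """Percentage of G/C bases in ``seq`` (case-insensitive)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class GeneCharacteristics:
    """Per-gene summary statistics over the reference (longest) transcript."""

    gene_id: str
    min_exon_len: int
    max_exon_len: int
    mean_exon_len: float
    n_exons: int
    transcript_len: int
    gc_percent: float
    overlapping_fragments: int


def characterize_gene(
    gene: GeneModel,
    fragments: Iterable[AlignedFragment] = (),
    sequence: str | None = None,
) -> GeneCharacteristics:
    """Exon-length/GC statistics plus the count of overlapping fragments.

    Statistics are computed over the reference (longest) transcript's exons.
    ``overlapping_fragments`` counts each fragment once if *any* of its loci
    overlaps the gene's exon union by at least one base — multi-mapped
    fragments from near-identical paralogues therefore inflate it, which is
    exactly the signal it exists to expose. ``sequence`` is the spliced
    transcript sequence (for GC); omit it to get gc_percent 0.
    """
    ref = select_reference_transcript(gene)
    lens = [e - s for s, e in ref.exons]
    union = gene.exon_union
    n_overlap = 0
    for frag in fragments:
        hit = False
        for locus in frag.loci:
            for mate in locus.mates:
                if mate.ref_name != gene.seq_id:
                    continue
                s, e = mate.pos, mate.ref_end
                if any(s < ue and us < e for us, ue in union):
                    hit = True
                    break
            if hit:
                break
        n_overlap += hit
    return GeneCharacteristics(
        gene_id=gene.gene_id,
        min_exon_len=min(lens),
        max_exon_len=max(lens),
        mean_exon_len=fmean(lens),
        n_exons=len(lens),
        transcript_len=ref.length,
        gc_percent=gc_percent(sequence) if sequence else 0.0,
        overlapping_fragments=n_overlap,
    )


def filter_genes(
    genes: Iterable[GeneModel],
    min_transcript_len: int = 400,
    biotypes: frozenset[str] | set[str] | None = frozenset({"protein_coding"}),
) -> list[GeneModel]:
    """Keep protein-coding genes whose reference transcript exceeds 400 bp.

    This mirrors the transcript-selection rule used to define the simulation
    universe: biotype filter first (skipped when ``biotypes`` is None or when
    a gene carries no biotype metadata at all), then strict length cut on the
    longest transcript.
    """
    kept = []
    for gene in genes:
        if biotypes is not None and gene.biotype and gene.biotype not in biotypes:
            continue
        if select_reference_transcript(gene).length > min_transcript_len:
            kept.append(gene)
    return kept
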
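"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate convention: GTF is 1-based inclusive on disk and is converted
exactly once, here at the I/O boundary, to 0-based half-open coordinates.
Everything downstream (gene models, interval index, alignments) is 0-based
half-open.

SAM multi-mapping convention: a fragment with k reported loci appears as one
primary record plus k-1 secondary records per mate, each carrying an ``NH:i``
tag equal to k. NH is the authoritative multi-mapping signal; the number of
reported loci is the fallback when NH is absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from gffutils.feature import feature_from_line

__all__ = [
    "AnnotationRecord",
    "MateAlignment",
    "PairedLocus",
    "AlignedFragment",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "FragmentReader",
    "read_sam_fragments",
    "write_count_table",
    "read_count_table",
]

_KEPT_FEATURES = frozenset({"gene", "transcript", "exon"})

# CIGAR operation codes as used by pysam / the SAM spec.
_CIGAR_OPS = "MIDNSHP=X"


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; message names the line number."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene/transcript/exon row of an annotation.

    ``start``/``end`` are 1-based inclusive, exactly as on disk in GTF.
    """

    seq_id: str
    feature_type: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str = ""
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end ({self.start} > {self.end}) for {self.gene_id!r}"
            )
        if self.feature_type == "exon" and not self.gene_id:
            raise ValueError("exon record without gene_id")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end


def read_gtf(path: str | Path) -> list[AnnotationRecord]:
    """Parse a GTF file into :class:`AnnotationRecord` objects.

    Comment lines (``#``) are skipped; feature types other than gene,
    transcript and exon are ignored. A malformed line raises
    :class:`GtfParseError` naming the 1-based line number.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            if fields[2] not in _KEPT_FEATURES:
                continue
            try:
                feat = feature_from_line(line, dialect=None)
                gene_id = feat.attributes.get("gene_id", [""])[0]
                transcript_id = feat.attributes.get("transcript_id", [""])[0]
                extra = {
                    k: v[0]
                    for k, v in feat.attributes.items()
                    if k not in ("gene_id", "transcript_id")
                }
                rec = AnnotationRecord(
                    seq_id=feat.seqid,
                    feature_type=feat.featuretype,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    attributes=extra,
                )
            except GtfParseError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with line number
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            if rec.feature_type == "exon" and not rec.gene_id:
                raise GtfParseError(f"line {lineno}: exon record without gene_id")
            records.append(rec)
    return records


def write_gtf(records: Iterable[AnnotationRecord], path: str | Path,
              source: str = "mmgkit") -> None:
    """Write annotation records as Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for rec in records:
            attrs = f'gene_id "{rec.gene_id}";'
            if rec.transcript_id:
                attrs += f' transcript_id "{rec.transcript_id}";'
            for key, val in rec.attributes.items():
                attrs += f' {key} "{val}";'
            fh.write(
                f"{rec.seq_id}\t{source}\t{rec.feature_type}\t{rec.start}\t"
                f"{rec.end}\t.\t{rec.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Write (name, sequence) reads as FASTQ with a constant Phred+33 quality.

    The default 'I' (Q40) encodes the zero-error contract of simulated reads.
    """
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# SAM fragments


@dataclass(frozen=True)
class MateAlignment:
    """One mate aligned at one locus (0-based half-open reference coords)."""

    ref_name: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    reverse: bool = False

    @property
    def ref_end(self) -> int:
        """End of the reference span (M/D/N/=/X consume reference)."""
        end = self.pos
        for op, length in self.cigar:
            if op in "MDN=X":
                end += length
        return end


@dataclass(frozen=True)
class PairedLocus:
    """One reported locus of a fragment: both mates, either possibly absent."""

    mate1: MateAlignment | None
    mate2: MateAlignment | None

    @property
    def mates(self) -> tuple[MateAlignment, ...]:
        return tuple(m for m in (self.mate1, self.mate2) if m is not None)


@dataclass
class AlignedFragment:
    """One sequenced fragment (read pair) with all reported alignment loci.

    The unit of counting: a pair counts once, however many records describe it.
    """

    fragment_id: str
    loci: list[PairedLocus]
    nh: int

    @property
    def is_multimapped(self) -> bool:
        return self.nh > 1 or len(self.loci) > 1


def _cigar_from_pysam(cigartuples) -> tuple[tuple[str, int], ...]:
    return tuple((_CIGAR_OPS[op], length) for op, length in cigartuples)


class FragmentReader:
    """Iterate a SAM file as :class:`AlignedFragment` objects.

    All records sharing a query name (both mates, all loci) are merged into one
    fragment, yielded in first-seen order. Unmapped records (flag 0x4) are
    tallied in :attr:`not_aligned` and never become fragments. A paired record
    whose partner never appears yields a single-end locus and increments
    :attr:`orphan_mates`.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.not_aligned = 0
        self.orphan_mates = 0
        self.records_consumed = 0

    def __iter__(self) -> Iterator[AlignedFragment]:
        groups: dict[str, list] = {}
        order: list[str] = []
        with pysam.AlignmentFile(self.path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    self.not_aligned += 1
                    continue
                self.records_consumed += 1
                if rec.query_name not in groups:
                    groups[rec.query_name] = []
                    order.append(rec.query_name)
                groups[rec.query_name].append(
                    (
                        rec.is_read2,
                        rec.reference_name,
                        rec.reference_start,
                        _cigar_from_pysam(rec.cigartuples or ()),
                        rec.is_reverse,
                        rec.get_tag("NH") if rec.has_tag("NH") else None,
                        rec.next_reference_name,
                        rec.next_reference_start,
                        rec.is_paired,
                    )
                )
        for qname in order:
            yield self._build_fragment(qname, groups[qname])

    def _build_fragment(self, qname: str, recs: list) -> AlignedFragment:
        mate1 = [r for r in recs if not r[0]]
        mate2 = [r for r in recs if r[0]]
        nh_tags = [r[5] for r in recs if r[5] is not None]
        nh = max(nh_tags) if nh_tags else max(len(mate1), len(mate2), 1)

        def mk(r) -> MateAlignment:
            return MateAlignment(ref_name=r[1], pos=r[2], cigar=r[3], reverse=r[4])

        # Pair mate1 loci with mate2 loci through RNEXT/PNEXT; leftovers become
        # single-end loci (orphans).
        m2_by_pos: dict[tuple[str, int], list] = {}
        for r in mate2:
            m2_by_pos.setdefault((r[1], r[2]), []).append(r)
        loci: list[PairedLocus] = []
        for r in mate1:
            partner_key = (r[6], r[7])
            bucket = m2_by_pos.get(partner_key)
            if bucket:
                loci.append(PairedLocus(mate1=mk(r), mate2=mk(bucket.pop(0))))
            else:
                loci.append(PairedLocus(mate1=mk(r), mate2=None))
                if r[8]:
                    self.orphan_mates += 1
        for bucket in m2_by_pos.values():
            for r in bucket:
                loci.append(PairedLocus(mate1=None, mate2=mk(r)))
                if r[8]:
                    self.orphan_mates += 1
        if self.orphan_mates:
            pass  # counter is the warning surface; no per-fragment noise
        loci.sort(key=lambda l: (l.mates[0].ref_name, l.mates[0].pos))
        return AlignedFragment(fragment_id=qname, loci=loci, nh=nh)


def read_sam_fragments(path: str | Path) -> FragmentReader:
    """Open a SAM file for fragment-level iteration (see :class:`FragmentReader`)."""
    reader = FragmentReader(path)
    return reader


# ---------------------------------------------------------------------------
# Count tables


def write_count_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a gene/MMG x sample matrix as TSV with an ``id`` index column.

    Row keys must be unique (MMG keys use the ``G1|G2`` serialization).
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row keys: {dupes}")
    matrix.to_csv(path, sep="\t", index_label="id")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_count_table`; integer counts survive."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row keys: {dupes}")
    df.index.name = None
    return df
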
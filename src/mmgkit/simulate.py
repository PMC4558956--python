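"""Synthetic transcriptomes, perfect paired-end reads, and a truth aligner.

The generator emulates the study conditions every downstream stage is tested
under: a transcriptome mixing unique genes with near-identical gene families
(paralogue/pseudogene copies), 100-bp paired-end reads with a 250-bp insert
and zero errors, and alignments that report *all* equally-best loci per
fragment.

Reads are simulated from transcript sequence and aligned against the genome
the transcripts are embedded in. Because reads are perfect, alignment is exact
substring matching: the truth aligner indexes every read-length k-mer of every
transcript and projects hits to genome coordinates through the known embedding
layout. On toy genomes this equals a naive all-positions string scan, which the
test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .formats import (
    AlignedFragment,
    AnnotationRecord,
    MateAlignment,
    PairedLocus,
    write_fasta,
    write_fastq,
    write_gtf,
)

__all__ = [
    "SimDesign",
    "SimTruth",
    "SimulatedPair",
    "TranscriptLayout",
    "Transcriptome",
    "generate_transcriptome",
    "simulate_pairs",
    "simulate_reads",
    "count_pairs",
    "TruthAligner",
    "truth_align",
    "write_truth_sam",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a simulation run.

    ``pairs_per_gene`` is either a fixed integer (the global design: 1000
    perfect pairs from every gene) or an inclusive integer range ``(lo, hi)``
    (the targeted design: a random depth between 100 and 100,000 per gene).
    ``family_spec`` lists duplicated gene groups as (family_size,
    divergence_rate) pairs; divergence 0 gives byte-identical copies.
    """

    n_genes: int
    pairs_per_gene: int | tuple[int, int] = 1000
    read_len: int = 100
    insert_len: int = 250
    min_transcript_len: int = 400
    max_transcript_len: int = 1500
    family_spec: tuple[tuple[int, float], ...] = ()
    intergenic_len: int = 100
    n_exons: int = 1
    intron_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_len < self.read_len:
            raise ValueError("insert_len must be >= read_len")
        if self.min_transcript_len < self.insert_len:
            raise ValueError("min_transcript_len must be >= insert_len")
        for size, div in self.family_spec:
            if not 0.0 <= div <= 1.0:
                raise ValueError(f"divergence_rate {div} outside [0, 1]")
            if size < 2:
                raise ValueError("family_size must be >= 2")
        if isinstance(self.pairs_per_gene, tuple):
            lo, hi = self.pairs_per_gene
            if not 0 <= lo <= hi:
                raise ValueError("pairs_per_gene range must satisfy 0 <= lo <= hi")

    @property
    def n_family_genes(self) -> int:
        return sum(size for size, _ in self.family_spec)

    @property
    def total_genes(self) -> int:
        return self.n_genes + self.n_family_genes


@dataclass(frozen=True)
class TranscriptLayout:
    """Where one transcript lives in the synthetic genome.

    ``blocks`` are the exon intervals (0-based half-open genome coordinates)
    in transcript order; a contiguous embedding has a single block.
    """

    gene_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]

    @property
    def transcript_len(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def project(self, t_start: int, length: int) -> tuple[int, tuple[tuple[str, int], ...]]:
        """Map a transcript interval to (genome_pos, cigar) with N gaps."""
        ops: list[tuple[str, int]] = []
        pos = None
        remaining = length
        offset = t_start
        for i, (bs, be) in enumerate(self.blocks):
            blen = be - bs
            if offset >= blen:
                offset -= blen
                continue
            take = min(blen - offset, remaining)
            if pos is None:
                pos = bs + offset
            else:
                gap = bs - self.blocks[i - 1][1]
                if gap > 0:
                    ops.append(("N", gap))
            ops.append(("M", take))
            remaining -= take
            offset = 0
            if remaining == 0:
                break
        if remaining > 0 or pos is None:
            raise ValueError("interval extends beyond transcript")
        # merge adjacent M ops (blocks abutting with zero-length gap)
        merged: list[tuple[str, int]] = []
        for op, ln in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return pos, tuple(merged)


@dataclass
class Transcriptome:
    """Generated transcripts, their genome embedding, and the annotation."""

    transcripts: dict[str, str]  # gene_id -> spliced transcript sequence
    layouts: dict[str, TranscriptLayout]
    genome: dict[str, str]
    annotation: list[AnnotationRecord]
    families: dict[str, list[str]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.transcripts)

    def transcript_len(self, gene_id: str) -> int:
        return len(self.transcripts[gene_id])


@dataclass(frozen=True)
class SimulatedPair:
    """One perfect read pair and its true origin."""

    fragment_id: str
    gene_id: str
    t_start: int  # fragment start on the transcript
    mate1: str
    mate2: str  # as sequenced: reverse-complement of the fragment's 3' end


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-gene depth and per-fragment origins."""

    true_counts: dict[str, int]
    origins: list[tuple[str, str, int]]  # (fragment_id, gene_id, t_start)

    @property
    def total_pairs(self) -> int:
        return sum(self.true_counts.values())


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = {65: 0, 67: 1, 71: 2, 84: 3}
    codes = np.vectorize(idx.get)(arr) if len(arr) else arr
    mask = rng.random(len(arr)) < rate
    shift = rng.integers(1, 4, size=len(arr))
    codes = np.where(mask, (codes + shift) % 4, codes)
    return bytes(_BASES[codes]).decode()


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def generate_transcriptome(design: SimDesign, max_retries: int = 20) -> Transcriptome:
    """Generate transcripts, embed them in a genome, and write the annotation.

    Unique genes get i.i.d. random sequence; each family is one ancestral
    sequence copied ``family_size`` times with per-base substitution at its
    divergence rate. Transcripts from *different* families (or unique genes)
    are checked to share no read-length k-mer and regenerated on collision, so
    multi-mapping arises only where the design asks for it. Deterministic under
    a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    chrom = "chr1"

    # family membership: gene_id -> family key (unique genes are their own key)
    members: list[tuple[str, str]] = []  # (gene_id, family_key)
    for i in range(design.n_genes):
        gid = f"G{i + 1:05d}"
        members.append((gid, gid))
    for fi, (size, _div) in enumerate(design.family_spec, start=1):
        for m in range(size):
            members.append((f"F{fi}_{m + 1}", f"F{fi}"))

    k = design.read_len
    seen_kmers: dict[str, str] = {}  # kmer -> family_key of owner

    def draw_len() -> int:
        return int(rng.integers(design.min_transcript_len,
                                design.max_transcript_len + 1))

    def admit(seq: str, fam: str) -> bool:
        """Register k-mers unless another family already owns one."""
        new = [km for km in set(_kmers(seq, k)) if seen_kmers.get(km, fam) != fam]
        if new:
            return False
        for km in _kmers(seq, k):
            seen_kmers[km] = fam
        return True

    transcripts: dict[str, str] = {}
    fam_ancestors: dict[str, tuple[str, float]] = {}
    for fi, (size, div) in enumerate(design.family_spec, start=1):
        fam_ancestors[f"F{fi}"] = ("", div)

    for gid, fam in members:
        if fam in fam_ancestors:
            anc, div = fam_ancestors[fam]
            if not anc:
                for _ in range(max_retries):
                    anc = _random_seq(rng, draw_len())
                    if admit(anc, fam):
                        break
                else:
                    raise RuntimeError("could not generate distinct ancestral sequence")
                fam_ancestors[fam] = (anc, div)
            for _ in range(max_retries):
                seq = _mutate(rng, anc, div)
                if admit(seq, fam):
                    break
            else:
                raise RuntimeError("could not generate family member sequence")
        else:
            for _ in range(max_retries):
                seq = _random_seq(rng, draw_len())
                if admit(seq, fam):
                    break
            else:
                raise RuntimeError("could not generate distinct gene sequence")
        transcripts[gid] = seq

    # embed on one chromosome, in order, separated by random intergenic filler
    genome_parts: list[str] = []
    layouts: dict[str, TranscriptLayout] = {}
    annotation: list[AnnotationRecord] = []
    cursor = 0
    for gid, seq in transcripts.items():
        filler = _random_seq(rng, design.intergenic_len)
        genome_parts.append(filler)
        cursor += len(filler)
        blocks: list[tuple[int, int]] = []
        if design.n_exons <= 1:
            exon_lens = [len(seq)]
        else:
            base = len(seq) // design.n_exons
            exon_lens = [base] * design.n_exons
            exon_lens[-1] += len(seq) - base * design.n_exons
        t_off = 0
        for j, elen in enumerate(exon_lens):
            if j > 0 and design.intron_len > 0:
                intron = _random_seq(rng, design.intron_len)
                genome_parts.append(intron)
                cursor += design.intron_len
            genome_parts.append(seq[t_off : t_off + elen])
            blocks.append((cursor, cursor + elen))
            cursor += elen
            t_off += elen
        layout = TranscriptLayout(gene_id=gid, chrom=chrom, blocks=tuple(blocks))
        layouts[gid] = layout
        tid = f"{gid}.1"
        span = (blocks[0][0] + 1, blocks[-1][1])  # 1-based inclusive
        attrs = {"gene_biotype": "protein_coding"}
        annotation.append(AnnotationRecord(chrom, "gene", span[0], span[1], "+",
                                           gid, "", dict(attrs)))
        annotation.append(AnnotationRecord(chrom, "transcript", span[0], span[1],
                                           "+", gid, tid, dict(attrs)))
        for bs, be in blocks:
            annotation.append(AnnotationRecord(chrom, "exon", bs + 1, be, "+",
                                               gid, tid, dict(attrs)))
    genome_parts.append(_random_seq(rng, design.intergenic_len))

    families = {}
    for fi, (size, _div) in enumerate(design.family_spec, start=1):
        families[f"F{fi}"] = [f"F{fi}_{m + 1}" for m in range(size)]

    return Transcriptome(
        transcripts=transcripts,
        layouts=layouts,
        genome={chrom: "".join(genome_parts)},
        annotation=annotation,
        families=families,
    )


def simulate_pairs(
    transcript_seq: str,
    n_pairs: int,
    read_len: int,
    insert_len: int,
    rng: np.random.Generator,
    gene_id: str = "gene",
    id_offset: int = 0,
) -> list[SimulatedPair]:
    """Simulate perfect read pairs from one transcript.

    Fragment starts are uniform on [0, L - insert_len]; mate 1 is the first
    ``read_len`` bases of the fragment, mate 2 the reverse complement of its
    last ``read_len`` bases. Zero errors. A transcript shorter than the insert
    is an error — the reason short transcripts are excluded upstream.
    """
    L = len(transcript_seq)
    if L < insert_len:
        raise ValueError(
            f"transcript length {L} < insert length {insert_len}"
        )
    if n_pairs == 0:
        return []
    starts = rng.integers(0, L - insert_len + 1, size=n_pairs)
    out: list[SimulatedPair] = []
    for i, st in enumerate(starts):
        st = int(st)
        frag = transcript_seq[st : st + insert_len]
        out.append(
            SimulatedPair(
                fragment_id=f"{gene_id}:{id_offset + i}",
                gene_id=gene_id,
                t_start=st,
                mate1=frag[:read_len],
                mate2=revcomp(frag[insert_len - read_len :]),
            )
        )
    return out


def _draw_depth(design: SimDesign, rng: np.random.Generator) -> int:
    if isinstance(design.pairs_per_gene, tuple):
        lo, hi = design.pairs_per_gene
        return int(rng.integers(lo, hi + 1))
    return int(design.pairs_per_gene)


def simulate_reads(
    transcriptome: Transcriptome, design: SimDesign, seed: int | None = None
) -> tuple[list[SimulatedPair], SimTruth]:
    """Simulate the whole design: every gene at its (fixed or drawn) depth."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pairs: list[SimulatedPair] = []
    counts: dict[str, int] = {}
    for gid, seq in transcriptome.transcripts.items():
        n = _draw_depth(design, rng)
        counts[gid] = n
        pairs.extend(
            simulate_pairs(seq, n, design.read_len, design.insert_len, rng,
                           gene_id=gid)
        )
    origins = [(p.fragment_id, p.gene_id, p.t_start) for p in pairs]
    return pairs, SimTruth(true_counts=counts, origins=origins)


def count_pairs(design: SimDesign, seed: int | None = None) -> tuple[int, dict[str, int]]:
    """Count-only mode: per-gene depths and the total, with no sequence work.

    Uses the same depth rule as :func:`simulate_reads` (fixed depth is exact;
    ranged depth is drawn). Gene ids follow the generator's naming.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ids = [f"G{i + 1:05d}" for i in range(design.n_genes)]
    for fi, (size, _d) in enumerate(design.family_spec, start=1):
        ids.extend(f"F{fi}_{m + 1}" for m in range(size))
    counts = {gid: _draw_depth(design, rng) for gid in ids}
    return sum(counts.values()), counts


class TruthAligner:
    """Report every exact-match locus of each perfect read.

    Index: every read-length k-mer of every transcript, mapped back to genome
    coordinates through the embedding layout. Mates are paired per transcript
    occurrence at the design insert spacing; NH is the number of paired loci.
    Loci are ordered by (chromosome, position) and the lowest-coordinate locus
    is primary, so output is deterministic.
    """

    def __init__(self, transcriptome: Transcriptome, read_len: int, insert_len: int):
        self.transcriptome = transcriptome
        self.read_len = read_len
        self.insert_len = insert_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for gid, seq in transcriptome.transcripts.items():
            for off in range(len(seq) - read_len + 1):
                self._index.setdefault(seq[off : off + read_len], []).append((gid, off))

    def align_pair(self, pair: SimulatedPair) -> AlignedFragment:
        rl, il = self.read_len, self.insert_len
        hits1 = self._index.get(pair.mate1, [])
        hits2 = self._index.get(revcomp(pair.mate2), [])
        if not hits1 or not hits2:
            raise ValueError(
                f"fragment {pair.fragment_id}: read has no exact locus "
                "(violates the perfect-read contract)"
            )
        want = il - rl
        h2 = {(gid, off) for gid, off in hits2}
        loci: list[PairedLocus] = []
        for gid, o1 in hits1:
            if (gid, o1 + want) not in h2:
                continue
            layout = self.transcriptome.layouts[gid]
            p1, c1 = layout.project(o1, rl)
            p2, c2 = layout.project(o1 + want, rl)
            loci.append(
                PairedLocus(
                    mate1=MateAlignment(layout.chrom, p1, c1, reverse=False),
                    mate2=MateAlignment(layout.chrom, p2, c2, reverse=True),
                )
            )
        if not loci:
            raise ValueError(
                f"fragment {pair.fragment_id}: mates have no concordant locus"
            )
        loci.sort(key=lambda l: (l.mate1.ref_name, l.mate1.pos))
        return AlignedFragment(fragment_id=pair.fragment_id, loci=loci, nh=len(loci))

    def align(self, pairs: Iterable[SimulatedPair]) -> list[AlignedFragment]:
        return [self.align_pair(p) for p in pairs]


def truth_align(
    pairs: Iterable[SimulatedPair], transcriptome: Transcriptome, design: SimDesign
) -> list[AlignedFragment]:
    """Convenience wrapper: build the index and align all pairs."""
    aligner = TruthAligner(transcriptome, design.read_len, design.insert_len)
    return aligner.align(pairs)


def write_truth_sam(
    fragments: Sequence[AlignedFragment],
    pairs: Sequence[SimulatedPair],
    transcriptome: Transcriptome,
    path: str | Path,
) -> None:
    """Write truth alignments as SAM (primary + secondaries, NH:i on each)."""
    refs = list(transcriptome.genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r, "LN": len(transcriptome.genome[r])} for r in refs],
    }
    seq_by_id = {p.fragment_id: p for p in pairs}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in fragments:
            pair = seq_by_id[frag.fragment_id]
            insert = None
            for li, locus in enumerate(frag.loci):
                m1, m2 = locus.mate1, locus.mate2
                tlen = (m2.ref_end - m1.pos) if (m1 and m2) else 0
                for is2, mate, partner, seq in (
                    (False, m1, m2, pair.mate1),
                    (True, m2, m1, revcomp(pair.mate2)),
                ):
                    if mate is None:
                        continue
                    a = pysam.AlignedSegment()
                    a.query_name = frag.fragment_id
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    a.flag = (
                        0x1 | 0x2
                        | (0x10 if mate.reverse else 0)
                        | (0x20 if (partner and partner.reverse) else 0)
                        | (0x80 if is2 else 0x40)
                        | (0x100 if li > 0 else 0)
                    )
                    a.reference_id = refs.index(mate.ref_name)
                    a.reference_start = mate.pos
                    a.mapping_quality = 255 if frag.nh == 1 else 0
                    a.cigartuples = [("MIDNSHP=X".index(op), ln) for op, ln in mate.cigar]
                    if partner is not None:
                        a.next_reference_id = refs.index(partner.ref_name)
                        a.next_reference_start = partner.pos
                        a.template_length = tlen if not is2 else -tlen
                    a.set_tag("NH", frag.nh)
                    out.write(a)


def write_simulation(
    transcriptome: Transcriptome,
    pairs: Sequence[SimulatedPair],
    truth: SimTruth,
    fragments: Sequence[AlignedFragment] | None,
    out_dir: str | Path,
    total_pairs: int | None = None,
) -> None:
    """Write the full artifact set: FASTA, GTF, FASTQ x2, SAM, truth TSV."""
    from .expression import expected_fpkm_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(transcriptome.genome, out / "genome.fa")
    write_fasta(transcriptome.transcripts, out / "transcriptome.fa")
    write_gtf(transcriptome.annotation, out / "annotation.gtf")
    write_fastq(((p.fragment_id, p.mate1) for p in pairs), out / "reads_1.fastq")
    write_fastq(((p.fragment_id, p.mate2) for p in pairs), out / "reads_2.fastq")
    if fragments is not None:
        write_truth_sam(fragments, pairs, transcriptome, out / "alignments.sam")
    lengths = {g: len(s) for g, s in transcriptome.transcripts.items()}
    table = expected_fpkm_table(truth.true_counts, lengths,
                                total_pairs or truth.total_pairs)
    table.to_csv(out / "truth.tsv", sep="\t", index_label="gene_id")
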
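import pytest

from mmgkit.annotation import GeneModel, TranscriptModel, build_index
from mmgkit.formats import AlignedFragment, MateAlignment, PairedLocus


def make_gene(gene_id, exons, seq_id="chr1", strand="+", biotype="protein_coding"):
    """GeneModel with a single transcript from 0-based half-open exons."""
    return GeneModel(
        gene_id=gene_id,
        seq_id=seq_id,
        strand=strand,
        transcripts=[TranscriptModel(f"{gene_id}.1", sorted(exons))],
        biotype=biotype,
    )


def make_mate(pos, length=100, ref="chr1", cigar=None, reverse=False):
    return MateAlignment(ref, pos, cigar or (("M", length),), reverse=reverse)


def make_fragment(fid, loci, nh=None):
    """loci: list of (mate1, mate2) MateAlignment pairs (either may be None)."""
    plocs = [PairedLocus(mate1=m1, mate2=m2) for m1, m2 in loci]
    return AlignedFragment(fragment_id=fid, loci=plocs, nh=nh or len(plocs))


@pytest.fixture
def two_gene_index():
    """Genes A [100,200) and B [150,250) on chr1 — the overlap toy."""
    return build_index([make_gene("A", [(100, 200)]), make_gene("B", [(150, 250)])])


@pytest.fixture
def disjoint_index():
    """Genes A [100,300) and B [500,700), with intergenic space between."""
    return build_index([make_gene("A", [(100, 300)]), make_gene("B", [(500, 700)])])
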
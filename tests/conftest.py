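import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from meripeak.annotation import GenomicInterval, TranscriptModel


def make_transcript(
    exons: list[tuple[int, int]],
    strand: str = "+",
    cds: tuple[int, int] | None = None,
    seqid: str = "chr1",
    tid: str = "t1",
    gene: str = "g1",
) -> TranscriptModel:
    exon_ivs = [GenomicInterval(seqid, a, b, strand) for a, b in exons]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        interval=GenomicInterval(seqid, exons[0][0], exons[-1][1], strand),
        exons=exon_ivs,
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
    )


def random_coding_transcript(rng: np.random.Generator) -> TranscriptModel:
    """Random multi-exon coding transcript with a CDS placed in spliced
    coordinates, for property tests."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 500))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 200))
    strand = "+" if rng.random() < 0.5 else "-"
    tm = make_transcript(exons, strand=strand)
    L = tm.spliced_length
    s = int(rng.integers(0, L - 1))
    t = int(rng.integers(s + 1, L + 1))
    pieces = tm.spliced_to_genomic(s, t)
    cds_start = min(p.start for p in pieces)
    cds_end = max(p.end for p in pieces)
    return make_transcript(exons, strand=strand, cds=(cds_start, cds_end))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
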
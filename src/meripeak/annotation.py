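"""Transcript annotation and metagene segmentation.

Parses GTF transcript models and divides each coding transcript into five
non-overlapping metagene segments in spliced (mature mRNA) coordinates:
5'UTR, a 100-nt window centered on the translation start, CDS, a 100-nt
window centered on the translation stop, and 3'UTR.  The two codon windows
span [s-50, s+50) and [t-50, t+50) where ``s`` is the spliced position of
the first CDS base and ``t`` is one past the last CDS base.  Segments are
truncated at transcript ends (or at the CDS midpoint when the CDS is
shorter than 100 nt) so they always tile the spliced transcript exactly.

All coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

#: Metagene segment labels in 5'->3' spliced order.
SEGMENT_LABELS = ("five_prime_utr", "start_codon", "cds", "stop_codon", "three_prime_utr")

#: Label used for non-coding transcripts, which are kept for peak
#: assignment but excluded from metagene profiling.
EXONIC_LABEL = "exonic"


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; names the offending line number."""


class AnnotationValidationError(ValueError):
    """Raised when features violate transcript-model invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware half-open interval on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are kept sorted by genomic coordinate and must be disjoint.
    ``cds_start``/``cds_end`` are genomic (strand-agnostic) bounds of the
    translated region; both are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    _tx_exons: list[GenomicInterval] = field(init=False, repr=False)
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise AnnotationValidationError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        for e in exons:
            if e.seqid != self.interval.seqid or e.strand != self.interval.strand:
                raise AnnotationValidationError(
                    f"{self.transcript_id}: exon {e} not on transcript seqid/strand"
                )
            if e.start < self.interval.start or e.end > self.interval.end:
                raise AnnotationValidationError(
                    f"{self.transcript_id}: exon {e} outside transcript bounds"
                )
        self.exons = exons
        # Transcript-order exons: 5'->3' along the spliced molecule.
        tx = exons if self.strand == "+" else list(reversed(exons))
        self._tx_exons = tx
        cum = [0]
        for e in tx:
            cum.append(cum[-1] + e.length)
        self._cum = cum
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationValidationError(
                f"{self.transcript_id}: cds_start/cds_end must both be set or unset"
            )
        if self.cds_start is not None:
            if self.spliced_position(self.cds_start) is None or (
                self.spliced_position(self.cds_end - 1) is None
            ):
                raise AnnotationValidationError(
                    f"{self.transcript_id}: CDS bounds not exonic"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def seqid(self) -> str:
        return self.interval.seqid

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def spliced_length(self) -> int:
        return self._cum[-1]

    @property
    def cds_spliced_length(self) -> int:
        if not self.is_coding:
            return 0
        s, t = self.cds_spliced_bounds()
        return t - s

    def cds_spliced_bounds(self) -> tuple[int, int]:
        """Spliced [s, t) of the CDS: s = first CDS base, t = one past the last."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        if self.strand == "+":
            s = self.spliced_position(self.cds_start)
            t = self.spliced_position(self.cds_end - 1) + 1
        else:
            s = self.spliced_position(self.cds_end - 1)
            t = self.spliced_position(self.cds_start) + 1
        return s, t

    def spliced_position(self, genomic_pos: int) -> int | None:
        """0-based offset along the spliced transcript (0 = 5' end).

        Returns ``None`` for intronic or out-of-bounds positions.
        """
        for i, e in enumerate(self._tx_exons):
            if e.contains(genomic_pos):
                if self.strand == "+":
                    return self._cum[i] + (genomic_pos - e.start)
                return self._cum[i] + (e.end - 1 - genomic_pos)
        return None

    def genomic_position(self, spliced_pos: int) -> int:
        """Inverse of :meth:`spliced_position` (valid spliced offsets only)."""
        if not (0 <= spliced_pos < self.spliced_length):
            raise ValueError(f"spliced position {spliced_pos} out of range")
        for i, e in enumerate(self._tx_exons):
            if self._cum[i] <= spliced_pos < self._cum[i + 1]:
                off = spliced_pos - self._cum[i]
                if self.strand == "+":
                    return e.start + off
                return e.end - 1 - off
        raise AssertionError("unreachable")

    def spliced_to_genomic(self, sstart: int, send: int) -> list[GenomicInterval]:
        """Map a spliced range onto genomic exon pieces, in spliced order."""
        if sstart >= send:
            return []
        pieces: list[GenomicInterval] = []
        for i, e in enumerate(self._tx_exons):
            a = max(sstart, self._cum[i])
            b = min(send, self._cum[i + 1])
            if a >= b:
                continue
            if self.strand == "+":
                g0 = e.start + (a - self._cum[i])
                g1 = e.start + (b - self._cum[i])
            else:
                g1 = e.end - (a - self._cum[i])
                g0 = e.end - (b - self._cum[i])
            pieces.append(GenomicInterval(self.seqid, g0, g1, self.strand))
        return pieces


@dataclass
class SegmentedTranscript:
    """A transcript tiled by the five metagene segments.

    ``spliced_segments`` maps each label to its half-open spliced range and
    ``segments`` to the genomic exon pieces of that range (spliced order).
    Empty segments are present with zero-length ranges and no pieces.
    """

    transcript_id: str
    spliced_length: int
    spliced_segments: dict[str, tuple[int, int]]
    segments: dict[str, list[GenomicInterval]]
    model: TranscriptModel

    @property
    def is_coding(self) -> bool:
        return EXONIC_LABEL not in self.spliced_segments

    def segment_of(self, spliced_pos: int) -> str | None:
        for label, (a, b) in self.spliced_segments.items():
            if a <= spliced_pos < b:
                return label
        return None


def segment_transcript(tm: TranscriptModel) -> SegmentedTranscript:
    """Tile a transcript with the five metagene segments.

    Non-coding transcripts get a single ``exonic`` segment instead.  Codon
    windows are truncated at transcript ends; when the CDS is shorter than
    100 nt the CDS segment is empty and the two codon windows abut at the
    CDS midpoint, preserving the non-overlap and full-cover invariants.
    """
    L = tm.spliced_length
    if not tm.is_coding:
        return SegmentedTranscript(
            transcript_id=tm.transcript_id,
            spliced_length=L,
            spliced_segments={EXONIC_LABEL: (0, L)},
            segments={EXONIC_LABEL: tm.spliced_to_genomic(0, L)},
            model=tm,
        )
    s, t = tm.cds_spliced_bounds()
    sc0, sc1 = s - 50, s + 50
    tc0, tc1 = t - 50, t + 50
    if sc1 > tc0:  # CDS < 100 nt: codon windows meet at the CDS midpoint
        mid = (s + t) // 2
        sc1 = tc0 = mid
    bounds = [sc0, sc1, tc0, tc1]
    # clamp into [0, L] and enforce monotonicity
    prev = 0
    for i, b in enumerate(bounds):
        b = min(max(b, prev), L)
        bounds[i] = b
        prev = b
    b1, b2, b3, b4 = bounds
    edges = [0, b1, b2, b3, b4, L]
    spliced = {
        label: (edges[i], edges[i + 1]) for i, label in enumerate(SEGMENT_LABELS)
    }
    genomic = {
        label: tm.spliced_to_genomic(a, b) for label, (a, b) in spliced.items()
    }
    return SegmentedTranscript(
        transcript_id=tm.transcript_id,
        spliced_length=L,
        spliced_segments=spliced,
        segments=genomic,
        model=tm,
    )


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GtfParseError(f"line {lineno}: invalid coordinates {start}-{end}")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"line {lineno}: invalid strand {fields[6]!r}")


def load_gtf(path: str) -> list[TranscriptModel]:
    """Read an Ensembl-dialect GTF into transcript models.

    Exon and CDS features are grouped by their ``transcript_id`` attribute;
    transcripts without CDS features are flagged non-coding.  GTF 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    _validate_gtf_lines(path)
    with open(path) as fh:
        if not fh.read().strip():
            logger.warning("GTF %s is empty; returning no transcripts", path)
            return []
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, seqid, strand)
    declared: dict[str, tuple[int, int]] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS", "transcript"):
            continue
        tid = f.attributes.get("transcript_id", [None])[0]
        gid = f.attributes.get("gene_id", [tid])[0]
        if tid is None:
            raise GtfParseError(f"{f.featuretype} feature without transcript_id")
        meta.setdefault(tid, (gid, f.seqid, f.strand))
        start, end = f.start - 1, f.end  # to 0-based half-open
        if f.featuretype == "transcript":
            declared[tid] = (start, end)
        elif f.featuretype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(f.seqid, start, end, f.strand)
            )
        else:
            cds.setdefault(tid, []).append((start, end))
    models = []
    for tid, (gid, seqid, strand) in meta.items():
        if tid not in exons:
            logger.warning("transcript %s has no exon features; skipped", tid)
            continue
        ex = _merge_adjacent(sorted(exons[tid], key=lambda e: e.start))
        lo, hi = ex[0].start, ex[-1].end
        if tid in declared:
            dlo, dhi = declared[tid]
            if lo < dlo or hi > dhi:
                raise AnnotationValidationError(
                    f"{tid}: exons [{lo},{hi}) outside declared bounds [{dlo},{dhi})"
                )
            lo, hi = dlo, dhi
        cstart = cend = None
        if tid in cds:
            cstart = min(a for a, _ in cds[tid])
            cend = max(b for _, b in cds[tid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                interval=GenomicInterval(seqid, lo, hi, strand),
                exons=ex,
                cds_start=cstart,
                cds_end=cend,
            )
        )
    return models


def _merge_adjacent(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for e in exons:
        if merged and e.start <= merged[-1].end:
            prev = merged.pop()
            merged.append(
                GenomicInterval(e.seqid, prev.start, max(prev.end, e.end), e.strand)
            )
        else:
            merged.append(e)
    return merged


def primary_isoforms(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One representative isoform per gene: longest CDS, then longest
    spliced length, then lexicographically smallest transcript id."""
    best: dict[str, TranscriptModel] = {}
    for tm in sorted(
        models,
        key=lambda m: (-m.cds_spliced_length, -m.spliced_length, m.transcript_id),
    ):
        best.setdefault(tm.gene_id, tm)
    return best


def write_segments_tsv(segmented: list[SegmentedTranscript], path: str) -> None:
    """Export segment pieces as a BED-like TSV (0-based half-open), one row
    per genomic piece, name = ``transcript_id|segment_label``."""
    with open(path, "w") as fh:
        for st in segmented:
            for label in st.segments:
                for piece in st.segments[label]:
                    fh.write(
                        f"{piece.seqid}\t{piece.start}\t{piece.end}\t"
                        f"{st.transcript_id}|{label}\t0\t{piece.strand}\n"
                    )
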
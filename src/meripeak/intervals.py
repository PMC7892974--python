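"""Peak I/O and fraction-overlap peak set algebra.

Implements the 50%-overlap rules used throughout the analysis: replicate
consolidation (recurrent peaks), between-line common/unique classification,
and summit-based peak-to-transcript assignment.  The overlap fraction is by
default the overlap length divided by the length of the *shorter* interval,
which makes the >=50% relation symmetric; ``either``-basis (fraction of the
first interval, bedtools ``-f`` semantics) and ``reciprocal`` are also
available.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from statistics import median_low

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomicInterval, SegmentedTranscript

logger = logging.getLogger(__name__)

OVERLAP_BASES = ("shorter", "either", "reciprocal")


class BedParseError(ValueError):
    pass


@dataclass
class Peak:
    """An enrichment peak: interval plus summit, fold change, p-value and
    provenance labels.  The summit defaults to the interval midpoint."""

    interval: GenomicInterval
    summit: int = -1
    fold_change: float = 1.0
    p_value: float = 1.0
    sample_id: str = ""
    line: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit < 0:
            self.summit = (self.interval.start + self.interval.end) // 2
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")

    @property
    def seqid(self) -> str:
        return self.interval.seqid

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self) -> tuple:
        return (self.seqid, self.start, self.end)


def read_bed(path: str, sample_id: str = "", line: str = "") -> list[Peak]:
    """Read peaks from BED6+2 (columns 7-8 = fold_change, p_value).

    Missing optional columns fall back to fold_change=1, p=1 with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        logger.warning("BED %s is empty", path)
        return []
    if df.shape[1] < 3:
        raise BedParseError(f"{path}: need at least 3 BED columns")
    if df.shape[1] < 8:
        logger.warning(
            "%s: no fold-change/p-value columns; defaulting to fc=1, p=1", path
        )
    peaks = []
    for idx, row in df.iterrows():
        start, end = int(row[1]), int(row[2])
        if start >= end:
            raise BedParseError(f"{path} line {idx + 1}: start {start} >= end {end}")
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in "+-" else "+"
        name = str(row[3]) if df.shape[1] > 3 else ""
        fc = float(row[6]) if df.shape[1] > 6 else 1.0
        p = float(row[7]) if df.shape[1] > 7 else 1.0
        peaks.append(
            Peak(
                interval=GenomicInterval(str(row[0]), start, end, strand),
                fold_change=fc,
                p_value=p,
                sample_id=sample_id,
                line=line,
                name=name,
            )
        )
    return peaks


def write_bed(peaks: list[Peak], path: str) -> None:
    """Write peaks as BED6+2; score column carries the summit offset so the
    read/write round trip is lossless for the columns present."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            fh.write(
                f"{p.seqid}\t{p.start}\t{p.end}\t{name}\t0\t{p.interval.strand}\t"
                f"{p.fold_change:g}\t{p.p_value:g}\n"
            )


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, basis: str = "shorter"
) -> float:
    """Overlap length divided by the basis length (0 when disjoint or on
    different sequences).  ``shorter`` is symmetric; ``either`` divides by
    ``a``'s length; ``reciprocal`` by the longer (both must satisfy it)."""
    if basis not in OVERLAP_BASES:
        raise ValueError(f"unknown basis {basis!r}")
    if a.seqid != b.seqid:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    if basis == "shorter":
        denom = min(a.length, b.length)
    elif basis == "either":
        denom = a.length
    else:
        denom = max(a.length, b.length)
    return ov / denom


def _intersection(intervals: list[GenomicInterval]) -> GenomicInterval:
    start = max(i.start for i in intervals)
    end = min(i.end for i in intervals)
    return GenomicInterval(intervals[0].seqid, start, end, intervals[0].strand)


class _SortedPeaks:
    """Per-seqid coordinate-sorted peak index for windowed overlap scans."""

    def __init__(self, peaks: list[Peak]):
        self.by_seqid: dict[str, list[tuple[Peak, int]]] = {}
        for i, p in enumerate(peaks):
            self.by_seqid.setdefault(p.seqid, []).append((p, i))
        self.starts: dict[str, list[int]] = {}
        self.max_len: dict[str, int] = {}
        for seqid, items in self.by_seqid.items():
            items.sort(key=lambda t: (t[0].start, t[0].end, t[1]))
            self.starts[seqid] = [p.start for p, _ in items]
            self.max_len[seqid] = max(p.interval.length for p, _ in items)

    def overlapping(self, interval: GenomicInterval) -> list[tuple[Peak, int]]:
        """Peaks that overlap the interval, in (start, end) order."""
        items = self.by_seqid.get(interval.seqid)
        if not items:
            return []
        starts = self.starts[interval.seqid]
        lo = bisect_left(starts, interval.start - self.max_len[interval.seqid])
        hi = bisect_right(starts, interval.end)
        return [
            (p, i) for p, i in items[lo:hi] if p.end > interval.start and p.start < interval.end
        ]


def consolidate_recurrent(
    replicate_peak_sets: list[list[Peak]],
    min_fraction: float = 0.5,
    min_replicates: int | None = None,
    basis: str = "shorter",
    representative: str = "intersection",
) -> list[Peak]:
    """Consolidate replicate peak sets into recurrent peaks.

    A recurrent peak is a chain of peaks, at most one per replicate and
    drawn from at least ``min_replicates`` replicates (default: all), whose
    members pairwise share >= ``min_fraction`` overlap.  Chains are grown
    greedily from each unused peak in global coordinate order, extending
    with the best-fraction compatible peak of each other replicate (ties ->
    leftmost); each peak joins at most one chain.  The emitted peak takes
    the intersection of member intervals (or their union / the first
    replicate's interval), the median member summit, and the mean member
    fold change; output is coordinate-sorted.
    """
    if len(replicate_peak_sets) < 2:
        raise ValueError("need at least two replicate peak sets")
    if representative not in ("intersection", "union", "first"):
        raise ValueError(f"unknown representative {representative!r}")
    n_rep = len(replicate_peak_sets)
    if min_replicates is None:
        min_replicates = n_rep
    if min_replicates == n_rep and any(not s for s in replicate_peak_sets):
        logger.warning("an empty replicate set with min_replicates=all: no recurrent peaks")
        return []
    # global coordinate order over (replicate, index) handles
    indexed = [
        (p, r, i)
        for r, peaks in enumerate(replicate_peak_sets)
        for i, p in enumerate(peaks)
    ]
    indexed.sort(key=lambda t: (t[0].sort_key(), t[1], t[2]))
    sorted_reps = [_SortedPeaks(peaks) if peaks else None for peaks in replicate_peak_sets]
    used: set[tuple[int, int]] = set()
    out = []
    for anchor, r0, i0 in indexed:
        if (r0, i0) in used:
            continue
        chain = [(anchor, r0, i0)]
        for r in range(n_rep):
            if r == r0 or sorted_reps[r] is None:
                continue
            best = None
            best_frac = -1.0
            for cand, i in sorted_reps[r].overlapping(anchor.interval):
                if (r, i) in used:
                    continue
                fracs = [
                    overlap_fraction(cand.interval, m.interval, basis)
                    for m, _, _ in chain
                ]
                if min(fracs) < min_fraction:
                    continue
                frac = overlap_fraction(cand.interval, anchor.interval, basis)
                if frac > best_frac:
                    best, best_frac = (cand, r, i), frac
            if best is not None:
                chain.append(best)
        if len(chain) >= min_replicates:
            for _, r, i in chain:
                used.add((r, i))
            members = [m for m, _, _ in chain]
            if representative == "intersection":
                interval = _intersection([m.interval for m in members])
            elif representative == "union":
                interval = GenomicInterval(
                    members[0].seqid,
                    min(m.start for m in members),
                    max(m.end for m in members),
                    members[0].interval.strand,
                )
            else:
                interval = min(chain, key=lambda t: t[1])[0].interval
            summit = median_low(sorted(m.summit for m in members))
            if not interval.contains(summit):
                summit = (interval.start + interval.end) // 2
            out.append(
                Peak(
                    interval=interval,
                    summit=summit,
                    fold_change=sum(m.fold_change for m in members) / len(members),
                    p_value=min(m.p_value for m in members),
                    sample_id="recurrent",
                    line=members[0].line,
                )
            )
    out.sort(key=Peak.sort_key)
    return out


@dataclass
class PeakSetComparison:
    """Common/unique classification of two consolidated peak sets.

    ``common`` pairs each common A-peak with its best-fraction B partner
    (a B-peak may certify several A-peaks); ``common_b`` lists the B-peaks
    that match at least one A-peak.  Counts are conserved:
    |A| = len(common) + len(unique_a) and |B| = len(common_b) + len(unique_b).
    """

    common: list[tuple[Peak, Peak]]
    common_b: list[Peak]
    unique_a: list[Peak]
    unique_b: list[Peak]
    min_fraction: float = 0.5
    basis: str = "shorter"

    @property
    def n_common_a(self) -> int:
        return len(self.common)

    @property
    def n_common_b(self) -> int:
        return len(self.common_b)


def _best_match(
    peak: Peak, others: _SortedPeaks, min_fraction: float, basis: str
) -> Peak | None:
    """Best-fraction partner at >= min_fraction; ties -> leftmost (start,
    end order)."""
    best = None
    best_frac = -1.0
    for cand, _ in others.overlapping(peak.interval):
        frac = overlap_fraction(peak.interval, cand.interval, basis)
        if frac >= min_fraction and frac > best_frac:
            best, best_frac = cand, frac
    return best


def classify_common_unique(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    min_fraction: float = 0.5,
    basis: str = "shorter",
) -> PeakSetComparison:
    """Split two peak sets into common (matched >= min_fraction overlap)
    and line-unique peaks.  Matching is greedy best-fraction without
    exclusivity, so the relation mirrors set-intersection semantics."""
    sorted_a = _SortedPeaks(peaks_a) if peaks_a else None
    sorted_b = _SortedPeaks(peaks_b) if peaks_b else None
    common, unique_a = [], []
    for pa in peaks_a:
        match = _best_match(pa, sorted_b, min_fraction, basis) if sorted_b else None
        if match is not None:
            common.append((pa, match))
        else:
            unique_a.append(pa)
    common_b, unique_b = [], []
    for pb in peaks_b:
        match = _best_match(pb, sorted_a, min_fraction, basis) if sorted_a else None
        if match is not None:
            common_b.append(pb)
        else:
            unique_b.append(pb)
    return PeakSetComparison(
        common=common,
        common_b=common_b,
        unique_a=unique_a,
        unique_b=unique_b,
        min_fraction=min_fraction,
        basis=basis,
    )


INTERGENIC = "intergenic"


def assign_peaks_to_transcripts(
    peaks: list[Peak],
    segmented: dict[str, SegmentedTranscript] | list[SegmentedTranscript],
    by: str = "summit",
) -> list[list[str]]:
    """Assign each peak to every transcript whose exons contain its summit
    (or midpoint with ``by='midpoint'``).  Returns, per peak, the sorted
    list of matching transcript ids; an empty list means intergenic."""
    if by not in ("summit", "midpoint"):
        raise ValueError(f"unknown assignment mode {by!r}")
    if isinstance(segmented, dict):
        segmented = list(segmented.values())
    trees: dict[str, IntervalTree] = {}
    for st in segmented:
        tree = trees.setdefault(st.model.seqid, IntervalTree())
        for exon in st.model.exons:
            tree.addi(exon.start, exon.end, st.transcript_id)
    assignments = []
    for p in peaks:
        pos = p.summit if by == "summit" else (p.start + p.end) // 2
        tree = trees.get(p.seqid)
        hits = sorted({iv.data for iv in tree[pos]}) if tree is not None else []
        assignments.append(hits)
    return assignments


def comparison_to_frames(cmp: PeakSetComparison) -> dict[str, pd.DataFrame]:
    """Tabular view of a comparison: three peak tables plus the pair table."""

    def frame(peaks: list[Peak]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seqid": [p.seqid for p in peaks],
                "start": [p.start for p in peaks],
                "end": [p.end for p in peaks],
                "summit": [p.summit for p in peaks],
                "fold_change": [p.fold_change for p in peaks],
                "p_value": [p.p_value for p in peaks],
            }
        )

    pairs = pd.DataFrame(
        {
            "a_seqid": [a.seqid for a, _ in cmp.common],
            "a_start": [a.start for a, _ in cmp.common],
            "a_end": [a.end for a, _ in cmp.common],
            "b_start": [b.start for _, b in cmp.common],
            "b_end": [b.end for _, b in cmp.common],
            "overlap_fraction": [
                overlap_fraction(a.interval, b.interval, cmp.basis)
                for a, b in cmp.common
            ],
        }
    )
    return {
        "common_pairs": pairs,
        "common_a": frame([a for a, _ in cmp.common]),
        "unique_a": frame(cmp.unique_a),
        "unique_b": frame(cmp.unique_b),
    }
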
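"""Positional statistics of peaks on transcripts.

The metagene profile stretches each of the five transcript segments to 20
bins (100 bins total, ordered 5'UTR, start-codon window, CDS, stop-codon
window, 3'UTR); a peak contributes exactly one count, in the bin holding
its summit on its assigned transcript, so bin counts always sum to the
number of peaks used.  A length-weighted mode spreads each peak's unit mass
over the bins its interval covers instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import SEGMENT_LABELS, SegmentedTranscript
from .intervals import Peak
from .utils import round_half_up

logger = logging.getLogger(__name__)

N_BINS_PER_SEGMENT = 20
NOT_EXONIC = ("not_exonic", -1)


@dataclass
class MetageneProfile:
    """100-bin peak density along the normalized transcript model."""

    bin_counts: np.ndarray  # shape (100,)
    n_peaks_used: int

    @property
    def bin_density(self) -> np.ndarray | None:
        if self.n_peaks_used == 0:
            return None
        return self.bin_counts / self.bin_counts.sum()

    def segment_counts(self) -> dict[str, float]:
        out = {}
        for i, label in enumerate(SEGMENT_LABELS):
            lo = i * N_BINS_PER_SEGMENT
            out[label] = float(self.bin_counts[lo : lo + N_BINS_PER_SEGMENT].sum())
        return out

    def to_frame(self) -> pd.DataFrame:
        dens = self.bin_density
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.bin_counts)),
                "segment": np.repeat(SEGMENT_LABELS, N_BINS_PER_SEGMENT),
                "count": self.bin_counts,
                "density": dens if dens is not None else np.nan,
            }
        )


def locate_peak(peak: Peak, st: SegmentedTranscript) -> tuple[str, int]:
    """(segment label, bin 0-19) of a peak summit on a segmented transcript.

    The summit is mapped to spliced coordinates (bin 0 is 5'-most on either
    strand); bin = floor(20 * offset / segment length), clamped to 19.
    Returns ``("not_exonic", -1)`` for non-exonic summits.
    """
    spos = st.model.spliced_position(peak.summit)
    if spos is None:
        return NOT_EXONIC
    label = st.segment_of(spos)
    if label is None:  # cannot happen on a full segment cover
        return NOT_EXONIC
    a, b = st.spliced_segments[label]
    bin_idx = min(
        N_BINS_PER_SEGMENT - 1, int(N_BINS_PER_SEGMENT * (spos - a) / (b - a))
    )
    return (label, bin_idx)


def _rank(st: SegmentedTranscript) -> tuple:
    tm = st.model
    return (-tm.cds_spliced_length, -tm.spliced_length, tm.transcript_id)


def _choose_transcript(
    tids: list[str], segmented: dict[str, SegmentedTranscript]
) -> SegmentedTranscript | None:
    candidates = [segmented[t] for t in tids if t in segmented and segmented[t].is_coding]
    if not candidates:
        return None
    return min(candidates, key=_rank)


def metagene_profile(
    peaks: list[Peak],
    segmented: dict[str, SegmentedTranscript],
    assignments: list[list[str]],
    weighted: bool = False,
) -> MetageneProfile:
    """Accumulate peaks into the 100-bin metagene profile.

    Each peak is placed on its assigned coding transcript (the isoform with
    the longest CDS when several are assigned); peaks with no coding
    assignment or a non-exonic summit are skipped.  In summit mode each
    peak adds exactly 1 to one bin; in ``weighted`` mode its unit mass is
    split evenly over the bins its interval overlaps.
    """
    counts = np.zeros(len(SEGMENT_LABELS) * N_BINS_PER_SEGMENT)
    used = 0
    seg_offset = {label: i * N_BINS_PER_SEGMENT for i, label in enumerate(SEGMENT_LABELS)}
    for peak, tids in zip(peaks, assignments):
        st = _choose_transcript(tids, segmented)
        if st is None:
            continue
        if not weighted:
            label, bin_idx = locate_peak(peak, st)
            if bin_idx < 0:
                continue
            counts[seg_offset[label] + bin_idx] += 1
            used += 1
        else:
            bins = _covered_bins(peak, st, seg_offset)
            if not bins:
                continue
            for b in bins:
                counts[b] += 1.0 / len(bins)
            used += 1
    if used == 0:
        logger.warning("no usable peaks: metagene density undefined")
    return MetageneProfile(bin_counts=counts, n_peaks_used=used)


def _covered_bins(
    peak: Peak, st: SegmentedTranscript, seg_offset: dict[str, int]
) -> list[int]:
    bins = set()
    for pos in range(peak.start, peak.end):
        spos = st.model.spliced_position(pos)
        if spos is None:
            continue
        label = st.segment_of(spos)
        if label is None:
            continue
        a, b = st.spliced_segments[label]
        idx = min(N_BINS_PER_SEGMENT - 1, int(N_BINS_PER_SEGMENT * (spos - a) / (b - a)))
        bins.add(seg_offset[label] + idx)
    return sorted(bins)


def segment_pie(
    peaks: list[Peak],
    segmented: dict[str, SegmentedTranscript],
    assignments: list[list[str]],
) -> dict[str, float] | None:
    """Fraction of peaks per segment (sums to 1); None when no peak usable."""
    profile = metagene_profile(peaks, segmented, assignments)
    if profile.n_peaks_used == 0:
        logger.warning("no usable peaks: segment fractions undefined")
        return None
    seg = profile.segment_counts()
    total = sum(seg.values())
    return {label: seg[label] / total for label in SEGMENT_LABELS}


def peaks_per_transcript(
    assignments: list[list[str]],
    n_transcripts: int,
) -> tuple[dict[str, int], float, float]:
    """Peaks-per-transcript histogram and the two summary ratios.

    A methylated transcript carries >= 1 assigned peak.  Each peak counts
    once, on its first assigned transcript.  Returns the histogram over
    {1, 2, 3, >=4} peaks, peaks per methylated transcript, and peaks per
    transcript (both rounded to 2 decimals).
    """
    if n_transcripts <= 0:
        raise ValueError("need a positive transcript count")
    per_tid: dict[str, int] = {}
    n_peaks = 0
    for tids in assignments:
        if not tids:
            continue
        per_tid[tids[0]] = per_tid.get(tids[0], 0) + 1
        n_peaks += 1
    hist = {"1": 0, "2": 0, "3": 0, ">=4": 0}
    for c in per_tid.values():
        hist[str(c) if c < 4 else ">=4"] += 1
    n_meth = len(per_tid)
    per_meth = round_half_up(n_peaks / n_meth, 2) if n_meth else 0.0
    per_tx = round_half_up(n_peaks / n_transcripts, 2)
    return hist, per_meth, per_tx
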
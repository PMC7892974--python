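"""Sliding-window Poisson enrichment peak caller (IP vs input).

A deliberately simple stand-in for a full ChIP/MeRIP peak caller: windows
slide along each sequence, the background rate for a window is the larger
of the library-size-scaled input count and a global uniform-coverage rate
over the effective (transcriptome) size, and enrichment is tested with an
upper-tail Poisson p-value.  Significant windows (p below threshold AND
fold enrichment above threshold) within ``merge_gap`` of each other are
merged into peaks.

Coverage tracks hold per-base fragment-coverage counts; a window's count is
the sum over its bases, treated as a Poisson draw.  There is no duplicate
handling or fragment-model estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .annotation import GenomicInterval
from .intervals import Peak, overlap_fraction

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base fragment coverage per sequence, with the library size.

    ``total_fragments`` defaults to (coverage sum) / fragment_length, the
    fragment-equivalent library size.
    """

    counts: dict[str, np.ndarray]
    total_fragments: float = 0.0
    fragment_length: int = 100

    def __post_init__(self) -> None:
        for seqid, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"{seqid}: coverage must be 1-D")
            if (arr < 0).any():
                raise ValueError(f"{seqid}: negative coverage")
            self.counts[seqid] = arr
        if self.total_fragments <= 0:
            total = sum(float(a.sum()) for a in self.counts.values())
            self.total_fragments = total / self.fragment_length

    @classmethod
    def from_bedgraph(
        cls, path: str, lengths: dict[str, int] | None = None, fragment_length: int = 100
    ) -> "CoverageTrack":
        """Read a bedGraph (0-based half-open) into per-base arrays."""
        spans: dict[str, list[tuple[int, int, float]]] = {}
        maxend: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                seqid, start, end, value = line.split()[:4]
                s, e, v = int(start), int(end), float(value)
                spans.setdefault(seqid, []).append((s, e, v))
                maxend[seqid] = max(maxend.get(seqid, 0), e)
        counts = {}
        for seqid, rows in spans.items():
            n = lengths[seqid] if lengths else maxend[seqid]
            arr = np.zeros(n, dtype=np.float64)
            for s, e, v in rows:
                arr[s:e] = v
            counts[seqid] = arr
        return cls(counts=counts, fragment_length=fragment_length)

    def write_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for seqid in sorted(self.counts):
                arr = self.counts[seqid]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{seqid}\t{s}\t{e}\t{v:g}\n")


@dataclass
class PeakCallerParams:
    """Window scan parameters.

    ``effective_size`` is the background genome/transcriptome size used for
    the global uniform-coverage rate (the study-scale value is 1.77e8 for
    the chicken transcriptome; synthetic runs use the simulated
    transcriptome size).
    """

    window_size: int = 100
    step: int = 50
    effective_size: float = 1.77e8
    p_threshold: float = 1e-5
    fc_threshold: float = 2.0
    merge_gap: int | None = None
    fragment_length: int = 100

    def __post_init__(self) -> None:
        if self.merge_gap is None:
            self.merge_gap = self.window_size
        if min(self.window_size, self.step, self.merge_gap + 1) <= 0:
            raise ValueError("window_size, step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.effective_size <= 0 or self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("effective_size, thresholds must be positive")


def _window_sums(arr: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    cum = np.concatenate(([0.0], np.cumsum(arr, dtype=np.float64)))
    ends = np.minimum(starts + window, len(arr))
    return cum[ends] - cum[starts]


def window_scan(
    ip: CoverageTrack, input_: CoverageTrack, params: PeakCallerParams, seqid: str
) -> dict[str, np.ndarray]:
    """Window-level statistics for one sequence: counts, background rates,
    Poisson p-values and fold enrichments."""
    c_ip = ip.counts[seqid]
    starts = np.arange(0, max(len(c_ip) - params.window_size, 0) + 1, params.step)
    k = np.rint(_window_sums(c_ip, starts, params.window_size)).astype(np.int64)
    lam_global = (
        ip.total_fragments
        * params.fragment_length
        * params.window_size
        / params.effective_size
    )
    if input_.total_fragments <= 0:
        logger.warning("input library empty: falling back to global rate only")
        lam = np.full(len(starts), lam_global)
    else:
        scale = ip.total_fragments / input_.total_fragments
        c_in = input_.counts.get(seqid)
        if c_in is None:
            raise ValueError(f"input track lacks sequence {seqid}")
        lam_local = _window_sums(c_in, starts, params.window_size) * scale
        lam = np.maximum(lam_local, lam_global)
    lam = np.maximum(lam, 1e-12)
    # upper tail P(X >= k | lam); pdtrc(k-1, lam) = P(X > k-1)
    p = np.ones(len(starts))
    pos = k > 0
    p[pos] = special.pdtrc(k[pos] - 1, lam[pos])
    fc = k / lam
    return {"starts": starts, "k": k, "lam": lam, "p": p, "fc": fc}


def call_peaks(
    ip: CoverageTrack,
    input_: CoverageTrack,
    params: PeakCallerParams | None = None,
    sample_id: str = "",
    line: str = "",
) -> list[Peak]:
    """Call IP-over-input enrichment peaks on every sequence of the IP track.

    A window is significant when p < p_threshold and count/background >=
    fc_threshold; significant windows closer than ``merge_gap`` are merged.
    Each peak carries summit = argmax per-base IP coverage, fold change =
    (sum of member window counts) / (sum of member backgrounds) and p =
    minimum member window p.
    """
    params = params or PeakCallerParams()
    peaks: list[Peak] = []
    for seqid in sorted(ip.counts):
        stats = window_scan(ip, input_, params, seqid)
        sig = (
            (stats["p"] < params.p_threshold)
            & (stats["fc"] >= params.fc_threshold)
            & (stats["k"] > 0)
        )
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        c_ip = ip.counts[seqid]
        groups: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev_end = stats["starts"][groups[-1][-1]] + params.window_size
            if stats["starts"][i] - prev_end <= params.merge_gap:
                groups[-1].append(i)
            else:
                groups.append([i])
        for g, members in enumerate(groups):
            start = int(stats["starts"][members[0]])
            end = int(min(stats["starts"][members[-1]] + params.window_size, len(c_ip)))
            summit = start + int(np.argmax(c_ip[start:end]))
            k_sum = float(stats["k"][members].sum())
            lam_sum = float(stats["lam"][members].sum())
            peaks.append(
                Peak(
                    interval=GenomicInterval(seqid, start, end),
                    summit=summit,
                    fold_change=k_sum / lam_sum,
                    p_value=float(stats["p"][members].min()),
                    sample_id=sample_id,
                    line=line,
                )
            )
    return peaks


def peak_fdr_recall(
    called: list[Peak],
    truth: list[GenomicInterval],
    match_fraction: float = 0.5,
) -> tuple[float, float]:
    """(recall, false-discovery proportion) of called peaks against ground
    truth, matched at >= match_fraction overlap of the shorter interval.

    Empty truth gives recall = nan; no calls give FDP = 0 by convention.
    """
    if not truth:
        logger.warning("empty truth set: recall undefined")
        return (math.nan, 0.0 if not called else _fdp(called, truth, match_fraction))
    if not called:
        logger.warning("no called peaks: FDP reported as 0 by convention")
        return (0.0, 0.0)
    called_idx = _interval_index([c.interval for c in called])
    hit = sum(
        1 for t in truth if _matched(t, called_idx, match_fraction)
    )
    return (hit / len(truth), _fdp(called, truth, match_fraction))


def _interval_index(
    intervals: list[GenomicInterval],
) -> dict[str, tuple[list[int], list[GenomicInterval], int]]:
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seqid, []).append(iv)
    out = {}
    for seqid, ivs in by_seq.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        out[seqid] = ([iv.start for iv in ivs], ivs, max(iv.length for iv in ivs))
    return out


def _matched(
    query: GenomicInterval,
    index: dict[str, tuple[list[int], list[GenomicInterval], int]],
    match_fraction: float,
) -> bool:
    import bisect

    entry = index.get(query.seqid)
    if entry is None:
        return False
    starts, ivs, max_len = entry
    lo = bisect.bisect_left(starts, query.start - max_len)
    hi = bisect.bisect_right(starts, query.end)
    return any(
        overlap_fraction(query, iv) >= match_fraction for iv in ivs[lo:hi]
    )


def _fdp(called: list[Peak], truth: list[GenomicInterval], match_fraction: float) -> float:
    if not called:
        return 0.0
    if not truth:
        return 1.0
    truth_idx = _interval_index(truth)
    spurious = sum(
        1 for c in called if not _matched(c.interval, truth_idx, match_fraction)
    )
    return spurious / len(called)


def count_in_interval(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Fragment-coverage count in an interval (sum of per-base coverage)."""
    arr = track.counts.get(interval.seqid)
    if arr is None:
        return 0.0
    return float(arr[interval.start : min(interval.end, len(arr))].sum())
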
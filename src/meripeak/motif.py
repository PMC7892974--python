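"""Motif-window preparation and k-mer/IUPAC enrichment.

Prepares motif-discovery inputs the way the MeRIP analysis does: the top
1,000 significantly enriched peaks (fold change > 2, p < 1e-5) yield
101-nt windows centered on the peak summit, paired with per-sequence
shuffled controls (mononucleotide or dinucleotide-preserving).  A built-in
two-proportion z-test on per-position match rates scores IUPAC patterns
such as GGACU and RRACH against the controls, so the canonical m6A motif
claim can be checked without external motif-discovery binaries.  U and T
are equivalent throughout; sequences are handled in the DNA alphabet.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .intervals import Peak

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifWindow:
    """A 101-nt (unless truncated) sequence centered on a peak summit."""

    peak_id: str
    sequence: str
    origin: str = "target"  # target / shuffled-control
    truncated: bool = False


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def select_top_peaks(
    peaks: list[Peak], n: int = 1000, fc_min: float = 2.0, p_max: float = 1e-5
) -> list[Peak]:
    """The n most significant peaks with fold change > fc_min and
    p < p_max, ordered by ascending p, then descending fold change, then
    coordinate — a pure function of the peak multiset."""
    qualified = [p for p in peaks if p.fold_change > fc_min and p.p_value < p_max]
    qualified.sort(key=lambda p: (p.p_value, -p.fold_change, p.sort_key()))
    if len(qualified) < n:
        logger.warning("only %d peaks qualify (requested %d)", len(qualified), n)
    return qualified[:n]


def extract_windows(
    peaks: list[Peak],
    sequences: dict[str, str],
    flank: int = 50,
    strands: list[str] | None = None,
    center: str = "summit",
) -> list[MotifWindow]:
    """Extract [center-flank, center+flank+1) windows around peak summits
    (or midpoints).  Windows on minus-strand hosts are reverse-complemented
    so they read in transcript orientation; windows truncated at contig
    ends are flagged."""
    windows = []
    for i, p in enumerate(peaks):
        if p.seqid not in sequences:
            raise KeyError(f"sequence {p.seqid} not found in genome")
        seq = sequences[p.seqid]
        c = p.summit if center == "summit" else (p.start + p.end) // 2
        lo, hi = c - flank, c + flank + 1
        truncated = lo < 0 or hi > len(seq)
        sub = seq[max(lo, 0) : min(hi, len(seq))].upper()
        strand = strands[i] if strands is not None else p.interval.strand
        if strand == "-":
            sub = reverse_complement(sub)
        if truncated:
            logger.warning("window %d truncated to %d nt at contig end", i, len(sub))
        windows.append(
            MotifWindow(
                peak_id=p.name or f"peak_{i + 1}",
                sequence=sub,
                origin="target",
                truncated=truncated,
            )
        )
    return windows


def _mono_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: random Eulerian walk over the
    first-order transition multigraph, preserving the exact dinucleotide
    count multiset."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # Pick, for each vertex except the last, a random terminal edge forming
    # a spanning arborescence into `last` (so the walk can always finish).
    vertices = set(seq)
    terminal: dict[str, str] = {}
    while True:
        for v in vertices:
            if v != last:
                terminal[v] = edges[v][rng.integers(len(edges[v]))]
        # check connectivity of terminal edges to `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled_edges = {}
    for v in vertices:
        out = list(edges[v])
        if v != last:
            out.remove(terminal[v])
        rng.shuffle(out)
        if v != last:
            out.append(terminal[v])
        shuffled_edges[v] = out
    walk = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_controls(
    windows: list[MotifWindow], mode: str = "dinucleotide", seed: int = 0
) -> list[MotifWindow]:
    """Per-sequence shuffled controls preserving mononucleotide
    (``mode='mono'``) or dinucleotide (default) composition; deterministic
    under ``seed``."""
    if mode not in ("mono", "dinucleotide"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        seq = (
            _mono_shuffle(w.sequence, rng)
            if mode == "mono"
            else _dinucleotide_shuffle(w.sequence, rng)
        )
        out.append(
            MotifWindow(
                peak_id=f"{w.peak_id}|shuffled",
                sequence=seq,
                origin="shuffled-control",
                truncated=w.truncated,
            )
        )
    return out


def expand_iupac(pattern: str) -> list[str]:
    pattern = pattern.upper()
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in {pattern!r}")
    kmers = [""]
    for ch in pattern:
        kmers = [k + b for k in kmers for b in IUPAC[ch]]
    return kmers


def count_matches(sequence: str, pattern: str) -> int:
    """Occurrences of an IUPAC pattern (overlaps allowed, U == T)."""
    seq = sequence.upper().replace("U", "T")
    allowed = [set(IUPAC[ch]) for ch in pattern.upper()]
    k = len(allowed)
    n = 0
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in allowed[j] for j in range(k)):
            n += 1
    return n


@dataclass
class MotifEnrichment:
    motif: str
    target_rate: float
    control_rate: float
    z: float
    p_value: float
    target_matches: int
    control_matches: int


def _rate_and_positions(seqs: list[str], pattern: str) -> tuple[int, int]:
    k = len(pattern)
    matches = sum(count_matches(s, pattern) for s in seqs)
    positions = sum(max(len(s) - k + 1, 0) for s in seqs)
    return matches, positions


def _two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(max(pooled * (1 - pooled) * (1 / n1 + 1 / n2), 1e-300))
    z = (p1 - p2) / se
    from scipy.stats import norm

    return z, float(norm.sf(z))


def kmer_enrichment(
    targets: list[MotifWindow],
    controls: list[MotifWindow],
    motifs: list[str],
    n_extra_shuffles: int = 0,
    seed: int = 0,
) -> list[MotifEnrichment]:
    """Per-motif enrichment of targets over controls.

    The test is a one-sided two-proportion z on per-position match rates.
    When ``n_extra_shuffles`` > 0, an empirical p is computed instead from
    that many additional per-sequence shuffles of the targets (fraction of
    shuffles whose match count >= the observed count).
    """
    if not targets or not controls:
        raise ValueError("need at least one target and one control sequence")
    tseqs = [w.sequence for w in targets]
    cseqs = [w.sequence for w in controls]
    out = []
    for motif in motifs:
        xt, nt = _rate_and_positions(tseqs, motif)
        xc, nc = _rate_and_positions(cseqs, motif)
        z, p = _two_proportion_z(xt, nt, xc, nc)
        if n_extra_shuffles > 0:
            ge = 0
            for rep in range(n_extra_shuffles):
                shuf = shuffle_controls(targets, seed=seed + rep)
                xs, _ = _rate_and_positions([w.sequence for w in shuf], motif)
                if xs >= xt:
                    ge += 1
            p = (ge + 1) / (n_extra_shuffles + 1)
        out.append(
            MotifEnrichment(
                motif=motif,
                target_rate=xt / nt if nt else 0.0,
                control_rate=xc / nc if nc else 0.0,
                z=z,
                p_value=p,
                target_matches=xt,
                control_matches=xc,
            )
        )
    return out


def rank_kmers(
    targets: list[MotifWindow], controls: list[MotifWindow], k: int = 5
) -> list[tuple[str, float]]:
    """All 4^k k-mers ranked by enrichment z (descending), computed in one
    counting pass over targets and controls."""

    def kmer_counts(seqs: list[str]) -> tuple[Counter, int]:
        counts: Counter = Counter()
        positions = 0
        for s in seqs:
            s = s.upper().replace("U", "T")
            positions += max(len(s) - k + 1, 0)
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
        return counts, positions

    tc, tn = kmer_counts([w.sequence for w in targets])
    cc, cn = kmer_counts([w.sequence for w in controls])
    from itertools import product

    scored = []
    for kmer_tuple in product("ACGT", repeat=k):
        kmer = "".join(kmer_tuple)
        z, _ = _two_proportion_z(tc.get(kmer, 0), tn, cc.get(kmer, 0), cn)
        scored.append((kmer, z))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def write_fasta(windows: list[MotifWindow], path: str) -> None:
    """DREME-compatible FASTA of windows."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.peak_id}\n{w.sequence}\n")
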
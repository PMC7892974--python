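"""Independent brute-force oracles for the interval and metagene algebra.

Everything here is written from the operation definitions (base counting,
exhaustive enumeration, per-base labelling) without reusing the package's
optimized code paths, so agreement is a meaningful check.
"""

from __future__ import annotations

import math

from meripeak.annotation import TranscriptModel


def brute_overlap_fraction(a, b, basis: str = "shorter") -> float:
    """Overlap fraction by literally counting shared bases."""
    if a.seqid != b.seqid:
        return 0.0
    shared = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    if shared == 0:
        return 0.0
    if basis == "shorter":
        denom = min(a.end - a.start, b.end - b.start)
    elif basis == "either":
        denom = a.end - a.start
    else:
        denom = max(a.end - a.start, b.end - b.start)
    return shared / denom


def brute_label_spliced_bases(spliced_length: int, s: int, t: int) -> list[str]:
    """Label every spliced base of a coding transcript by the segment rule:
    a 100-nt window centered on the translation start covers [s-50, s+50),
    one on the stop covers [t-50, t+50); windows truncate at transcript
    ends and, when the CDS is shorter than 100 nt, meet at the CDS
    midpoint."""
    sc_end, tc_start = s + 50, t - 50
    if sc_end > tc_start:
        mid = (s + t) // 2
        sc_end = tc_start = mid
    labels = []
    for i in range(spliced_length):
        if i < s - 50:
            labels.append("five_prime_utr")
        elif i < sc_end:
            labels.append("start_codon")
        elif i < tc_start:
            labels.append("cds")
        elif i < t + 50:
            labels.append("stop_codon")
        else:
            labels.append("three_prime_utr")
    return labels


def brute_locate(tm: TranscriptModel, genomic_summit: int) -> tuple[str, int] | None:
    """(segment, bin) of a summit via the per-base labeller."""
    spos = tm.spliced_position(genomic_summit)
    if spos is None:
        return None
    s, t = tm.cds_spliced_bounds()
    labels = brute_label_spliced_bases(tm.spliced_length, s, t)
    label = labels[spos]
    seg_positions = [i for i, lab in enumerate(labels) if lab == label]
    offset = seg_positions.index(spos)
    bin_idx = min(19, 20 * offset // len(seg_positions))
    return (label, bin_idx)


def brute_consolidate_intervals(
    replicate_sets: list[list[tuple[int, int]]],
    min_fraction: float = 0.5,
    min_replicates: int | None = None,
) -> list[tuple[int, int]]:
    """Exhaustive re-implementation of the greedy recurrent-chain rule on
    plain (start, end) tuples, one seqid.

    Anchors are visited in global (start, end, replicate, index) order; a
    chain greedily adds, per other replicate, the unused peak with the
    highest base-counted overlap fraction against the anchor (ties -> the
    peak earliest in (start, end) order) among peaks pairwise compatible
    with the whole chain.  Emitted interval = intersection of members.
    """

    def frac(x, y):
        shared = len(set(range(*x)) & set(range(*y)))
        if shared == 0:
            return 0.0
        return shared / min(x[1] - x[0], y[1] - y[0])

    n_rep = len(replicate_sets)
    if min_replicates is None:
        min_replicates = n_rep
    order = sorted(
        (
            (iv, r, i)
            for r, ivs in enumerate(replicate_sets)
            for i, iv in enumerate(ivs)
        ),
        key=lambda t: (t[0][0], t[0][1], t[1], t[2]),
    )
    used: set[tuple[int, int]] = set()
    out = []
    for anchor, r0, i0 in order:
        if (r0, i0) in used:
            continue
        chain = [(anchor, r0, i0)]
        for r in range(n_rep):
            if r == r0:
                continue
            candidates = []
            for i, cand in enumerate(replicate_sets[r]):
                if (r, i) in used:
                    continue
                if all(frac(cand, m) >= min_fraction for m, _, _ in chain):
                    candidates.append((-frac(cand, anchor), cand[0], cand[1], i, cand))
            if candidates:
                candidates.sort()
                _, _, _, i, cand = candidates[0]
                chain.append((cand, r, i))
        if len(chain) >= min_replicates:
            for _, r, i in chain:
                used.add((r, i))
            start = max(m[0] for m, _, _ in chain)
            end = min(m[1] for m, _, _ in chain)
            out.append((start, end))
    return sorted(out)


def brute_classify_intervals(
    set_a: list[tuple[int, int]],
    set_b: list[tuple[int, int]],
    min_fraction: float = 0.5,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(common_a, unique_a) by exhaustive pair enumeration, base counting."""

    def frac(x, y):
        shared = len(set(range(*x)) & set(range(*y)))
        return shared / min(x[1] - x[0], y[1] - y[0]) if shared else 0.0

    common, unique = [], []
    for a in set_a:
        if any(frac(a, b) >= min_fraction for b in set_b):
            common.append(a)
        else:
            unique.append(a)
    return common, unique


def poisson_upper_tail(k: int, lam: float, terms: int = 2000) -> float:
    """P(X >= k) by direct series summation of the Poisson pmf."""
    total = 0.0
    for j in range(k, k + terms):
        total += math.exp(-lam + j * math.log(lam) - math.lgamma(j + 1))
    return total


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, hits: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, hits) by exact
    summation with integer binomials."""
    total = 0
    denom = math.comb(universe, hits)
    for k in range(overlap, min(set_size, hits) + 1):
        total += math.comb(set_size, k) * math.comb(universe - set_size, hits - k)
    return total / denom
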
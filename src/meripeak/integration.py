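"""Expression/methylation integration.

Brings together the two assays per gene: FPKM from the input library
measures mRNA abundance, and NNFPKM = FPKM_IP / FPKM_INPUT measures m6A
enrichment.  Provides the log2 Pearson correlation between the two (gene
level or averaged within equal-count expression bins), quadrant
classification of genes that change in both methylation and expression
(hyper-up / hyper-down / hypo-up / hypo-down), Table-2-style methylation
summaries, and a generic hypergeometric gene-set over-representation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import round_half_up

logger = logging.getLogger(__name__)

QUADRANT_LABELS = ("hyper-up", "hyper-down", "hypo-up", "hypo-down")


@dataclass
class ExpressionRecord:
    """Per-gene expression and m6A enrichment for one line."""

    gene_id: str
    fpkm_input: float
    fpkm_ip: float
    line: str = ""

    def __post_init__(self) -> None:
        if self.fpkm_input < 0 or self.fpkm_ip < 0:
            raise ValueError("FPKM must be non-negative")

    @property
    def nnfpkm(self) -> float | None:
        """m6A enrichment level; undefined (None) when the gene is not
        expressed in the input library."""
        if self.fpkm_input <= 0:
            return None
        return self.fpkm_ip / self.fpkm_input


@dataclass
class QuadrantCall:
    gene_id: str
    m6a_direction: str  # hyper / hypo
    expr_direction: str  # up / down

    @property
    def label(self) -> str:
        return f"{self.m6a_direction}-{self.expr_direction}"


def fpkm(fragments: float, transcript_length: int, total_fragments: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length <= 0 or total_fragments <= 0:
        raise ValueError("transcript_length and total_fragments must be positive")
    return fragments * 1e9 / (transcript_length * total_fragments)


def expression_methylation_correlation(
    records: list[ExpressionRecord], n_bins: int | None = 50
) -> tuple[float, float]:
    """Pearson r (and p) between log2 FPKM_INPUT and log2 NNFPKM.

    With ``n_bins`` set (the default), genes are ranked by expression and
    averaged within equal-count bins before correlating, which summarizes
    the global abundance/methylation trend; ``n_bins=None`` correlates at
    gene level.  Records without positive FPKM_INPUT and NNFPKM are
    excluded.
    """
    x, y = [], []
    for r in records:
        nn = r.nnfpkm
        if nn is None or nn <= 0:
            continue
        x.append(np.log2(r.fpkm_input))
        y.append(np.log2(nn))
    if len(x) < 3:
        raise ValueError("need >= 3 records with positive FPKM_INPUT and NNFPKM")
    x, y = np.asarray(x), np.asarray(y)
    if n_bins is not None and n_bins >= 3 and len(x) > n_bins:
        order = np.argsort(x, kind="stable")
        splits_x = np.array_split(x[order], n_bins)
        splits_y = np.array_split(y[order], n_bins)
        x = np.array([s.mean() for s in splits_x])
        y = np.array([s.mean() for s in splits_y])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: correlation undefined")
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quadrant_classify(
    dynamic_by_gene: dict[str, str],
    de_by_gene: dict[str, str],
) -> tuple[list[QuadrantCall], dict[str, int], int]:
    """Cross genes' methylation direction with their expression direction.

    ``dynamic_by_gene`` maps gene -> aggregated dynamic direction (high /
    low / conflict / ns); ``de_by_gene`` maps gene -> up / down / ns.  A
    gene is classified only when both calls are directional; genes whose
    dynamic peaks disagree (``conflict``) are excluded and counted.
    Returns (calls, per-label counts, number of conflict-excluded genes).
    """
    calls = []
    n_conflict = 0
    for gene, mdir in dynamic_by_gene.items():
        if mdir == "conflict":
            n_conflict += 1
            continue
        if mdir not in ("high", "low"):
            continue
        edir = de_by_gene.get(gene, "ns")
        if edir not in ("up", "down"):
            continue
        calls.append(
            QuadrantCall(gene, "hyper" if mdir == "high" else "hypo", edir)
        )
    counts = {label: 0 for label in QUADRANT_LABELS}
    for c in calls:
        counts[c.label] += 1
    if n_conflict:
        logger.info("excluded %d genes with conflicting dynamic peaks", n_conflict)
    return calls, counts, n_conflict


def aggregate_dynamic_directions(
    peak_directions_by_gene: dict[str, list[str]],
) -> dict[str, str]:
    """Collapse per-peak dynamic directions to one per gene; genes with
    both high and low peaks become ``conflict``."""
    out = {}
    for gene, dirs in peak_directions_by_gene.items():
        directional = {d for d in dirs if d in ("high", "low")}
        if len(directional) == 2:
            out[gene] = "conflict"
        elif directional:
            out[gene] = directional.pop()
        else:
            out[gene] = "ns"
    return out


def quadrant_shares(counts: dict[str, int]) -> dict[str, float]:
    """Printed-precision shares: concordance within hyper and hypo (integer
    %), discordant share of all classified genes (integer %), and the
    concordant fraction (one decimal %)."""
    hyper = counts["hyper-up"] + counts["hyper-down"]
    hypo = counts["hypo-up"] + counts["hypo-down"]
    total = hyper + hypo
    out = {}
    if hyper:
        out["hyper_up_pct"] = round_half_up(100 * counts["hyper-up"] / hyper)
    if hypo:
        out["hypo_down_pct"] = round_half_up(100 * counts["hypo-down"] / hypo)
    if total:
        discordant = counts["hyper-down"] + counts["hypo-up"]
        out["discordant_pct"] = round_half_up(100 * discordant / total)
        out["concordant_frac_pct"] = round_half_up(
            100 * (counts["hyper-up"] + counts["hypo-down"]) / total, 1
        )
    return out


def share_pct(part: float, total: float, ndigits: int = 0) -> float:
    """Percentage share at printed precision (round-half-up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, ndigits)


def summarize_counts(
    n_transcripts: int, n_methylated: int, n_peaks: int
) -> dict[str, float]:
    """Table-2-style summary from raw counts: peaks per methylated
    transcript and per transcript (2 decimals), percent methylated
    (integer %, round-half-up)."""
    if n_transcripts <= 0:
        raise ValueError("need a positive transcript count")
    out = {
        "n_transcripts": n_transcripts,
        "n_methylated": n_methylated,
        "n_peaks": n_peaks,
        "peaks_per_transcript": round_half_up(n_peaks / n_transcripts, 2),
        "percent_methylated": round_half_up(100 * n_methylated / n_transcripts),
    }
    out["peaks_per_methylated_transcript"] = (
        round_half_up(n_peaks / n_methylated, 2) if n_methylated else float("nan")
    )
    return out


def methylation_summary(
    assignments: list[list[str]], n_transcripts: int
) -> dict[str, float]:
    """Methylation summary from peak-to-transcript assignments (each peak
    counted on its first assigned transcript)."""
    methylated = {tids[0] for tids in assignments if tids}
    n_peaks = sum(1 for tids in assignments if tids)
    return summarize_counts(n_transcripts, len(methylated), n_peaks)


def geneset_overrepresentation(
    hit_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation p per gene set.

    Sets are intersected with the universe; sets with < 2 universe members
    are skipped.  Returns a frame with overlap counts, p-values and a
    significance flag at ``p_threshold``.
    """
    if not universe:
        raise ValueError("empty universe")
    hits = hit_genes & universe
    rows = []
    for set_id, members in gene_sets.items():
        members = members & universe
        if len(members) < 2:
            logger.warning("gene set %s has < 2 universe members: skipped", set_id)
            continue
        overlap = len(hits & members)
        # P(X >= overlap), X ~ Hypergeom(|U|, |set|, |hits|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(members),
                "n_hits": len(hits),
                "overlap": overlap,
                "p_value": p,
                "significant": p < p_threshold,
            }
        )
    return pd.DataFrame(rows)


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT-like TSV: set_id <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
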
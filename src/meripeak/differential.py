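"""Line-dynamic methylation and differential expression.

Dynamic methylation on common peaks uses a likelihood-ratio (G) test on
replicate-pooled, library-size-normalized IP counts: the pooled counts of
the two lines form a 2-cell table tested against an equal split (df = 1),
G = 2 * sum O ln(O/E).  Size factors are DESeq-style median-of-ratios over
the common peaks.  Fold changes use a 0.5-count pseudocount.

Differential expression between lines uses a Welch t-test on log2(FPKM+1)
with a small variance floor; fold changes use a 1-FPKM pseudocount.

Both calls apply the same thresholds: |log2 FC| >= 1 and raw p < 0.05 (no
multiple-testing correction in the default decision; BH-FDR values are
emitted alongside for reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Peak

logger = logging.getLogger(__name__)

LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
COUNT_PSEUDO = 0.5
FPKM_PSEUDO = 1.0
_VAR_EPS = 1e-8


@dataclass
class DynamicPeakResult:
    """Per-common-peak dynamic-methylation call (direction of line B
    relative to line A)."""

    peak: tuple[Peak, Peak]
    counts_a: np.ndarray
    counts_b: np.ndarray
    log2fc: float
    p_value: float
    direction: str  # high / low / ns


@dataclass
class DiffExprResult:
    gene_id: str
    fpkm_a: np.ndarray
    fpkm_b: np.ndarray
    log2fc: float
    p_value: float
    direction: str  # up / down / ns


def _direction(log2fc: float, p: float, pos: str, neg: str) -> str:
    if p < P_THRESHOLD and log2fc >= LOG2FC_THRESHOLD:
        return pos
    if p < P_THRESHOLD and log2fc <= -LOG2FC_THRESHOLD:
        return neg
    return "ns"


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors for a (features x samples) count matrix.

    Rows with any zero are excluded from the geometric-mean reference; a
    factor of 1 is used when nothing is left.
    """
    counts = np.asarray(counts, dtype=float)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        logger.warning("no all-positive rows: size factors set to 1")
        return np.ones(counts.shape[1])
    ref = np.exp(np.mean(np.log(counts[pos]), axis=1))
    return np.median(counts[pos] / ref[:, None], axis=0)


def g_test_pooled(
    norm_a: np.ndarray, norm_b: np.ndarray
) -> tuple[float, float]:
    """G statistic and p for pooled normalized counts vs an equal split.

    O = (sum of normalized counts in A, in B); E splits the pooled total by
    normalized library mass, which is equal after normalization; df = 1.
    """
    oa, ob = float(np.sum(norm_a)), float(np.sum(norm_b))
    total = oa + ob
    if total <= 0:
        return 0.0, 1.0
    ea = eb = total / 2.0
    g = 0.0
    for o, e in ((oa, ea), (ob, eb)):
        if o > 0:
            g += o * np.log(o / e)
    g *= 2.0
    return g, float(stats.chi2.sf(g, df=1))


def dynamic_peaks(
    common_pairs: list[tuple[Peak, Peak]],
    ip_counts_a: np.ndarray,
    ip_counts_b: np.ndarray,
    norm_factors: np.ndarray | None = None,
) -> list[DynamicPeakResult]:
    """Dynamic-methylation calls for common peaks.

    ``ip_counts_a``/``ip_counts_b`` are (peaks x replicates) IP fragment
    counts in the common-peak intervals.  ``norm_factors`` (one per sample,
    A replicates then B) defaults to median-of-ratios over the peaks.
    """
    a = np.atleast_2d(np.asarray(ip_counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(ip_counts_b, dtype=float))
    if a.shape[0] != len(common_pairs) or b.shape[0] != len(common_pairs):
        raise ValueError("count matrices must have one row per common peak")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per line")
    if norm_factors is None:
        norm_factors = median_of_ratios(np.hstack([a, b]))
    norm_factors = np.asarray(norm_factors, dtype=float)
    na = a / norm_factors[: a.shape[1]]
    nb = b / norm_factors[a.shape[1] :]
    out = []
    for i, pair in enumerate(common_pairs):
        if a[i].sum() == 0 and b[i].sum() == 0:
            logger.warning("peak %d has zero counts in both lines: ns", i)
            out.append(
                DynamicPeakResult(pair, a[i], b[i], 0.0, 1.0, "ns")
            )
            continue
        g, p = g_test_pooled(na[i], nb[i])
        log2fc = float(
            np.log2((nb[i].mean() + COUNT_PSEUDO) / (na[i].mean() + COUNT_PSEUDO))
        )
        out.append(
            DynamicPeakResult(
                pair, a[i], b[i], log2fc, p, _direction(log2fc, p, "high", "low")
            )
        )
    return out


def welch_log_t(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t p-value on log2(FPKM+1) with a variance floor; identical
    zero-variance vectors give p = 1."""
    lx, ly = np.log2(np.asarray(x, float) + FPKM_PSEUDO), np.log2(
        np.asarray(y, float) + FPKM_PSEUDO
    )
    vx, vy = lx.var(ddof=1), ly.var(ddof=1)
    if vx == 0 and vy == 0 and lx.mean() == ly.mean():
        return 1.0
    vx, vy = max(vx, _VAR_EPS), max(vy, _VAR_EPS)
    nx, ny = len(lx), len(ly)
    se2 = vx / nx + vy / ny
    t = (ly.mean() - lx.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2 * stats.t.sf(abs(t), df))


def diff_expression(
    fpkm_table_a: pd.DataFrame, fpkm_table_b: pd.DataFrame
) -> list[DiffExprResult]:
    """Differential expression of line B vs line A from per-replicate FPKM
    tables (rows = genes, columns = replicates).  Genes absent from one
    table are treated as all-zero there."""
    if fpkm_table_a.shape[1] < 2 or fpkm_table_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per line")
    genes = sorted(set(fpkm_table_a.index) | set(fpkm_table_b.index))
    out = []
    for gene in genes:
        fa = (
            fpkm_table_a.loc[gene].to_numpy(dtype=float)
            if gene in fpkm_table_a.index
            else np.zeros(fpkm_table_a.shape[1])
        )
        fb = (
            fpkm_table_b.loc[gene].to_numpy(dtype=float)
            if gene in fpkm_table_b.index
            else np.zeros(fpkm_table_b.shape[1])
        )
        if fa.sum() == 0 and fb.sum() == 0:
            out.append(DiffExprResult(gene, fa, fb, 0.0, 1.0, "ns"))
            continue
        p = welch_log_t(fa, fb)
        log2fc = float(np.log2((fb.mean() + FPKM_PSEUDO) / (fa.mean() + FPKM_PSEUDO)))
        out.append(
            DiffExprResult(gene, fa, fb, log2fc, p, _direction(log2fc, p, "up", "down"))
        )
    return out


def results_to_frame(
    results: list[DynamicPeakResult] | list[DiffExprResult],
) -> pd.DataFrame:
    """Tabular results with a BH-FDR column (reference only; directions use
    raw p)."""
    rows = []
    for r in results:
        if isinstance(r, DynamicPeakResult):
            pa = r.peak[0]
            rows.append(
                {
                    "seqid": pa.seqid,
                    "start": pa.start,
                    "end": pa.end,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = _bh(df["p_value"].to_numpy())
    return df


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
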
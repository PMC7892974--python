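"""End-to-end orchestration of the analysis stages.

Runs, on a simulated (or pre-generated) dataset: per-replicate peak
calling -> replicate consolidation -> between-line comparison -> metagene
profiling and methylation summaries -> dynamic-methylation and
differential-expression tests -> expression/methylation integration ->
motif-window preparation and k-mer enrichment.  Collects plain-number
summaries suitable for manifests and reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .differential import (
    DiffExprResult,
    DynamicPeakResult,
    diff_expression,
    dynamic_peaks,
    results_to_frame,
)
from .integration import (
    ExpressionRecord,
    aggregate_dynamic_directions,
    expression_methylation_correlation,
    methylation_summary,
    quadrant_classify,
    quadrant_shares,
)
from .intervals import (
    Peak,
    PeakSetComparison,
    assign_peaks_to_transcripts,
    classify_common_unique,
    consolidate_recurrent,
    write_bed,
)
from .metagene import metagene_profile, peaks_per_transcript, segment_pie
from .motif import (
    extract_windows,
    kmer_enrichment,
    rank_kmers,
    select_top_peaks,
    shuffle_controls,
    write_fasta,
)
from .peakcall import PeakCallerParams, count_in_interval, peak_fdr_recall
from .synthetic import MeripDataset, SimulationConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Structured stage outputs plus a JSON-serializable summary."""

    dataset: MeripDataset
    peaks_by_line: dict[str, list[Peak]]
    comparison: PeakSetComparison
    dynamic: list[DynamicPeakResult]
    de: list[DiffExprResult]
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    outdir: str | None = None,
    caller_params: PeakCallerParams | None = None,
    motif_top_n: int = 1000,
) -> PipelineResult:
    """Simulate a dataset and run every analysis stage on it.

    The peak caller's effective background size is the simulated
    transcriptome size (the spliced length of all primary isoforms), the
    same convention the study uses for its real transcriptome.
    """
    data = simulate(config)
    return analyze(data, outdir=outdir, caller_params=caller_params, motif_top_n=motif_top_n)


def analyze(
    data: MeripDataset,
    outdir: str | None = None,
    caller_params: PeakCallerParams | None = None,
    motif_top_n: int = 1000,
) -> PipelineResult:
    config = SimulationConfig(**data.truth.config)
    txome = data.transcriptome
    segmented = txome.segmented_primary()
    primary = txome.primary
    tid_to_gene = {tm.transcript_id: tm.gene_id for tm in txome.transcripts}
    if caller_params is None:
        caller_params = PeakCallerParams(
            effective_size=float(txome.transcriptome_size),
            fragment_length=config.fragment_length,
        )
    summary: dict = {"n_genes": len(primary), "version": __version__}

    # --- peak calling and consolidation per line ---
    truth_intervals = [s.interval for s in data.truth.sites]
    peaks_by_line: dict[str, list[Peak]] = {}
    for line in config.lines:
        replicate_sets = []
        for rep in range(1, config.n_replicates + 1):
            replicate_sets.append(_call(data, line, rep, caller_params))
        consolidated = consolidate_recurrent(replicate_sets)
        for p in consolidated:
            p.line = line
        peaks_by_line[line] = consolidated
        recall, fdp = peak_fdr_recall(consolidated, truth_intervals)
        summary[f"recall_{line}"] = recall
        summary[f"fdp_{line}"] = fdp
        summary[f"n_recurrent_peaks_{line}"] = len(consolidated)

    # --- assignment, metagene, methylation summary per line ---
    assignments_by_line = {}
    for line in config.lines:
        peaks = peaks_by_line[line]
        assignments = assign_peaks_to_transcripts(peaks, segmented)
        assignments_by_line[line] = assignments
        profile = metagene_profile(peaks, segmented, assignments)
        pie = segment_pie(peaks, segmented, assignments)
        hist, per_meth, per_tx = peaks_per_transcript(assignments, len(primary))
        summary[f"metagene_{line}"] = {
            "segment_fractions": pie,
            "n_peaks_used": profile.n_peaks_used,
            "histogram": hist,
        }
        summary[f"methylation_summary_{line}"] = methylation_summary(
            assignments, len(primary)
        )

    # Union-of-lines methylated fraction: a transcript counts as methylated
    # when a recurrent peak is assigned to it in either line (sites exist in
    # both lines; line effects only modulate intensity, so the union is the
    # natural estimator of the underlying methylated fraction).
    union_meth: set[str] = set()
    for line in config.lines:
        for tids in assignments_by_line[line]:
            if tids:
                union_meth.add(tids[0])
    summary["methylated_fraction_union_pct"] = 100.0 * len(union_meth) / len(primary)

    # --- between-line comparison ---
    line_a, line_b = config.lines
    comparison = classify_common_unique(peaks_by_line[line_a], peaks_by_line[line_b])
    summary["n_common_peaks"] = comparison.n_common_a
    summary["n_unique_a"] = len(comparison.unique_a)
    summary["n_unique_b"] = len(comparison.unique_b)

    # --- dynamic methylation on common peaks ---
    pairs = comparison.common
    counts_a = np.array(
        [
            [
                count_in_interval(data.tracks[(line_a, rep, "ip")], pa.interval)
                for rep in range(1, config.n_replicates + 1)
            ]
            for pa, _ in pairs
        ]
    )
    counts_b = np.array(
        [
            [
                count_in_interval(data.tracks[(line_b, rep, "ip")], pa.interval)
                for rep in range(1, config.n_replicates + 1)
            ]
            for pa, _ in pairs
        ]
    )
    # Library-depth size factors: with a 71%-one-directional change
    # composition, median-of-ratios is biased toward the majority direction,
    # so the pipeline normalizes by IP library totals instead.
    ip_totals = np.array(
        [
            data.tracks[(line, rep, "ip")].total_fragments
            for line in (line_a, line_b)
            for rep in range(1, config.n_replicates + 1)
        ]
    )
    norm = ip_totals / np.exp(np.mean(np.log(ip_totals)))
    dyn = (
        dynamic_peaks(pairs, counts_a, counts_b, norm_factors=norm)
        if len(pairs)
        else []
    )
    n_dynamic = sum(1 for d in dyn if d.direction != "ns")
    n_low = sum(1 for d in dyn if d.direction == "low")
    summary["n_dynamic_peaks"] = n_dynamic
    summary["dynamic_low_share_pct"] = (
        100.0 * n_low / n_dynamic if n_dynamic else float("nan")
    )

    # --- differential expression (input libraries) ---
    de = diff_expression(data.fpkm_input[line_a], data.fpkm_input[line_b])
    summary["n_up_genes"] = sum(1 for r in de if r.direction == "up")
    summary["n_down_genes"] = sum(1 for r in de if r.direction == "down")

    # --- integration: correlation and quadrants ---
    for line in config.lines:
        fin = data.fpkm_input[line].mean(axis=1)
        fip = data.fpkm_ip[line].mean(axis=1)
        records = [
            ExpressionRecord(g, float(fin[g]), float(fip[g]), line=line)
            for g in fin.index
        ]
        r_binned, _ = expression_methylation_correlation(records, n_bins=50)
        r_gene, _ = expression_methylation_correlation(records, n_bins=None)
        summary[f"correlation_{line}"] = {"binned_r": r_binned, "gene_r": r_gene}

    pair_assignments = assign_peaks_to_transcripts([pa for pa, _ in pairs], segmented)
    dirs_by_gene: dict[str, list[str]] = {}
    for d, tids in zip(dyn, pair_assignments):
        for tid in tids:
            gene = tid_to_gene[tid]
            dirs_by_gene.setdefault(gene, []).append(d.direction)
            break
    dynamic_by_gene = aggregate_dynamic_directions(dirs_by_gene)
    de_by_gene = {r.gene_id: r.direction for r in de}
    calls, quad_counts, n_conflict = quadrant_classify(dynamic_by_gene, de_by_gene)
    summary["quadrant_counts"] = quad_counts
    summary["quadrant_shares"] = quadrant_shares(quad_counts)
    summary["n_conflict_genes"] = n_conflict
    n_dyn_genes = sum(1 for v in dynamic_by_gene.values() if v in ("high", "low"))
    summary["n_dynamic_genes"] = n_dyn_genes
    n_classified = sum(quad_counts.values())
    summary["dynamic_genes_with_expression_change_pct"] = (
        100.0 * n_classified / n_dyn_genes if n_dyn_genes else float("nan")
    )

    # --- motif windows and k-mer enrichment (reference line) ---
    sequences = txome.sequences
    top = select_top_peaks(peaks_by_line[line_a], n=motif_top_n)
    if not top:
        logger.warning("no qualifying peaks for motif analysis")
        summary["motif"] = None
        result = PipelineResult(
            dataset=data,
            peaks_by_line=peaks_by_line,
            comparison=comparison,
            dynamic=dyn,
            de=de,
            summary=summary,
        )
        if outdir:
            _write_outputs(result, [], [], outdir)
        return result
    strands = [
        _strand_for(assign, primary, tid_to_gene)
        for assign in assign_peaks_to_transcripts(top, segmented)
    ]
    targets = extract_windows(top, sequences, strands=strands)
    controls = shuffle_controls(targets, seed=int(data.truth.config["seed"]))
    enr = kmer_enrichment(targets, controls, ["GGACU", "RRACH"])
    ranked = rank_kmers(targets, controls, k=5)
    rank_of_ggact = next(i for i, (kmer, _) in enumerate(ranked) if kmer == "GGACT") + 1
    summary["motif"] = {
        "ggacu_z": enr[0].z,
        "ggacu_target_rate": enr[0].target_rate,
        "ggacu_control_rate": enr[0].control_rate,
        "rrach_z": enr[1].z,
        "top_kmer": ranked[0][0],
        "ggacu_rank": rank_of_ggact,
        "n_windows": len(targets),
    }

    result = PipelineResult(
        dataset=data,
        peaks_by_line=peaks_by_line,
        comparison=comparison,
        dynamic=dyn,
        de=de,
        summary=summary,
    )
    if outdir:
        _write_outputs(result, targets, controls, outdir)
    return result


def _call(data: MeripDataset, line: str, rep: int, params: PeakCallerParams) -> list[Peak]:
    from .peakcall import call_peaks

    return call_peaks(
        data.tracks[(line, rep, "ip")],
        data.tracks[(line, rep, "input")],
        params,
        sample_id=f"{line}_rep{rep}",
        line=line,
    )


def _strand_for(tids: list[str], primary, tid_to_gene) -> str:
    for tid in tids:
        gene = tid_to_gene.get(tid)
        if gene in primary:
            return primary[gene].strand
    return "+"


def _write_outputs(result: PipelineResult, targets, controls, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for line, peaks in result.peaks_by_line.items():
        write_bed(peaks, os.path.join(outdir, f"recurrent_peaks_{line}.bed"))
    write_bed(
        [pa for pa, _ in result.comparison.common],
        os.path.join(outdir, "common_peaks.bed"),
    )
    write_bed(result.comparison.unique_a, os.path.join(outdir, "unique_a.bed"))
    write_bed(result.comparison.unique_b, os.path.join(outdir, "unique_b.bed"))
    results_to_frame(result.dynamic).to_csv(
        os.path.join(outdir, "dynamic_peaks.tsv"), sep="\t", index=False
    )
    results_to_frame(result.de).to_csv(
        os.path.join(outdir, "diff_expression.tsv"), sep="\t", index=False
    )
    if targets:
        write_fasta(targets, os.path.join(outdir, "motif_targets.fa"))
        write_fasta(controls, os.path.join(outdir, "motif_controls.fa"))
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=float)
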
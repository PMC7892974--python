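"""Synthetic two-line, three-replicate MeRIP-seq dataset with ground truth.

The generator emulates the statistical structure of a divergent-line m6A
profiling study at desk scale: a random multi-exon transcriptome on one
~4 Mb chromosome; ~70% of genes methylated with 1-4 m6A sites biased
toward CDS and the start/stop-codon windows; GGACU (DNA: GGACT) embedded
at most true summits; IP coverage equal to the input background except at
sites, where it is multiplied by a flat-top enrichment profile; a fraction
of sites line-dynamic with a 71.1% low-in-B share; and gene expression
log-linearly coupled (negative slope by default) to the per-gene
methylation load.

Coverage is drawn per base as gamma-Poisson (negative binomial) counts:
a per-gene, per-replicate gamma factor models biological dispersion and a
uniform library factor models depth differences.  Per-base draws are
independent given the rate, so window sums are well-calibrated count
statistics; fragment-level autocorrelation of real coverage is not
modelled (the ~100-nt fragment size instead shapes the enrichment
footprint and sets the fragment-equivalent library size).

Everything is deterministic under the config seed, and the ground truth is
stored independently of the emitted files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    GenomicInterval,
    SegmentedTranscript,
    TranscriptModel,
    primary_isoforms,
    segment_transcript,
)
from .integration import fpkm as fpkm_value
from .peakcall import CoverageTrack

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-scale simulation parameters.

    Scale parameters are chosen to mirror the profiled study design: two
    lines ("A" = lean-like reference, "B" = fat-like), three biological
    replicates each, IP + input per replicate, ~70% methylated transcripts,
    and a 71.1% low-in-B share among line-dynamic sites.
    """

    n_genes: int = 1200
    seqid: str = "chr1"
    seed: int = 0
    # transcript structure
    length_log_mean: float = 7.95  # ln nt; median ~2840 nt
    length_log_sd: float = 0.45
    min_length: int = 800
    max_length: int = 12000
    utr5_frac: float = 0.12
    utr3_frac: float = 0.28
    max_exons: int = 4
    intron_range: tuple[int, int] = (100, 600)
    spacing_range: tuple[int, int] = (600, 1500)
    isoform_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # 1..3 isoforms
    # methylation truth
    methylated_fraction: float = 0.7
    peak_count_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)  # 1..4 sites
    segment_weights: tuple[float, ...] = (0.05, 0.20, 0.40, 0.25, 0.10)
    min_site_separation: int = 550  # spliced nt between summits
    motif_embed_prob: float = 0.8
    # enrichment / coverage
    enrichment_fold: float = 8.0
    site_flat_halfwidth: int = 75  # ~fragment-smeared m6A peak core
    site_taper: int = 50
    background_window_mean: float = 20.0  # input fragments per 100-nt window
    fragment_length: int = 100
    nb_dispersion: float = 0.1
    library_factor_range: tuple[float, float] = (0.9, 1.1)
    n_replicates: int = 3
    lines: tuple[str, str] = ("A", "B")
    # line-dynamic methylation
    dynamic_fraction: float = 0.35
    low_share: float = 0.711
    dynamic_effect_fold: float = 3.5  # B:A intensity ratio at dynamic sites
    dynamic_effect_split: float = 7 / 3  # major-line multiplier of the base fold
    # expression-methylation coupling
    coupling_slope: float = -0.5
    coupling_noise_sd: float = 0.25
    expr_log2_sd: float = 0.25
    expr_response_prob: float = 0.125
    concordant_prob: float = 0.93
    expr_effect_log2: float = 1.2

    def __post_init__(self) -> None:
        for probs, name in (
            (self.isoform_probs, "isoform_probs"),
            (self.peak_count_probs, "peak_count_probs"),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for p, name in (
            (self.methylated_fraction, "methylated_fraction"),
            (self.motif_embed_prob, "motif_embed_prob"),
            (self.dynamic_fraction, "dynamic_fraction"),
            (self.low_share, "low_share"),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(
            self.n_genes,
            self.min_length,
            self.enrichment_fold,
            self.background_window_mean,
            self.fragment_length,
        ) <= 0:
            raise ValueError("scale parameters must be positive")
        if self.min_length < 2 * (self.site_flat_halfwidth + self.site_taper):
            raise ValueError("min_length too short for the site footprint")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("intron_range", "spacing_range", "library_factor_range",
                    "isoform_probs", "peak_count_probs", "segment_weights", "lines"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SiteTruth:
    """One true m6A site with its host transcript and line effect."""

    gene_id: str
    transcript_id: str
    seqid: str
    summit: int  # genomic
    spliced_pos: int
    segment: str
    flat_start: int  # genomic bounds of the flat-top footprint
    flat_end: int
    motif: bool
    line_effect: str  # high / low / none (line B relative to line A)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.flat_start, self.flat_end)


@dataclass
class GroundTruth:
    sites: list[SiteTruth]
    methylated_genes: list[str]
    expression_log2: dict[str, float]  # line-A log2 offset from base rate
    expression_log2_b: dict[str, float]
    methyl_load_log2: dict[str, float]
    coupling_slope: float
    config: dict

    def to_json(self, path: str) -> None:
        data = {
            "sites": [asdict(s) for s in self.sites],
            "methylated_genes": self.methylated_genes,
            "expression_log2": self.expression_log2,
            "expression_log2_b": self.expression_log2_b,
            "methyl_load_log2": self.methyl_load_log2,
            "coupling_slope": self.coupling_slope,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            sites=[SiteTruth(**s) for s in data["sites"]],
            methylated_genes=data["methylated_genes"],
            expression_log2=data["expression_log2"],
            expression_log2_b=data["expression_log2_b"],
            methyl_load_log2=data["methyl_load_log2"],
            coupling_slope=data["coupling_slope"],
            config=data["config"],
        )


@dataclass
class Transcriptome:
    """Simulated genome + annotation, with segmentations precomputed for
    the primary (longest-CDS) isoform of each gene."""

    sequence_codes: dict[str, np.ndarray]  # uint8 codes 0..3
    transcripts: list[TranscriptModel]
    truth: GroundTruth

    @property
    def sequences(self) -> dict[str, str]:
        return {k: codes_to_str(v) for k, v in self.sequence_codes.items()}

    @property
    def primary(self) -> dict[str, TranscriptModel]:
        return primary_isoforms(self.transcripts)

    def segmented_primary(self) -> dict[str, SegmentedTranscript]:
        return {
            tm.transcript_id: segment_transcript(tm)
            for tm in self.primary.values()
        }

    @property
    def genome_size(self) -> int:
        return sum(len(v) for v in self.sequence_codes.values())

    @property
    def transcriptome_size(self) -> int:
        return sum(tm.spliced_length for tm in self.primary.values())

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for seqid in sorted(self.sequence_codes):
                fh.write(f">{seqid}\n")
                s = codes_to_str(self.sequence_codes[seqid])
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for tm in self.transcripts:
                attrs = (
                    f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}";'
                )
                rows = [
                    (
                        "transcript",
                        tm.interval.start + 1,
                        tm.interval.end,
                    )
                ]
                rows += [("exon", e.start + 1, e.end) for e in tm.exons]
                if tm.is_coding:
                    for piece in tm.spliced_to_genomic(*tm.cds_spliced_bounds()):
                        rows.append(("CDS", piece.start + 1, piece.end))
                for ftype, start, end in rows:
                    fh.write(
                        f"{tm.seqid}\tsim\t{ftype}\t{start}\t{end}\t.\t"
                        f"{tm.strand}\t.\t{attrs}\n"
                    )


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _make_gene(
    rng: np.random.Generator, cfg: SimulationConfig, gene_idx: int, cursor: int
) -> tuple[list[TranscriptModel], int]:
    L = int(
        np.clip(
            np.exp(rng.normal(cfg.length_log_mean, cfg.length_log_sd)),
            cfg.min_length,
            cfg.max_length,
        )
    )
    n_exons = int(rng.integers(1, cfg.max_exons + 1))
    n_exons = max(1, min(n_exons, L // 150))
    base = 100
    weights = rng.dirichlet(np.ones(n_exons))
    extra = rng.multinomial(L - base * n_exons, weights)
    exon_lengths = extra + base
    introns = (
        rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1, n_exons - 1)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    gid = f"G{gene_idx:05d}"
    exons = []
    pos = cursor
    for i, elen in enumerate(exon_lengths):
        exons.append(GenomicInterval(cfg.seqid, pos, pos + int(elen), strand))
        pos += int(elen)
        if i < len(introns):
            pos += int(introns[i])
    gene_end = pos
    u5 = int(cfg.utr5_frac * L)
    u3 = int(cfg.utr3_frac * L)
    tm = TranscriptModel(
        transcript_id=f"{gid}.t1",
        gene_id=gid,
        interval=GenomicInterval(cfg.seqid, cursor, gene_end, strand),
        exons=exons,
        cds_start=None,
        cds_end=None,
    )
    pieces = tm.spliced_to_genomic(u5, L - u3)
    tm.cds_start = min(p.start for p in pieces)
    tm.cds_end = max(p.end for p in pieces)
    tm.__post_init__()  # revalidate with CDS set
    models = [tm]
    n_iso = int(rng.choice(len(cfg.isoform_probs), p=cfg.isoform_probs)) + 1
    if n_iso >= 2:
        iso = _trimmed_isoform(tm, f"{gid}.t2", three_prime=True, trim=min(150, u3 - 5))
        if iso is not None:
            models.append(iso)
    if n_iso >= 3:
        iso = _trimmed_isoform(tm, f"{gid}.t3", three_prime=False, trim=min(100, u5 - 5))
        if iso is not None:
            models.append(iso)
    spacing = int(rng.integers(cfg.spacing_range[0], cfg.spacing_range[1] + 1))
    return models, gene_end + spacing


def _trimmed_isoform(
    tm: TranscriptModel, tid: str, three_prime: bool, trim: int
) -> TranscriptModel | None:
    """A UTR-trimmed isoform sharing the CDS (keeps the primary-isoform
    ranking on the full-length model)."""
    if trim <= 10:
        return None
    # identify the genomic end to trim: 3' end is the high end on +, low on -
    exons = [GenomicInterval(e.seqid, e.start, e.end, e.strand) for e in tm.exons]
    at_high_end = (tm.strand == "+") == three_prime
    idx = -1 if at_high_end else 0
    e = exons[idx]
    if e.length <= trim + 20:
        return None
    if at_high_end:
        new_e = GenomicInterval(e.seqid, e.start, e.end - trim, e.strand)
        bound = (tm.interval.start, tm.interval.end - trim)
        if tm.cds_end > new_e.end and idx == -1 and len(exons) == 1:
            return None
        if tm.cds_end > new_e.end:
            return None
    else:
        new_e = GenomicInterval(e.seqid, e.start + trim, e.end, e.strand)
        bound = (tm.interval.start + trim, tm.interval.end)
        if tm.cds_start < new_e.start:
            return None
    exons[idx] = new_e
    return TranscriptModel(
        transcript_id=tid,
        gene_id=tm.gene_id,
        interval=GenomicInterval(tm.seqid, bound[0], bound[1], tm.strand),
        exons=exons,
        cds_start=tm.cds_start,
        cds_end=tm.cds_end,
    )


def _place_sites(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    st: SegmentedTranscript,
) -> list[tuple[int, str]]:
    """Spliced summit positions + segment labels for one transcript,
    biased by segment weights and separated by >= min_site_separation."""
    n_sites = int(rng.choice(len(cfg.peak_count_probs), p=cfg.peak_count_probs)) + 1
    margin = cfg.site_flat_halfwidth + cfg.site_taper
    labels = [
        label
        for label, (a, b) in st.spliced_segments.items()
        if b - a > 0
    ]
    weights = np.array(
        [cfg.segment_weights[i] for i, lab in enumerate(
            ("five_prime_utr", "start_codon", "cds", "stop_codon", "three_prime_utr")
        ) if lab in labels]
    )
    weights = weights / weights.sum()
    placed: list[tuple[int, str]] = []
    for _ in range(n_sites):
        for _attempt in range(30):
            label = str(rng.choice(labels, p=weights))
            a, b = st.spliced_segments[label]
            spos = int(rng.integers(a, b))
            if spos < margin or spos > st.spliced_length - margin:
                continue
            if all(abs(spos - q) >= cfg.min_site_separation for q, _ in placed):
                placed.append((spos, label))
                break
    return placed


def simulate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Random genome + annotation + true m6A sites (with motifs embedded).

    Deterministic under ``config.seed``; line effects, expression and
    coverage are added by :func:`simulate_merip`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    cursor = 1000
    transcripts: list[TranscriptModel] = []
    for g in range(config.n_genes):
        models, cursor = _make_gene(rng, config, g, cursor)
        transcripts.extend(models)
    genome_len = cursor + 1000
    codes = rng.integers(0, 4, genome_len, dtype=np.uint8)
    txome_sites: list[SiteTruth] = []
    primary = primary_isoforms(transcripts)
    methylated = [
        tm.gene_id
        for tm in primary.values()
        if rng.random() < config.methylated_fraction
    ]
    methylated_set = set(methylated)
    for tm in primary.values():
        if tm.gene_id not in methylated_set:
            continue
        st = segment_transcript(tm)
        for spos, label in _place_sites(rng, config, st):
            summit = tm.genomic_position(spos)
            motif = bool(rng.random() < config.motif_embed_prob)
            if motif:
                _embed_motif(codes, tm, spos)
            flat = config.site_flat_halfwidth
            txome_sites.append(
                SiteTruth(
                    gene_id=tm.gene_id,
                    transcript_id=tm.transcript_id,
                    seqid=tm.seqid,
                    summit=summit,
                    spliced_pos=spos,
                    segment=label,
                    flat_start=min(summit - flat, summit + flat),
                    flat_end=max(summit - flat, summit + flat) + 1,
                    motif=motif,
                    line_effect="none",
                )
            )
    truth = GroundTruth(
        sites=txome_sites,
        methylated_genes=sorted(methylated_set),
        expression_log2={},
        expression_log2_b={},
        methyl_load_log2={},
        coupling_slope=config.coupling_slope,
        config=asdict(config),
    )
    return Transcriptome(
        sequence_codes={config.seqid: codes},
        transcripts=transcripts,
        truth=truth,
    )


def _embed_motif(codes: np.ndarray, tm: TranscriptModel, spos: int) -> None:
    """Write GGACT (RNA GGACU) in transcript orientation, centered on the
    methylated A, through the exon chain."""
    motif = "GGACT"
    for j, base in enumerate(motif):
        sp = spos - 2 + j
        if not (0 <= sp < tm.spliced_length):
            continue
        g = tm.genomic_position(sp)
        code = _CODE[base]
        codes[g] = code if tm.strand == "+" else int(_COMP[code])


@dataclass
class MeripDataset:
    """Coverage tracks and derived tables for 2 lines x replicates x
    {IP, input}, plus the completed ground truth."""

    tracks: dict[tuple[str, int, str], CoverageTrack]  # (line, rep, "ip"/"input")
    gene_counts: pd.DataFrame  # genes x sample columns "A_rep1_ip" ...
    fpkm_input: dict[str, pd.DataFrame]  # line -> genes x replicates
    fpkm_ip: dict[str, pd.DataFrame]
    truth: GroundTruth
    transcriptome: Transcriptome


def _site_profile(cfg: SimulationConfig, fold: float) -> np.ndarray:
    """Multiplier profile over spliced offsets: flat top at ``fold``,
    linear taper to 1."""
    flat, taper = cfg.site_flat_halfwidth, cfg.site_taper
    d = np.abs(np.arange(-(flat + taper), flat + taper + 1))
    prof = np.ones(len(d))
    prof[d <= flat] = fold
    mask = (d > flat) & (d <= flat + taper)
    prof[mask] = 1 + (fold - 1) * (flat + taper - d[mask]) / taper
    return prof


def simulate_merip(config: SimulationConfig, txome: Transcriptome) -> MeripDataset:
    """Line effects, expression, and IP/input coverage for the simulated
    transcriptome; completes the ground truth in place."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    truth = txome.truth
    primary = txome.primary
    genome_len = txome.genome_size
    base_rate = config.background_window_mean / 100.0

    # --- line effects on sites ---
    sites_by_gene: dict[str, list[SiteTruth]] = {}
    for s in truth.sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)
        if rng.random() < config.dynamic_fraction:
            s.line_effect = "low" if rng.random() < config.low_share else "high"

    # --- methylation load and coupled expression ---
    flat_width = 2 * config.site_flat_halfwidth + 1
    load_log2: dict[str, float] = {}
    for gid, tm in primary.items():
        n_sites = len(sites_by_gene.get(gid, []))
        load = 1.0 + (config.enrichment_fold - 1.0) * (
            n_sites * flat_width / tm.spliced_length
        )
        load_log2[gid] = float(np.log2(load))
    methylated = set(truth.methylated_genes)
    meth_loads = [load_log2[g] for g in methylated if g in load_log2]
    mean_load = float(np.mean(meth_loads)) if meth_loads else 0.0
    expr_a: dict[str, float] = {}
    expr_b: dict[str, float] = {}
    for gid in primary:
        if gid in methylated:
            z = config.coupling_slope * (load_log2[gid] - mean_load) + rng.normal(
                0.0, config.coupling_noise_sd
            )
        else:
            z = rng.normal(0.0, config.expr_log2_sd)
        expr_a[gid] = float(z)
        expr_b[gid] = float(z)

    # --- expression response of dynamic genes ---
    for gid, sites in sites_by_gene.items():
        dirs = [s.line_effect for s in sites if s.line_effect != "none"]
        if not dirs:
            continue
        if rng.random() >= config.expr_response_prob:
            continue
        n_hi, n_lo = dirs.count("high"), dirs.count("low")
        if n_hi != n_lo:
            majority = "high" if n_hi > n_lo else "low"
        else:
            majority = "low" if rng.random() < config.low_share else "high"
        concordant = rng.random() < config.concordant_prob
        up_in_b = (majority == "high") == concordant
        expr_b[gid] = expr_a[gid] + (
            config.expr_effect_log2 if up_in_b else -config.expr_effect_log2
        )

    truth.expression_log2 = expr_a
    truth.expression_log2_b = expr_b
    truth.methyl_load_log2 = load_log2

    # --- rate arrays per line ---
    up = config.dynamic_effect_split
    down = config.dynamic_effect_fold / config.dynamic_effect_split
    rates: dict[tuple[str, str], np.ndarray] = {}
    gene_spans: dict[str, tuple[int, int]] = {}
    for line, expr in zip(config.lines, (expr_a, expr_b)):
        input_rate = np.zeros(genome_len)
        for gid, tm in primary.items():
            r = base_rate * 2.0 ** expr[gid]
            for e in tm.exons:
                input_rate[e.start : e.end] = r
            gene_spans[gid] = (tm.interval.start, tm.interval.end)
        ip_rate = input_rate.copy()
        for s in truth.sites:
            tm = primary[s.gene_id]
            fold = config.enrichment_fold
            if s.line_effect == "high":
                fold = fold * up if line == config.lines[1] else fold / down
            elif s.line_effect == "low":
                fold = fold / down if line == config.lines[1] else fold * up
            prof = _site_profile(config, fold)
            half = config.site_flat_halfwidth + config.site_taper
            lo = max(0, s.spliced_pos - half)
            hi = min(tm.spliced_length, s.spliced_pos + half + 1)
            gpos = np.array([tm.genomic_position(sp) for sp in range(lo, hi)])
            ip_rate[gpos] *= prof[(lo - (s.spliced_pos - half)) : (hi - (s.spliced_pos - half))]
        # IP libraries are sequenced to the same target depth as the input:
        # rescale so enrichment redistributes reads instead of adding them.
        ip_rate *= input_rate.sum() / ip_rate.sum()
        rates[(line, "input")] = input_rate
        rates[(line, "ip")] = ip_rate

    # --- replicate count tracks ---
    tracks: dict[tuple[str, int, str], CoverageTrack] = {}
    shape = 1.0 / config.nb_dispersion
    for line in config.lines:
        for rep in range(1, config.n_replicates + 1):
            # IP and input libraries of one replicate derive from the same
            # fragmented RNA sample: the per-gene biological factor is shared,
            # while library depth factors are drawn per library.
            factor = np.ones(genome_len)
            for gid, (lo, hi) in gene_spans.items():
                factor[lo:hi] = rng.gamma(shape, config.nb_dispersion)
            lib = rng.uniform(*config.library_factor_range)
            for kind in ("input", "ip"):
                lam = rates[(line, kind)] * factor * lib
                counts = rng.poisson(lam).astype(np.int32)
                tracks[(line, rep, kind)] = CoverageTrack(
                    counts={config.seqid: counts},
                    fragment_length=config.fragment_length,
                )

    # --- per-gene fragment counts and FPKM ---
    genes = sorted(primary)
    count_cols = {}
    for (line, rep, kind), track in tracks.items():
        arr = track.counts[config.seqid]
        cum = np.concatenate(([0], np.cumsum(arr, dtype=np.float64)))
        col = []
        for gid in genes:
            tm = primary[gid]
            depth = sum(float(cum[e.end] - cum[e.start]) for e in tm.exons)
            col.append(depth / config.fragment_length)
        count_cols[f"{line}_rep{rep}_{kind}"] = col
    gene_counts = pd.DataFrame(count_cols, index=genes)

    fpkm_input: dict[str, pd.DataFrame] = {}
    fpkm_ip: dict[str, pd.DataFrame] = {}
    for line in config.lines:
        for kind, store in (("input", fpkm_input), ("ip", fpkm_ip)):
            cols = {}
            for rep in range(1, config.n_replicates + 1):
                track = tracks[(line, rep, kind)]
                frag = gene_counts[f"{line}_rep{rep}_{kind}"]
                cols[f"rep{rep}"] = [
                    fpkm_value(
                        frag[gid], primary[gid].spliced_length, track.total_fragments
                    )
                    for gid in genes
                ]
            store[line] = pd.DataFrame(cols, index=genes)

    return MeripDataset(
        tracks=tracks,
        gene_counts=gene_counts,
        fpkm_input=fpkm_input,
        fpkm_ip=fpkm_ip,
        truth=truth,
        transcriptome=txome,
    )


def simulate(config: SimulationConfig) -> MeripDataset:
    """Convenience: transcriptome + MeRIP dataset in one call."""
    return simulate_merip(config, simulate_transcriptome(config))


def null_coverage_pair(
    n_bases: int,
    mean_per_base: float,
    seed: int,
    fragment_length: int = 100,
    seqid: str = "chr1",
) -> tuple[CoverageTrack, CoverageTrack]:
    """An IP/input pair with identical rates and no enrichment anywhere
    (per-base Poisson), for calibration checks."""
    rng = np.random.default_rng(seed)
    ip = rng.poisson(mean_per_base, n_bases).astype(np.int32)
    inp = rng.poisson(mean_per_base, n_bases).astype(np.int32)
    return (
        CoverageTrack(counts={seqid: ip}, fragment_length=fragment_length),
        CoverageTrack(counts={seqid: inp}, fragment_length=fragment_length),
    )


def null_peak_counts(
    n_peaks: int,
    n_replicates: int,
    seed: int,
    mean_log: float = 4.0,
    mean_sd: float = 0.8,
    dispersion: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (no line effect) NB count matrices for two lines, for type-I
    error checks of the dynamic-peak test.  Per-peak means are shared by
    both lines; counts are gamma-Poisson with the given dispersion."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(mean_log, mean_sd, n_peaks))
    shape = 1.0 / dispersion

    def draw() -> np.ndarray:
        g = rng.gamma(shape, dispersion, (n_peaks, n_replicates))
        return rng.poisson(mu[:, None] * g).astype(float)

    return draw(), draw()


def emit_fixture(config: SimulationConfig, outdir: str) -> dict[str, str]:
    """Write the full fixture (FASTA, GTF, 12 bedGraphs, count/FPKM TSVs,
    ground-truth JSON) plus a manifest with sha256 checksums."""
    os.makedirs(outdir, exist_ok=True)
    data = simulate(config)
    txome = data.transcriptome
    files = {}

    def emit(name: str, writer) -> None:
        path = os.path.join(outdir, name)
        writer(path)
        files[name] = path

    emit("genome.fa", txome.write_fasta)
    emit("annotation.gtf", txome.write_gtf)
    emit("ground_truth.json", data.truth.to_json)
    emit("config.yaml", config.to_yaml)
    emit(
        "gene_counts.tsv",
        lambda p: data.gene_counts.to_csv(p, sep="\t", index_label="gene_id"),
    )
    for line in config.lines:
        emit(
            f"fpkm_input_{line}.tsv",
            lambda p, li=line: data.fpkm_input[li].to_csv(p, sep="\t", index_label="gene_id"),
        )
        emit(
            f"fpkm_ip_{line}.tsv",
            lambda p, li=line: data.fpkm_ip[li].to_csv(p, sep="\t", index_label="gene_id"),
        )
    for (line, rep, kind), track in data.tracks.items():
        emit(f"coverage_{line}_rep{rep}_{kind}.bedgraph", track.write_bedgraph)
    manifest = {}
    for name, path in files.items():
        with open(path, "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"config_seed": config.seed, "sha256": manifest}, fh, indent=1, sort_keys=True)
    files["manifest.json"] = os.path.join(outdir, "manifest.json")
    return files
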
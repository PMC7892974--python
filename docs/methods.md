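# Methods

This note documents the models and procedures implemented in `meripeak`,
the assumptions behind them, the simulator that the tests exercise them on,
and the design choices made where several reasonable options existed.

## Coordinate conventions and transcript segmentation

All coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted on read and BED output is written 0-based
half-open.  Metagene work is done in *spliced* coordinates: position 0 is
the 5′ end of the mature mRNA on either strand, and every spliced range
maps back to genomic exon pieces through the exon chain.

A coding transcript is tiled by five non-overlapping segments.  With s the
spliced position of the first CDS base and t one past the last:
5′UTR = [0, s−50), start-codon window = [s−50, s+50),
CDS = [s+50, t−50), stop-codon window = [t−50, t+50),
3′UTR = [t+50, L).  Segments truncate at transcript ends and, when the CDS
is shorter than 100 nt, the two codon windows meet at the CDS midpoint and
the CDS segment is empty.  These rules guarantee an exact cover: the five
segment lengths always sum to the spliced length, which the tests assert
against an independent per-base labeller on randomized transcript models.

Where a gene has several isoforms, metagene statistics use the isoform
with the longest CDS (ties: longest spliced length, then smallest
transcript id).  Non-coding transcripts are kept for peak assignment as a
single "exonic" segment but excluded from metagene profiles.  Whether the
original analysis segmented in spliced or genomic coordinates is not
documented anywhere we know of; spliced is the standard choice for
metagene plots and is used here.

## Peak calling

The caller is a deliberately simple, fully specified stand-in for a
MACS-style caller, not a re-implementation of one.  Coverage tracks store
per-base fragment-coverage counts; a window's count k is its per-base sum
(rounded to the nearest integer).  Windows of 100 nt slide in 50-nt steps.
The background for a window is

    λ_bg = max(input_count × N_IP/N_input,  N_IP · ℓ · w / G)

where N are fragment-equivalent library sizes, ℓ the fragment length
(100 nt), w the window size and G the effective background size — by
convention the transcriptome size, so the global floor equals the mean
transcriptome coverage per window.  Significance is the upper-tail Poisson
P(X ≥ k | λ_bg) < 10⁻⁵ together with k/λ_bg ≥ 2; significant windows
within 100 nt merge into a peak carrying the summit (argmax per-base IP
coverage), fold change (Σk / Σλ over member windows) and the minimum
window p.

Two properties follow and are tested: raising the p threshold can only add
peaks, and on enrichment-free tracks the fraction of windows passing
p < α stays below α (the max() background makes the test conservative).
A consequence of the transcriptome-sized floor worth knowing: sites on
transcripts expressed well below the transcriptome average are tested
against the *average* coverage, so even strong relative enrichment there
can fail the fold-change rule.  This mirrors how the convention behaves on
real data and bounds the attainable recall for weakly expressed genes.

The Poisson model treats per-base counts as independent given the local
rate; fragment-level autocorrelation of real coverage (adjacent bases
covered by the same fragment) is not modelled, and the simulator draws
coverage the same way, so window sums are genuinely Poisson under the
simulated null.  There is no duplicate filtering, fragment-model (d)
estimation, or broad-peak mode.

## Peak set algebra

The overlap fraction of two intervals is the overlap length divided by the
length of the *shorter* interval (making the ≥50 % relation symmetric);
bedtools-`-f`-style (fraction of the first interval) and reciprocal bases
are selectable.  Recurrent peaks are chains with at most one peak per
replicate, pairwise overlapping at ≥50 %, built greedily from each unused
peak in coordinate order and extended per replicate by the best-fraction
compatible candidate; each peak joins one chain.  The emitted peak is the
intersection of the members (union or first-replicate selectable), with
the median summit and mean fold change.  Between-line classification marks
a peak common when any peak of the other line overlaps it at ≥50 %
(greedy best-fraction, no exclusivity, so one peak may certify several) —
set-intersection semantics, conserving counts on each side.  Both
operations are verified against exhaustive brute-force enumeration on
randomized instances.

Peaks are assigned to transcripts by summit containment in an exon
(midpoint selectable); a peak therefore lands in exactly one metagene bin,
which keeps bin counts summing to the number of peaks used.  A
length-weighted mode that spreads a peak's unit mass over covered bins is
available by flag.

## Dynamic methylation and differential expression

Dynamic methylation is tested per common peak on IP fragment counts in the
peak interval, with three replicates per line.  Counts are scaled by
size factors, replicate-pooled per line, and the 2-cell table (line A sum,
line B sum) is tested against an equal split with the G statistic
G = 2 Σ O ln(O/E), df = 1.  Fold change uses normalized means with a
0.5-count pseudocount; a peak is called high/low (line B vs line A) at
|log₂FC| ≥ 1 and raw p < 0.05.  No multiple-testing correction enters the
decision — matching the thresholds the analysis is defined with — but a
BH-FDR column is emitted for users.

Size factors: the module's default is DESeq-style median-of-ratios over
the common peaks.  When changes are strongly one-directional (here ~71 %
of true changes go down in line B) that estimator's
"most-features-unchanged, changes-balanced" assumption fails and the
factors absorb part of the majority direction (~+0.13 log₂ bias measured
on the simulator, enough to produce a 21:1 false high:low imbalance).
The pipeline therefore normalizes by IP library depth, which is exact in
the simulator and is also what diffReps-style tools default to.  The
G-test on pooled counts ignores between-replicate overdispersion; the
fold-change gate is what keeps the realized null rate of *called* dynamic
peaks below 5 % under negative-binomial noise (dispersion 0.1), which the
type-I tests verify.  A negative-binomial exact test could replace the
G-test without interface changes.

Differential expression uses Welch's t on log₂(FPKM+1) across replicates
(variance floor 10⁻⁸; identical zero-variance vectors give p = 1), fold
change on means with a 1-FPKM pseudocount, same thresholds.  Genes absent
from one line count as zero there.

## Integration

FPKM = fragments × 10⁹ / (length × library size).  NNFPKM =
FPKM_IP / FPKM_INPUT measures per-gene m⁶A enrichment; it is undefined for
genes without input expression.  The expression–methylation correlation is
Pearson's r between log₂ FPKM_INPUT and log₂ NNFPKM, either at gene level
or after averaging within equal-count expression-ranked bins (default 50).
Binning averages out per-gene measurement noise and yields the
near-perfect |r| familiar from published versions of this plot; the
gene-level r is the honest per-gene coupling strength, and both are
reported.  Quadrants cross the aggregated per-gene dynamic direction
(genes whose peaks disagree are excluded and counted) with the expression
direction; shares are printed with round-half-up at the conventional
precisions (integer % within hyper/hypo, one decimal for overall shares).
Gene-set over-representation is an upper-tail hypergeometric test on
user-supplied GMT-style sets intersected with the analysis universe.

## The simulator

`meripeak.synthetic` generates the study the tests run on: one ~6 Mb
chromosome, 1,200 genes with 1–4 exons and 1–3 UTR-trimmed isoforms,
spliced lengths log-normal (median ≈ 2.8 kb, a realistic vertebrate mRNA
scale — important because shorter transcripts concentrate IP reads into
peaks and inflate the caller's background floor).  70 % of genes are
methylated, with 1/2/3/4 sites at probabilities 0.60/0.25/0.10/0.05
(≈1.6 sites per methylated transcript, ~85 % with one or two), placed with
segment weights 0.05/0.20/0.40/0.25/0.10 across
5′UTR/start/CDS/stop/3′UTR and ≥550 nt apart; 80 % of sites carry a GGACT
(RNA GGACU) motif written into the genome at the summit in transcript
orientation.

Coverage: input rate is uniform over a gene's exons, scaled by its
expression; the IP rate equals the input rate except at sites, where it is
multiplied by a flat-top profile (fold 8 over the central 151 nt, linear
taper over 50 nt to either side — the footprint of ~100-nt fragments over
a point modification), then rescaled so the IP library has the same depth
as the input (sequencing to target depth: enrichment redistributes reads).
Counts are gamma-Poisson: a per-gene, per-replicate gamma factor
(dispersion 0.1) shared between the IP and input libraries of that
replicate (they derive from the same fragmented RNA sample), one library
depth factor per replicate (±10 %), then independent per-base Poisson
draws.  Sharing the gamma factor within a replicate is what makes the
IP/input ratio estimable at all at these thresholds; the depth choice
(20 input fragments per 100-nt window at median expression) matches
deeply sequenced MeRIP libraries.

Line effects: 35 % of sites are dynamic, low in line B with probability
0.711.  The intensity split is asymmetric — the favoured line gets
fold × 7/3 ≈ 18.7 and the other fold ÷ 1.5 ≈ 5.3, a 3.5× ratio — and
symmetric between the high and low directions, so detection efficiency
does not bias the recovered low share.  Expression is log-linearly coupled
to the per-gene methylation load (default slope −0.5 with Gaussian noise),
and 12.5 % of dynamic genes additionally shift expression in line B,
concordant with their methylation direction with probability 0.93.

What the simulator does *not* model: fragment-level coverage
autocorrelation, positional coverage biases, multi-mapping, isoform
switching, and sequencing error.  Passing tests therefore demonstrate the
statistical machinery under a clean generative model, not performance on
real libraries.  One recovery asymmetry is intrinsic and worth noting:
hypo-down genes (methylation and expression both lower in B) have their
line-B site coverage suppressed twice over, often fail line-B peak
calling, and drop out of the common set — so quadrant recovery from raw
coverage under-represents hypo-down, a genuine property of the
common-peak-based procedure rather than a bug.

## Problem sizes and determinism

Default analyses run at 1,200 genes × 2 lines × 3 replicates × 2
libraries; the test suite uses this scale for the end-to-end statistical
checks and much smaller instances elsewhere, with every random draw seeded
(hypothesis properties derandomized).  All simulation randomness flows
from a single integer seed through `numpy`'s `SeedSequence`, making
fixtures byte-identical across runs; ground truth is stored independently
of the emitted files so tests never reverse-engineer outputs.

## Known limitations

- The caller's numerics make no attempt to match any particular MACS
  version or mode.
- The G-test is anti-conservative in isolation under overdispersion; it is
  the fold-change gate that controls the realized false-call rate (see
  above).  Users who need calibrated p-values per se should treat the
  emitted FDR column accordingly.
- Recall is intrinsically limited for sites on transcripts expressed well
  below the transcriptome mean (background-floor effect) and for the
  minor line of strongly dynamic sites.
- Gene-set testing takes user-supplied sets only; no ontology retrieval or
  redundancy reduction.
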
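# Methods

## Coordinate conventions and gene models

All internal coordinates are 0-based half-open. The TES is defined as the
final transcribed base (inclusive): on the plus strand `TES = end - 1`, and
the read-through window "TES to TES + 200 bp" is the half-open interval
`[end, end + 200)`. This makes window arithmetic identical to BED arithmetic
and leaves no ambiguity at either gene boundary. GTF input (1-based
inclusive) is shifted on load.

Transcripts on the same chromosome and strand that share an identical TSS
**or** an identical TES are collapsed transitively (union-find) into a single
transcription unit spanning the union of their extents, before any pausing
statistic is computed. The merged unit takes the lexicographically first
member id and the highest-priority member class
(RDH > snRNA > snoRNA > rRNA > protein_coding > other_noncoding); RDH ranks
first so a histone unit overlapping a host transcript keeps its focus class.

## Analysis windows

Per gene, five orientation-aware windows are derived (defaults in nt,
configurable via `WindowParams`):

| window | default | definition |
|--------|---------|------------|
| TSSr   | 150     | starts at the TSS |
| TESr   | 100     | ends at, and includes, the TES |
| GB     | —       | everything between TSSr and TESr |
| TSS200 | 200     | starts at the TSS (read-through denominator) |
| RT     | 200     | starts one base past the TES |

TSSr, GB and TESr tile `[TSS, TES]` exactly, with no gap or overlap. The
TESr and TSSr lengths are design choices: 3′ pausing concentrates within the
stem-loop region immediately upstream of the TES, so a window of roughly one
footprint-cluster width (100 nt) ending at the TES captures it; 150 nt is a
conventional promoter-proximal pause window. The gene body excludes both
pause windows so a pause peak can never inflate its own denominator. Genes
shorter than 150 nt, or whose gene body would be under 50 nt, are flagged
ineligible rather than silently shrunk; windows crossing contig edges are
clipped with a warning flag, never fatally (synthetic contigs are short).
Genes with windows overlapping neighbours in dense clusters are neither
clipped nor excluded.

## Pileup and normalization

Each accepted alignment (mapped, primary, MAPQ ≥ 10 by default) contributes
+1 at its 3′-most aligned base in read orientation: `end - 1` on the plus
strand, `start` on the minus strand. Soft-clipped bases are excluded — the
aligned end is reproducible from standard alignment fields. A `flip_strand`
flag inverts the recorded strand before the last-base rule is applied, for
library chemistries sequenced from the reverse complement. Raw track totals
always equal the accepted-read count.

Spike-in normalization: `coverage = aligned bases on spike contigs /
spike genome length`; the factor is `reference_coverage / coverage`, so
deeper libraries are scaled down. Aligned-base totals (not read counts) are
used, matching the genomic-coverage definition, and all accepted alignments
count (not 3′-end-collapsed reads). rRNA normalization (for α-amanitin
samples, where Pol II output itself collapses and the spike-free comparison
needs a Pol-I-insensitive denominator) is `1e6 / reads with 3′ end in the
rRNA interval`, default `chrUn_GL000220v1:105424-118780`. Tracks refuse to
be scaled twice.

## Pausing statistics

TPP and PPP are **density** ratios — window sum divided by window length,
TESr (or TSSr) over GB — with a pseudocount (default 1.0) added to the
denominator *count* before the density is formed. The density form keeps
indices comparable across the unequal window lengths and a uniform track
yields exactly 1.0; a raw-sum variant (`density=False`) is provided. The
pseudocount guarantees finiteness at silent gene bodies; recovery analyses
use pseudocount 0 so the estimator is unbiased.

The read-through ratio defaults to `RT / TSS200`; a gene-body denominator
(`mode="genebody"`) is selectable. Zero denominators make the ratio
undefined for that gene (dropped from summaries, not NaN-propagated). The
expression filter keeps genes with spike-normalized TSS200 signal **strictly
greater** than 10; the threshold's referent (normalized 3′-end counts in the
TSS-proximal window) and strictness are package decisions exposed in the
API. Class summaries (median, quartiles) cover eligible, filter-passing
genes only.

## Paired condition contrasts

Per-class contrasts use the two-sided Wilcoxon signed-rank test on per-gene
paired statistics. Zero differences are dropped (standard Wilcoxon
convention). For n ≤ 15 remaining pairs the p-value is computed by exhaustive
enumeration of all 2ⁿ sign assignments of the observed (tie-averaged)
absolute ranks — `p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))`, capped at 1 — which
remains exact under ties; above that, a normal approximation with continuity
correction and the standard tie-correction of the variance is used. All
differences zero yields p = 1.0 with a warning. No multiple-testing
correction is applied across classes (per-class p-values are reported
as such).

## Meta-gene profiles

Anchor-centered matrices (default: 500 nt each side of the anchor, 10 nt
bins) store minus-strand rows already flipped, so offset +x always means
downstream in transcript orientation. Profiles are either plain column
means or row-sum-normalized means (each gene's row divided by its total;
zero-total rows dropped with a reported count) — the generator's presets are
checked under both, and the normalization choice is exposed because neither
is canonical.

## Enrichment and locus windows

IP-style per-gene quantification: fragments are assigned to genes by the
midpoint of their aligned span against the whole gene span (a midpoint in
several overlapping spans counts for each — the correct behaviour inside
dense histone clusters); counts are CPM-normalized, then per-gene
`IP/input` (with a 1-CPM symmetric pseudocount) and `IP − input` are both
emitted, since different downstream displays use different forms. Locus-level
quantification sums a track strand-agnostically over fixed windows; the two
human RDH cluster definitions ship as presets
(`histone_cluster_1`: chr6 27,130,000–27,150,000 ∪ 27,801,000–27,903,000;
`histone_cluster_2`: chr1 149,780,000–149,890,000).

## Particle analysis

Particles are 8-connected components of pixels at or above a fixed,
user-supplied threshold with area ≥ `min_area` — the threshold is a required
input because a "clearly recognizable on the control" threshold is
inherently a judgement call. Centroids are intensity-weighted centers of
mass (sub-pixel). Anchor–partner association is mask overlap of ≥ 1 px by
default (the occupied-area reading of colocalization); a centroid-distance
criterion (default radius 0.5 µm) is provided for point-like loci. Per-anchor
occupied fraction is anchor pixels covered by any partner over anchor area.
Association frequencies are reported from both sides (anchors with ≥ 1
partner / total, and symmetrically). Averaged anchored images are means of
square crops centered at rounded anchor centroids, skipping (and counting)
anchors whose crop crosses the frame; the horizontal center line is emitted
as a profile per channel. The 2D kernel-density helper exists purely for
scatter-point coloring and produces no quantitative output.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions the rest of the package is validated under.

**Genome.** Two 300 kb host contigs each carry one cluster interval
(20–100 kb) holding half of the RDH-like genes, mirroring the two-cluster
organization of the human RDH genes; snRNA, snoRNA and protein-coding genes
are dispersed downstream of the cluster. A 50 kb spike contig emulates the
exogenous Drosophila genome and a 20 kb contig carries one Pol-I-like rRNA
unit insensitive to the α-amanitin preset. Gene lengths: RDH 400–800 nt,
snRNA/snoRNA 300–500 nt, protein-coding 1000–3000 nt. The snRNA/snoRNA range
is longer than real snRNA genes so every simulated gene supports the default
window geometry; this is a deliberate simplification — the generator
validates the measurement chain, not annotation edge cases.

**Reads.** Each gene's 3′-end positions follow a four-component mixture:
uniform over TSSr (weight `w5`), uniform over the gene body (`wgb`), a
discretized Gaussian centered `pause3_offset` = 35 nt upstream of the TES
with standard deviation `pause_width` = 10 nt truncated to the transcript
(`w3`; the stem-loop-proximal 3′ pause), and TES + geometric tail with mean
`rt_decay` = 50 nt (`rho`; read-through). Default WT weights
(`w5, w3, rho`): RDH (0.25, 0.35, 0.05), snRNA (0.25, 0.30, 0.05), snoRNA
(0.30, 0.20, 0.05), protein-coding (0.45, 0.03, 0.04), rRNA (0.05, 0, 0) —
strong 3′ pausing confined to the RDH/snRNA classes, promoter-proximal
pausing everywhere. Read lengths are uniform 25–50 nt ending at the 3′ end
(short run-on fragments; the length law is immaterial to 3′-end statistics).
Per-gene read counts are Poisson around the expected depth (default presets
use 2 000–20 000 reads/gene depending on the analysis). The spike-in
expectation is 10% of the WT genic total — emulating spike-in cells added at
10% of the sample cell number — and, being a per-cell addition, is never
rescaled by condition presets; `depth_factor` (sequencing depth) scales
everything.

**Condition presets.** `NELF_KD`: RDH `w3 → 0.5·w3`, snRNA `w3 → 0.8·w3`
(mild). `EAF1_mut`: RDH `w3 → 0.05·w3`, `rho → 2·rho` (pause collapse with
doubled read-through). `alpha_amanitin`: every non-rRNA gene's expected
reads × 0.1; the rRNA unit and spike-in untouched. The gene-body weight
absorbs the remainder so weights always sum to 1.

**Images.** Anchor blobs are Gaussians (σ = 1.5 px, amplitude 1000 over
background 10) at uniform random positions with a 12σ minimum separation.
Exactly `round(f · n_anchors)` randomly chosen anchors receive a partner
blob displaced by a vector of length uniform in [0, 2σ] (masks overlap);
free partner blobs land ≥ 10σ from every anchor. Pixels are Poisson draws
around background + signal (a noise-free mode exists for oracle tests). The
associated count is deterministic rather than Bernoulli-per-anchor so that
recovery tests measure the detection/association chain, not binomial
sampling noise. What the generator does **not** emulate: optical blur
correlations between channels, intensity heterogeneity between bodies,
clustered or nucleolus-excluded spatial patterns, z-structure. Passing
recovery tests therefore demonstrates correctness of the measurement chain
under the stated geometry, not robustness to real-microscopy artefacts.

**Reproducibility.** All randomness flows from one master seed through
named, CRC-keyed substreams (genome / reads / images / enrichment); the same
seed and configuration give byte-identical outputs. Alignments are emitted
coordinate-sorted; SAM/BAM export via pysam is provided.

## Problem sizes and numerical choices

Validation analyses run at desk scale by design: 10–40 genes per class,
500–20 000 reads per gene, 1024² image frames with 300 anchors — sizes at
which the statistical properties under test (index recovery within ±15%,
directional class shifts at p < 0.01, association-fraction recovery inside
the exact 99% binomial interval) are comfortably resolved. Index-recovery
experiments invert the mixture analytically
(`w3 = k·|TESr| / (k·|TESr| + |GB|)`, `w5 = rho = 0`) so the expected TPP at
pseudocount 0 equals the target k exactly. bedGraph export serializes values
with shortest-round-trip `repr`, making write-then-read exact. Minus-strand
bedGraph values are written negative by convention in the export layer only.

## Known limitations

* Exon structure, splicing and UTRs are not modelled; gene spans are single
  intervals.
* The expression-filter referent and the pausing-index window sizes are
  package decisions (exposed in configuration), not community standards.
* The simulator's read model has no mappability, duplication or base-quality
  structure; alignment-level artefacts are out of scope.
* Nuclei segmentation is assumed done upstream; images must be pre-masked.
* No multiple-testing correction across gene classes.
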
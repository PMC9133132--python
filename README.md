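# polpause

Quantification of RNA polymerase II pausing at transcript ends from PRO-seq
data, with companion tools for per-gene IP enrichment, fixed-window locus
signal, nuclear-body image quantification, and a ground-truthed synthetic-data
generator that exercises every stage at desk scale.

## The problem

PRO-seq maps the 3′ end of nascent RNA — the active position of engaged
RNA polymerase — at single-nucleotide resolution. At replication-dependent
histone (RDH) and snRNA genes, which produce non-polyadenylated transcripts,
Pol II pauses immediately upstream of the transcript end site (TES), over the
stem-loop region of the nascent RNA, and this 3′ pausing is coupled to
3′-end processing and transcription termination. When the pause is lost,
polymerase reads through past the TES.

`polpause` quantifies this phenomenology per gene:

* **TPP index** (TES-proximal pausing):
  `TPP = (signal(TESr) / |TESr|) / ((signal(GB) + c) / |GB|)`,
  the 3′-end signal density in a TES-proximal window (default 100 nt ending
  at the TES) over the gene-body density, with pseudocount `c` on the
  denominator count (default 1; a raw-sum variant is selectable).
* **PPP index** (promoter-proximal pausing): the same ratio with a
  TSS-proximal window (default 150 nt from the TSS).
* **Read-through ratio**:
  `RT = signal(TES+1 .. TES+200) / signal(TSS .. TSS+200)`
  (a gene-body denominator is selectable), computed over genes whose
  spike-normalized TSS-proximal signal exceeds a 10-count expression filter.
* **Normalization**: scaling by the genomic coverage of a Drosophila spike-in,
  or per million reads in a Pol-I rRNA interval
  (`chrUn_GL000220v1:105424-118780`) for α-amanitin experiments.
* **Condition contrasts**: per-class paired two-sided Wilcoxon signed-rank
  tests (exact 2ⁿ sign-flip enumeration for n ≤ 15, normal approximation with
  continuity and tie correction above).
* **Meta-gene profiles** around TSS/TES, orientation-flipped for minus-strand
  genes.
* **Particle analysis** for two-channel nuclear-body images (e.g.
  NPAT-marked histone locus bodies vs Coilin-marked Cajal bodies):
  fixed-threshold 8-connected particle detection, mask-overlap association,
  occupied-area fractions, inter-centroid distances in µm, and averaged
  anchor-centered crops.

Transcripts sharing a TSS or a TES on the same strand are collapsed
transitively into one transcription unit before any statistic is computed.
All genomic coordinates are 0-based half-open; the TES is the final
transcribed base.

## Worked example

Simulate a small genome with two RDH gene clusters under the wild-type and
termination-defective (`EAF1_mut`) presets, and contrast RDH pausing:

```python
import numpy as np
from polpause import simulate as sim
from polpause.annotation import define_regions_for
from polpause.signal import three_prime_pileup
from polpause.pausing import compute_pausing_records, compare_conditions

cfg = sim.GenomeConfig(n_rdh=30, n_snrna=20, n_snorna=10, n_coding=10)
genome = sim.simulate_genome(cfg, seed=303)
regions = define_regions_for(genome.genes, contig_lengths=genome.contig_lengths)

tables = {}
for cond, seed in (("WT", 303), ("EAF1_mut", 304)):
    truth = sim.default_truth(genome, cond, reads_per_gene=20_000, seed=303)
    track = three_prime_pileup(sim.simulate_proseq(genome, truth, seed=seed))
    tables[cond] = compute_pausing_records(track, genome.genes, regions,
                                           pseudocount=0.0)

def rdh(recs, stat):
    return {r.gene_id: getattr(r, stat) for r in recs
            if r.gene_class == "RDH" and getattr(r, stat) is not None}

cmp = compare_conditions(rdh(tables["WT"], "tpp_index"),
                         rdh(tables["EAF1_mut"], "tpp_index"), "RDH")
print(f"RDH TPP median WT={cmp.median_a:.2f}  mut={cmp.median_b:.2f}  "
      f"p={cmp.p_value:.2e}  (n={cmp.n_pairs})")
```

prints

```
RDH TPP median WT=3.38  mut=0.09  p=1.83e-06  (n=30)
```

i.e. the median TES-proximal pausing index of the 30 RDH-like genes collapses
roughly 40-fold in the mutant (whose ground truth reduces the TES-pause
mixture weight 20-fold and doubles read-through), and the paired signed-rank
test calls the shift highly significant.

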
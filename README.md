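# loopbench

**Evaluation toolkit for ChIA-PET and HiChIP chromatin-loop calls.**

Targeted chromatin conformation capture assays (ChIA-PET, HiChIP, PLAC-seq)
map the long-range contacts — enhancer–promoter loops, CTCF/cohesin loops —
that a protein of interest mediates. A dozen computational pipelines call
loops from such data, peak-based (seeded on ChIP-seq-style peaks) and
cluster-based (direct density clustering of paired-end tags), and they
disagree substantially. `loopbench` gives tool users and method developers
a uniform way to score any loop-call set, plus the synthetic-data
generators needed to test the whole pipeline with known ground truth and
no external downloads.

## Metrics

For a loop set with loops *i*, anchors (*s1*, *e1*) and (*s2*, *e2*), PET
count *C*ⁱ:

* **UV Rate** — pre-processing quality: the fraction of paired-end tags
  (PETs) that are *U*niquely mapped (both ends MAPQ ≥ 30), non-duplicate
  and *V*alid (inter-ligation; self-ligation products below an 8 kb span
  cutoff are uninformative).
* **PC (peak co-occupancy)** — anchor reliability of peak-based callers.
  Anchors are merged at 90% reciprocal overlap; each anchor with ≥ 1 bp of
  ChIP-seq peak overlap contributes
  max{ L(oᵢ)/L(pᵢ), L(oᵢ)/L(aᵢ) } for its best-overlapping peak. Both the
  literal form N_A·Σᵢ termᵢ / N and the bounded form Σᵢ termᵢ / N are
  reported.
* **ES (enrichment score)** — anchor reliability of cluster-based callers:
  ESᵢ = *C*ⁱ / *P*ₙⁱ, where *P*ₙⁱ = min over the two anchors of the PET
  count in the flanking windows of mean anchor length on each side. A true
  loop is a local maximum of PET enrichment, so ESᵢ < 1 flags an invalid
  call. The global ES aggregates Σ*C*ⁱ/Σ*P*ₙⁱ per chromosome with a
  coverage correction α = C/Cⱼ (C = LN/G, the genome-wide PET coverage).
* **ACC** — loop accuracy, ACC = (TP+TN)/(TP+TN+FP+FN), against a
  gold-standard "true" set and three matched sampled "false" sets (FP and
  TN are means over the three replicates).
* **AR (activation rate)** — functionality of significant loops (≥ 3 PETs
  for ChIA-PET, ≥ 8 for HiChIP, p ≤ 0.05 / FDR ≤ 0.05 where reported):
  loops with enhancer/promoter-annotated anchors are active when their
  anchors overlap active histone marks (H3K27ac, H3K4me1, H3K4me3) more
  than repressive ones (H3K27me3); AR is the active fraction.
* **Resolution levels** — the distribution of inter-anchor distances over
  d ≤ 10 kb, 10–100 kb and 100 kb–1 Mb.

Gold-standard sets are built by intersecting candidate loops with verified
contacts (eQTL variant–gene pairs with a 5 kb variant flank,
CRISPR-validated enhancer–gene pairs, strong Hi-C loops at FDR ≤ 0.01 and
counts ≥ 5) and keeping candidates whose contact coverage is significant
under a genome-wide permutation null (p < 0.05 and BH-FDR < 0.05).

The ChIA-PET simulator draws bin-pair counts n_ij ~ Pois(a/(1+δ)) with
δ = |i−j| in 5 kb bin units; the HiChIP simulator filters Hi-C anchor
pairs by ChIP-seq coverage at a 50% threshold. See `docs/methods.md` for
modelling details and design decisions.

## Worked example

Generate a synthetic input bundle with known ground truth (UV Rate 0.4,
20 gold loops planted among 100 candidates, a 50/30/20 active/inactive/
other split) and evaluate the candidate set against it:

```bash
loopbench fixture -o bundle --seed 1
loopbench goldset \
    --candidates bundle/candidates.bedpe --contacts bundle/contacts.bedpe \
    --sizes bundle/genome.chrom.sizes --seed 1 -o truth.bedpe
loopbench evaluate \
    --loops bundle/candidates.bedpe --protocol chiapet --method-class peak \
    --label demo-caller --sizes bundle/genome.chrom.sizes \
    --peaks bundle/chip_peaks.bed --pets bundle/pets.tsv \
    --enhancers bundle/enhancers.bed --promoters bundle/promoters.bed \
    --active-mark bundle/h3k27ac.bed --active-mark bundle/h3k4me.bed \
    --repressive-mark bundle/h3k27me3.bed \
    --truth truth.bedpe --mask-bed bundle/tss.bed --mask-bed bundle/enhancers.bed \
    --seed 1 -o out
```

The log and `out/report.tsv` show:

```
UV Rate 0.4000 over 1000 PETs
merged 200 anchors into 200 at 90% reciprocal overlap
PC literal 200.0000, normalized 1.0000
100 of 100 loops pass the significance pre-filter
ACC 1.0000 (TP 20.0 FP 0.0 TN 20.0 FN 0.0)
AR 0.5000 (50 active / 100 classified)
```

Every number is the planted value: 40% of PETs were written UV, every
anchor coincides with a ChIP peak (PC normalized 1.0; the literal form is
N_A = 200 times larger), all 20 planted gold loops are detected with no
false-set hits (ACC 1.0), and exactly half of the loops carry active
marks (AR 0.5). `loopbench compare` then assembles several such reports
into a method × metric matrix with min-max-scaled columns;
`loopbench goldset`, `falseset` and `simulate {chiapet,hichip}` expose the
remaining building blocks.

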
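# atcmap

Geomapping of **amplification-associated transcription coupling (ATC)**
regions in tumor cohorts, definition of **dense ERα binding hubs** from
consensus ChIP-seq peaks, and quantification of inter-/intra-chromosomal
rearrangement enrichment between the two — with a fully synthetic cohort
generator that plants known ground truth for every stage.

## Who this is for

Cancer genomicists studying co-amplified, co-transcribed gene neighborhoods
(candidate chromothripsis hotspots) and their long-range contacts with
estrogen-receptor binding territory. Real cohorts of this kind (matched
expression + segmented copy number + WGS rearrangement calls) are usually
controlled-access; the package ships a generator that emulates their
statistical structure so methods can be developed and validated openly.

## The method

**Two-step geomapping.** For each annotated gene *g*, the per-sample Pearson
correlation

&nbsp;&nbsp;&nbsp;&nbsp;*r(g)* = corr( log₂(expr(g) + 1), CN(seg(g)) )

is computed between log-transformed expression and the copy-number value of
the 100-kb genome segment containing the gene midpoint (0 = diploid, > 0 =
amplified). Genes with *r* ≥ 0.6 (inclusive) are **ATC loci**. Per
chromosome, ATC-locus start positions are then clustered with **exact
optimal univariate k-means** (dynamic programming over sorted positions —
the global WCSS optimum, not a Lloyd local optimum), with the number of
clusters selected automatically. Each cluster is a candidate **ATC region**,
retained when it (1) contains ≥ 15 genes, (2) spans < 20 Mb, and (3) has a
positional kernel-density estimate > 1 × 10⁻⁸ per bp.

**ERα hubs.** Consensus binding sites are the maximal intervals covered
simultaneously by peaks from three cell-line ChIP-seq peak sets (strict
base-pair three-way intersection). Site midpoints are clustered per
chromosome with the same engine; each cluster spans a **hub**.

**Rearrangement links.** BreakDancer-style or BEDPE paired-breakpoint calls
are kept when confidence score > 80 (strict), classified inter-/intra-
chromosomal, and counted against bait regions: an event contributes to a
bait if either breakpoint falls inside it, with the partner breakpoint
assigned to a 1-Mb genome bin (Circos-style links) or to an enclosing hub.
Group contrasts (e.g. ER⁺ vs ER⁻ per-sample counts) use the Mann-Whitney U
test; survival stratification uses the cumulative normalized expression
score (summed per-gene z-scores) with a median-split log-rank test.

## Worked example

Generate a synthetic cohort (200 samples, 1,000 genes on two chromosomes,
three planted dosage-coupled regions, ten planted hubs) and run the whole
pipeline:

```sh
atcmap simulate --seed 1 --out demo/sim
atcmap map-atc --annotation demo/sim/annotation.tsv \
    --expression demo/sim/expression.tsv \
    --copy-number demo/sim/copy_number.tsv \
    --metadata demo/sim/metadata.tsv --out demo/atc
```

prints

```
ATC geomapping results
======================================================
samples:              200
genes screened:       1000
ATC loci (r >= 0.6): 82
ATC regions retained: 3
------------------------------------------------------
  A  chr1:10,220,198-17,604,204  genes=25  span=7.38 Mb  density=2.12e-08
  B  chr1:45,158,383-52,846,090  genes=28  span=7.69 Mb  density=2.36e-08
  C  chr2:20,316,348-27,339,208  genes=29  span=7.02 Mb  density=1.73e-07
```

— 82 of the 90 planted coupled genes pass the r ≥ 0.6 screen and aggregate
into exactly the three planted regions (coordinates are reported 1-based
inclusive). Continuing:

```sh
atcmap map-hubs --peaks demo/sim/peaks_lineA.bed demo/sim/peaks_lineB.bed \
    demo/sim/peaks_lineC.bed --out demo/hubs
# 80 common sites -> 10 hubs

atcmap count-rearrangements --events demo/sim/rearrangements.breakdancer.tsv \
    --baits demo/atc/atc_regions.tsv --hubs demo/hubs/hubs.bed \
    --metadata demo/sim/metadata.tsv --out demo/links
# events after score > 80 filter: 2264
# link incidences: 1525
# Mann-Whitney U (negative n=74 vs positive n=126): U=29, p=6.992e-32

atcmap concordance --expression demo/sim/expression.tsv \
    --genes demo/atc/atc_genes.tsv --out demo/conc
atcmap survival --scores demo/conc/atc_scores.tsv \
    --metadata demo/sim/metadata.tsv --out demo/surv
# log-rank high (n=100) vs low (n=100): chi2=11.7706, p=0.0006017
```

The ER⁺ excess of rearrangements (the generator plants a 3× event rate and
70% hub targeting in ER⁺ samples) and the survival penalty of a high ATC
score (planted hazard coupling) are both recovered. The same steps are
available as library calls; `AtcGeomapper(cohort, annotation).fit()` returns
a results object with the gene table, the regions and a `summary()`.

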
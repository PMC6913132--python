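# m6aforest

Prediction of N6-methyladenosine (m⁶A) sites at single-coordinate,
isoform-level resolution from nanopore direct-RNA-sequencing signal tracks.

## The problem

Direct RNA sequencing preserves base modifications, but per-read calling is
defeated by the platform's high single-base error rate. Modification-detection
preprocessing (e.g. Tombo's de novo mode) instead emits, for every reference
position, the **fraction-modified value** — the fraction of reads whose
current deviates from the canonical model — as a wiggle track, plus a read
coverage bedgraph. These aggregate statistics hover around 0.5 even at
unmodified positions, so the raw tracks cannot be thresholded directly.

`m6aforest` turns those tracks into m⁶A calls by exploiting two facts:

1. m⁶A is deposited almost exclusively inside the degenerate 5-mer consensus
   **DRACH** (D = A/G/T, R = A/G, H = A/C/T; 18 concrete 5-mers), with the
   methylated A at the center;
2. methylation leaves a reproducible spike in the fraction-modified signal at
   the bases just 5′ of the motif, spread over the pore's ~5-base reading
   context.

For every DRACH-centered adenosine with coverage ≥ 5, the fraction-modified
values at offsets −10…+10 from the A form a 21-value feature vector. One
random forest per 5-mer (the pore responds differently to each sequence
context) classifies the vector. Training positives come from an external
single-base truth set (e.g. antibody-CLIP-derived m⁶A maps); an equal number
of non-truth sites balances the training set; each forest is fit 10 times on
resampled negatives and the fit with the highest training accuracy is kept.
A motif's model ships only if it clears strict quality thresholds
(detection rate > 0.7, precision > 0.85, ROC AUC > 0.67); on real data the
qualifying motifs are AGACT, GGACA, GGACC and GGACT.

Two downstream analyses are included:

* **Perturbation sensitivity** — a site is sensitive to writer depletion
  (METTL3 knockdown) or eraser overexpression (ALKBH5) when its mean
  fraction-modified value over the peak offsets (−5, −4, −3 from the A) is
  strictly greater in the baseline condition; comparing sensitive fractions
  between predicted classes validates calls without antibodies.
* **Isoform-level classification** — calls made against a cDNA reference are
  lifted through GTF exon structures to genomic coordinates; genomic
  positions covered by ≥ 2 isoforms are classified *never*, *consistently*,
  or *isoform-specifically* methylated.

## Worked example

The package ships a synthetic-data generator that emulates the track
phenomenology (baseline fraction ≈ 0.5, +0.3 spike at the peak offsets of
methylated sites, Gaussian noise sd 0.1, truth set covering only 70% of the
true sites):

```bash
m6aforest simulate --seed 1 --out fixtures/demo
m6aforest train \
    --signal fixtures/demo/wt.wig --coverage fixtures/demo/wt.bedgraph \
    --reference fixtures/demo/reference.fa --truth fixtures/demo/truth.bed \
    --motifs default4 --seed 1 --out models/
m6aforest predict \
    --signal fixtures/demo/wt.wig --coverage fixtures/demo/wt.bedgraph \
    --reference fixtures/demo/reference.fa --models models/ --out calls.bed
```

`train` prints one row per motif (here for the default 1000-site fixture,
seed 1):

```
motif  training_accuracy  clip_detection_rate  precision   roc_auc  n_train_pos  n_test_pos  n_test_neg
AGACT                1.0             1.000000   0.595238  0.924731           58          25          93
GGACA                1.0             0.961538   0.581395  0.907580           61          26         103
GGACC                1.0             1.000000   0.549020  0.881393           66          28          81
GGACT                1.0             0.846154   0.392857  0.843600           60          26         128
```

`clip_detection_rate` is the fraction of held-out truth-labeled sites called
methylated. The low apparent `precision` and `roc_auc` are expected: the
truth set deliberately misses 30% of true sites, so many "false" positives
are real discoveries — scored against the generator's complete ground truth
the held-out ROC AUC is 0.998. `calls.bed` contains one BED6 line per
candidate site, e.g. `seq003 110 111 GGACT:m6A 900 +` (score =
1000 × predicted probability).

`m6aforest sensitivity` compares a wild-type/perturbed track pair and
reports the sensitive fraction per class; `m6aforest isoform` lifts
transcript-space calls through a GTF and classifies shared genomic sites.

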
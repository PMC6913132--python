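# Methods

## Signal model and assumptions

The classifier operates on per-position *fraction-modified* tracks: for each
reference base, the fraction of reads whose nanopore current deviates from
the canonical k-mer model. Two empirical properties motivate the design:

* the statistic is noisy — it averages ≈ 0.5 across windows even at
  unmodified positions, so no single-position threshold separates classes;
* methylation produces a localized elevation ("peak") in the statistic at
  the bases immediately 5′ of the DRACH motif, smeared over the pore's
  ~5-base reading context.

A site is therefore represented by the ordered fraction values at offsets
−flank…+flank around the candidate A (default flank 10 → 21 values,
transcript-sense 5′→3′), and classification is left to a random forest that
can learn the peak shape per sequence context. One forest is trained per
resolved DRACH 5-mer because pore current response is k-mer specific; the
fully expanded consensus [AGT][AG]AC[ACT] yields exactly 18 motifs.

## Candidate enumeration and filtering

All DRACH occurrences are enumerated on the reference (plus strand for cDNA
references; optionally both strands for genomic ones — annotation-strand
restriction is the caller's choice). Overlapping occurrences are independent
candidates; any N inside the 5-mer disqualifies it, since it cannot be
assigned to one of the 18 models. A window is retained iff

* read coverage at the central A ≥ `min_coverage` (default 5 reads; the
  deviation statistic is unreliable at low coverage), and
* a fraction value exists at *every* window offset. Track positions that are
  absent are treated as missing, never as 0.0 — no signal was measured
  there — and missing values are never imputed: the forest needs complete
  fixed-length vectors and imputation would fabricate signal at exactly the
  positions that carry the class information. Windows running past a
  reference end drop under the same rule.

The coverage filter applies at the central A only; the completeness
requirement already guards the flanks. Dropped windows are tallied by reason
(`low_coverage`, `no_coverage`, `incomplete_signal`) in a per-run report.

## Training protocol

Truth labels come from a single-base interval set (BED); a window is
positive iff its central A lies inside an interval on the same reference
(strand-aware when the intervals carry strands). Per motif:

1. positives are partitioned once into round(0.7·n) training / rest test;
2. an equal number of negatives is sampled without replacement for training
   (balanced training set); every remaining negative goes to the test set;
3. ten forests are fit (100 trees, unlimited depth, `n_jobs=1`), run *i*
   resampling the negative training subset and seeding its forest with
   `seed + i`; the forest with the highest training accuracy is kept, ties
   to the lowest run index.

Fixing the positive partition across the ten runs keeps the test positives
identical, so run accuracies are comparable and the held-out positives are
never seen by any run. All sampling flows from a single integer seed;
training is bit-reproducible, and persisted model files (joblib payload
carrying the classifier, motif, flank, hyperparameters, metrics and a format
version) are byte-identical across repeated saves. Loading a model whose
flank differs from the prediction request is an error — silent feature-shape
mismatch is worse than a crash.

### Metrics and qualification

Because the truth set is incomplete (antibody-based maps miss real sites),
pooled test metrics understate performance: unlabeled true sites score as
false positives. The headline metric is therefore the **CLIP detection
rate** — the fraction of held-out truth-labeled sites called positive at the
0.5 probability threshold. Precision and ROC AUC over the pooled test set
are still computed and gate deployment: a motif's model qualifies only when
detection rate > 0.7, precision > 0.85 and ROC AUC > 0.67, all strict. The
shipped default whitelist is the four motifs that qualify on real data
(AGACT, GGACA, GGACC, GGACT).

Any evaluation against an *external* truth source (e.g. the synthetic
generator's manifest) is restricted to held-out windows
(`pipeline.held_out_predictions`): forests interpolate their training
windows almost perfectly, so including them leaks training labels and
inflates the score.

## Perturbation sensitivity

"Peak positions" default to offsets −5, −4, −3 from the central A — the
three bases immediately 5′ of the motif's first base; the offsets are
configurable per run since the peak location is an empirical observation. A
site is *sensitive* when its mean fraction value over the peak offsets is
strictly greater in the baseline than in the perturbed condition; exact ties
are not sensitive, making the relation antisymmetric. Sites surviving the
coverage filter in only one condition are excluded from the fractions and
counted. An empty prediction class reports an undefined fraction, not 0.
Under a null perturbation each site is a fair coin, so class fractions
concentrate at 0.5 with binomial error — a property the tests exploit.

## Isoform-level classification

Exon structures are read from a GTF (1-based closed intervals converted to
0-based half-open). Transcript offsets are lifted to genomic coordinates by
walking exons 5′→3′; only the central A is lifted, and windows whose ±flank
span crosses an exon junction are flagged (their signal context differs
from the genomic context) rather than dropped. Genomic positions are grouped
by (chromosome, position, strand); motif identity may differ across isoforms
at junctions and is not required to match. Positions covered by ≥ 2 isoforms
are classified `never` / `consistent` / `isoform_specific`; the three
categories partition the shared positions. The gene summary counts genes
with ≥ 1 m⁶A call and genes owning ≥ 1 isoform-specific shared site.
Transcripts present in the calls but absent from the GTF are reported and
skipped loudly — a cDNA reference and annotation must come from the same
release.

## Synthetic data generator

`synthetic.generate_fixture` emulates the statistical structure above:

| parameter | default | meaning |
| --- | --- | --- |
| `baseline_mean` | 0.5 | fraction-modified level at unmodified positions |
| `peak_delta` | 0.3 | spike added at peak offsets of methylated sites |
| `noise_sd` | 0.1 | Gaussian noise sd, values clipped to [0, 1] |
| `peak_offsets` | (−5, −4, −3) | where the spike is planted |
| `coverage_min/max` | 5 / 50 | per-position uniform read counts |
| `truth_label_fraction` | 0.7 | share of methylated sites in the truth BED |
| `perturbation_attenuation` | 1.0 | 1 = peak fully removed; 0 = null redraw |
| `n_methylated_sites` / decoys | 500 / 500 | planted DRACH sites per data set |
| `motifs` | the four qualifying 5-mers | planted motif alphabet |

Motifs are planted at positions ≥ 2·flank+5 apart (no window cross-talk) and
away from sequence ends; the random background is then iteratively scrubbed
of accidental DRACH occurrences, so the scanner finds exactly the planted
sites and every candidate has known status in the manifest. The truth BED
deliberately omits 30% of methylated sites, reproducing the
incomplete-truth-set regime the classifier faces on real data: recovering
those unlabeled sites (held-out ROC AUC vs the manifest ≈ 0.99 at defaults)
is the generator's central validation loop.

Noise is Gaussian with clipping rather than Beta — the simplest model
matching "mean ≈ 0.5 with tunable spread"; no distributional form is claimed
for real tracks. The generator does **not** simulate raw current,
basecalling error, read-length effects, per-read dropout, coverage decay
along transcripts, or correlated noise between neighboring positions.
Passing tests on these fixtures demonstrates the pipeline's correctness and
its statistical behavior under the assumed signal model, not performance on
real nanopore runs.

## Numerical and design choices

* Coordinates are 0-based internally; conversion happens only at file
  boundaries (wiggle is 1-based; bedgraph/BED are 0-based half-open).
* Overlapping bedgraph intervals are rejected, not summed: coverage
  emitters produce disjoint intervals, so overlap means corruption.
* The window is flank = 10 each side of the A (21 values), configurable;
  call threshold is 0.5, the natural forest majority vote.
* The problem sizes used by the test suite and the reproduction script
  (500+500 sites for recovery, 200+200 for sensitivity, 10 replicate seeds)
  give binomial/AUC standard errors comfortably inside the asserted bands.
* U is normalized to T on input; motifs are handled in DNA form throughout.

## Limitations

* Site-level only: the aggregate statistic cannot say what fraction of
  molecules is methylated at a site (per-read stoichiometry is out of
  scope).
* Non-DRACH m⁶A sites and other modifications are invisible by design.
* Real-data accuracy depends on the upstream preprocessing (aligner
  splice-awareness, resquiggle quality); the package starts at the
  wiggle/bedgraph boundary.
* Junction-spanning windows are flagged but still classified from their
  transcript-space signal.
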
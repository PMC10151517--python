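# Methods

## Problem and model

`epilink` treats enhancer–promoter interaction (EPI) prediction as binary
classification of (element, TSS) pairs. The working hypothesis is that a
small set of epigenomic measurements carries most of the signal: open
chromatin (ATAC-seq) and H3K27ac mark active elements, cohesin (RAD21)
binding marks loop anchors, and contact probability decays with genomic
distance. Each pair is represented by binned signal over two fixed-width
windows plus the distance, and a tree ensemble learns the mapping to the
interaction label.

## Coordinate conventions

All intervals are 0-based, half-open (the BED/bigWig convention); 1-based
inputs are converted at the reader boundary (`--tss-one-based`). Window
midpoints use floor division, which is deterministic for odd lengths.

- Enhancer window: `[mid − 1000, mid + 1000)` around the element midpoint;
  length exactly 2 000 bp, unstranded.
- Promoter window: 2 000 bp upstream to 500 bp downstream of the TSS;
  length exactly 2 500 bp. "Upstream" is defined by the annotated strand —
  on the minus strand the window is the mirror image about the TSS.
  Strand-awareness is the package's design choice: upstream is only
  meaningful relative to transcription direction.
- Windows crossing a chromosome edge are **rejected** (the pair is dropped
  and counted in the resolution report), never truncated: truncation would
  change the bin count and silently corrupt the fixed matrix geometry.
- Distance = |mid(enhancer) − mid(promoter)|, raw unsigned bp, no
  transform. Trans-chromosomal pairs are out of scope.

## Pair filtering

Two label-level filters run before resolution, in order: exact duplicate
(element, TSS, label) triples collapse to one; any (element, TSS) key
observed with *both* labels is removed entirely. The second rule is this
package's operational definition of an "ambiguous" pair — it is the only
label ambiguity expressible in the input schema — and the count removed is
reported so users can audit it. The filter is idempotent and
order-preserving.

A TSS table must be pre-collapsed to one row per identifier; the loader
errors on duplicates rather than guessing a canonical TSS for a gene.

## Feature extraction

Per-bin value = arithmetic mean of per-base signal with absent bases
counted as 0. Mean-with-zero-fill is the standard behaviour of bigWig
matrix tools and is the only statistic under which "no data" and "zero
signal" agree. Bins are 50 bp; 40 per enhancer window, 50 per promoter
window. On minus-strand windows the bin order is reversed so bin 0 is
always the 5′-most position relative to the element ("bin 1 = far
upstream" keeps its meaning); `strand_aware=False` disables this.

Column order is frozen: for each track in the configured order (default
ATAC, H3K27ac, RAD21) the 40 enhancer bins; then for each track the 50
promoter bins; then distance — 271 columns. Any fixed order is equivalent
for tree ensembles, but persistence and cross-cell-line transfer need one
canonical schema; a SHA-256-derived hash of the schema travels with every
matrix and model, and transfer refuses mismatched hashes.

The extractor supports any number of tracks (N tracks → 90·N + 1
columns); three is simply the default configuration.

## Classifiers and evaluation

- Random forest: 100 trees, otherwise scikit-learn defaults.
- AdaBoost: scikit-learn defaults with the shared seed (its
  hyperparameters are deliberately left at library defaults and recorded
  in the run manifest).
- GBDT: 100 estimators, learning rate 0.1, subsample 1.

Class imbalance is left untouched — no weights, no resampling — matching
the benchmark's fixed 1:4 design. Thresholded metrics (Sn, Sp, precision,
Acc) use a 0.5 probability cut-off, exposed as `--threshold`. AUC is the
trapezoidal ROC area (equivalently the tie-aware Mann–Whitney statistic);
AUPRC uses step-wise rectangular integration, which avoids the optimistic
bias of trapezoidal PR interpolation. Both are verified in the test suite
against exhaustive pair-counting / exhaustive-threshold oracles.

Model assessment is ten-fold stratified cross-validation on the training
split; the reported model is then refit on the entire training split and
scored once on the held-out 20 %. `split_mode="whole"` instead trains on
all pairs — the configuration used when the test set is a different cell
line. The 80/20 split is random per class under a stored seed (floor on
the train side), written out as a manifest of pair IDs so it is exactly
reconstructible.

## Synthetic data generator

The generator emulates the statistical structure the predictor relies on:

- **Planted enrichment.** Every track gains `enrichment_effect` signal
  units across both anchor windows of every interacting pair. An anchor
  shared between a positive and a negative pair keeps its enrichment —
  realistic leakage: an active enhancer contacts one promoter but not
  another, so element-level signal alone cannot separate such negatives.
- **Distance decay.** Positive pairs are drawn with probability
  ∝ exp(−d/`distance_decay`) (default scale 50 kb, a typical contact
  range); negatives are uniform over the remaining same-chromosome
  combinations. Positive and negative keys never overlap, so the
  ambiguity filter is a no-op on generated data by construction.
- **Noise.** Per-base signal is `max(0, background + noise)` (coverage is
  non-negative) plus the planted effect. Noise is drawn once per
  `noise_block` bp (default 50, the sequencing-fragment scale) and held
  constant within the block: real coverage fluctuates at fragment
  resolution, not independently per base. This matters quantitatively —
  with independent per-base noise, 50-bp bin averaging would shrink the
  noise by √50 and make even small planted effects trivially detectable;
  block noise keeps the bin-level signal-to-noise ratio equal to
  `enrichment_effect / noise_sd`, so the effect size is a meaningful dial.
  `noise_block=1` recovers independent noise.
- **Sparsity.** Defaults place 300 candidate elements and 300 TSSs across
  two 1-Mb chromosomes for 100 positive pairs (1:4 ratio), so most
  elements anchor no true interaction and most negative pairs touch at
  least one unenriched anchor — the sparse regime of real benchmarks. With
  too few elements, anchor reuse makes nearly every negative carry
  enrichment on both anchors and the planted contrast disappears.

Elements are placed uniformly with a minimum separation (700 bp, so
elements never overlap) and a 3-kb edge margin so no generated window is
boundary-rejected. One root RNG seeded from `SyntheticConfig.seed` drives
placement, pair sampling and track noise in a fixed order; identical
configs produce byte-identical files (the manifest stores paths relative
to its own directory for this reason).

What the generator does **not** emulate: peak shapes (enrichment is a
flat plateau), replicate structure, mappability artifacts, cross-track
correlation beyond the shared planted effect, chromatin-domain structure,
and any sequence content. Passing recovery tests therefore demonstrates
that the pipeline's plumbing, geometry and learning machinery are sound —
not that the feature set attains any particular accuracy on real data.

## Numerical and scale choices

- bigWig stores float32; tests generate ground-truth arrays quantised to
  float32 so file and oracle see identical values, and extraction is
  compared to a per-base brute-force average at 1e−9 relative tolerance.
- Test-suite and acceptance problem sizes (50–100 positives, 0.2–1 Mb
  chromosomes) keep a full pipeline run in seconds while leaving all
  planted contrasts detectable; the effect-size monotonicity experiment
  uses 5 seeds × 4 effect sizes at 50 positives each.
- The permutation null shuffles test labels 100 times against fixed
  scores; the observed AUC is compared to the whole null distribution.
- Degenerate inputs fail loudly: single-class training sets, windows not
  divisible by the bin width, chromosomes missing from a track, duplicate
  annotation IDs with conflicting coordinates, and labels outside {0, 1}
  all raise immediately with the offending record named.

## Known limitations

- "Ambiguous pair" handling is a schema-level definition; benchmarks with
  richer provenance may define ambiguity differently upstream.
- The random per-class split is one of several defensible protocols;
  chromosome-held-out splits (which control for genomic proximity
  leakage) are not implemented.
- No cross-cell-line signal normalisation is applied; transfer quality on
  real data depends on comparable track processing depth.
- AdaBoost hyperparameters are library defaults; no hyperparameter search
  is performed for any model.
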
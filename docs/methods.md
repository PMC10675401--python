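# Methods

`locfuse` implements a dual-signal protocol for predicting the subcellular
location of a protein among four compartments — endoplasmic reticulum (ER),
Golgi apparatus, cytosol, and nucleoplasm — from (a) its amino-acid sequence
plus an evolutionary profile and (b) an immunohistochemistry (IHC)
micrograph in which a DAB chromogen marks the protein and haematoxylin marks
nuclei. Each signal is quantified by classical descriptors, reduced, and
classified by a bank of one-vs-rest RBF-kernel support-vector heads
("binary relevance"); the per-signal sub-classifiers are then fused at the
decision layer by a centralized vote.

## Sequence signal

**Redundancy control.** Greedy longest-first clustering at an identity
cutoff (default 0.9): candidates are pre-screened by shared 5-mer counts
(a necessary condition derived from the cutoff: each mismatch on the shorter
sequence of length *n* destroys at most *k* of its *n−k+1* words), then
confirmed by global alignment, with identity defined as matched identical
pairs divided by the shorter length. Length filtering keeps 50 ≤ L ≤ 5000,
bounds inclusive.

**Descriptors.**

* *PseAAC (420)* — 20 residue-composition fractions followed by 400 ordered
  dipeptide fractions (row-major in the fixed PSI-BLAST alphabet order
  `ARNDCQEGHILKMFPSTWYV`, used everywhere in the package). Both blocks are
  probability distributions.
* *Physicochemical correlation (3675)* — the package ships a fixed table of
  50 classical amino-acid index scales (hydropathies, volume, polarity,
  secondary-structure propensities, …), each z-normalized across the 20
  residues. For every unordered scale pair (p < q; 1225 pairs) and lag
  d ∈ {1, 2, 3}, the descriptor is the Pearson correlation between
  `profile_p[1..L−d]` and `profile_q[1+d..L]`. 3675 = 3 · C(50, 2) is the
  unique simple factorization of the dimension by cross-property lagged
  correlation; the lag range 1–3 is the package's choice. Correlations over
  a (numerically) constant segment are defined as 0. Because profiles are
  z-normalized, the descriptor is invariant to affine rescaling of any
  scale, so the exact units of the table do not matter.
* *PSSM descriptors* — the L×20 matrix E comes from an external iterative
  database search (PSI-BLAST ASCII format; the package parses, it does not
  search). `dp_pssm` (240 = 40 + 40·α, α = 5): per column, the mean of
  positive and of negative scores, then per lag k ≤ α the means of positive
  and negative score differences E[i,j] − E[i+k,j]; empty sign sets
  contribute 0. α = 5 follows the common toolkit convention; the source
  protocol never states the dimension. `aac_pssm` (20): column means.
  `pssm_composition` (400): residue-conditioned column means. The registry
  is extensible to further PSSM transforms.

## Image signal

**Preprocessing.** RGB is converted to optical density
OD_c = −log10((I_c + 1)/256) (the +1 avoids log 0) and decomposed per pixel
into non-negative haematoxylin and DAB coefficients against the
Ruifrok–Johnston optical-density basis (closed-form two-variable NNLS,
vectorized). Each concentration plane is rescaled so its 99th percentile
maps to 255, which resists single-pixel outliers. A slide is accepted iff
its mean protein-plane intensity ≥ 13 on that scale; the same constant
defines an "effective" 512×512 patch, since the protocol states only one
empirical intensity threshold. The protein plane is tiled by a
non-overlapping 512-stride row-major grid (a 3000×3000 slide yields 25
candidates; remainder margins are discarded, not padded) and the first 15
effective patches are kept; a shortfall is flagged, not an error. All
threshold comparisons are inclusive (≥).

**Texture descriptors.**

* *Haralick (26)* — the patch is uniformly quantized to 32 gray levels
  ([min, max] binning; near-constant patches map to level 0 rather than
  amplifying round-off ripples). Four symmetric normalized co-occurrence
  matrices at distance 1 (0°, 45°, 90°, 135°, rows pointing down) give 13
  classic statistics each; the descriptor is their per-statistic mean and
  range across directions. Zero-variance degeneracies are analytic (ASM 1,
  entropy/contrast 0, correlation-type statistics defined 0), never NaN.
* *Wavelet Haralick (674 = 26 + 8·3·27)* — an 8-level Daubechies (db8 by
  default, db1–db10 supported) decomposition with symmetric extension; for
  each level (finest first) and detail orientation (horizontal, vertical,
  diagonal) the image is reconstructed from that band alone, re-quantized,
  and described by the 26 statistics plus one band energy (mean squared
  band coefficient). The 27th per-band feature is not specified by the
  protocol's "3 × 27" arithmetic; band energy is the cheapest
  orientation-discriminative scalar and is the package's choice. Features
  are computed on reconstructions, not raw coefficient arrays, following
  the protocol's wording.
* *LBP (256)* — per interior pixel, bit k is 1 iff the k-th neighbor ≥
  center, neighbors clockwise from the top-left of the 3×3 mask, bit 0 most
  significant; the histogram over the 256 codes is normalized to sum 1.
  The tie convention makes constant regions map to code 255 and the
  descriptor invariant to monotone intensity shifts. Border pixels are
  skipped.
* *Deep embeddings (2 × 1024)* — the original protocol reads two
  1024-dimensional layers ("C3", "GAP") of a pretrained attention CNN that
  is not publicly available. The package exposes a provider interface: any
  deterministic patch → vector mapping can be registered under a name. The
  default providers are frozen random-weight convolutional encoders
  (block-mean downsample to 64², two strided conv+ReLU stages, average
  pooling, fixed random projection with tanh) with different seeds for the
  two slots — reproducible random-feature embeddings, emphatically not the
  original CNN. Results with them characterize the pipeline, not the
  published network.

Per protein, the up-to-15 patch vectors of each operator are averaged
element-wise.

## Selection and classification

* *LASSO (sequence space)* — one-vs-rest L1 logistic regressions over 8
  log-spaced penalties; the penalty minimizing 3-fold cross-validated
  deviance is chosen per class; the selected set is the union of nonzero
  supports. An all-noise design falls back to the weakest penalty with ≥ 1
  nonzero coefficient. Features are standardized on the fitting rows;
  constant columns are dropped and logged.
* *SDA (image space)* — forward–backward stepwise selection on Wilks' Λ
  with F-to-enter 3.84 and F-to-remove 2.71 (classic defaults of standard
  statistical packages; the protocol states no thresholds). Partial F
  values are computed from Schur complements of the within-class and total
  scatter Gram matrices, vectorized over candidates; degenerate candidates
  (constant or collinear within tolerance 1e−10 relative) are skipped and
  counted. Λ after every accepted step is recorded and is non-increasing
  over forward steps by construction.
* *Classification* — each sub-classifier standardizes its selected columns,
  grid-searches a shared (C, γ) for the RBF kernel on its training rows
  (C ∈ {1, 10, 100}, γ ∈ {scale, 0.01}, 3-fold), and fits four one-vs-rest
  heads with cross-validated Platt calibration. Confidences live in [0, 1]
  and rows need not sum to 1.
* *Centralized voting* — each sub-classifier votes for its row-argmax
  location; the plurality wins. Ties are broken by the largest confidence
  sum over the tied locations across all voters, residual ties by the fixed
  class order (ER, Golgi, Cytosol, Nucleoplasm); tie-breaks are flagged in
  the result. The five shipped voters: sequence DP-PSSM+PC with LASSO;
  image C3; image GAP; image C3+Haralick+LBP with SDA; image
  GAP+Haralick+LBP with SDA.
* *Evaluation* — stratified seeded 5-fold or leave-one-out CV, with
  selection and classifier fitting strictly inside each training fold (the
  original protocol does not state per-fold selection; it is enforced here
  for statistical validity). Metrics: accuracy, macro precision and macro
  recall (0/0 per-class terms defined 0), 4×4 confusion matrix with true
  classes as rows. One deliberate boundary relaxation: leave-one-out on a
  dataset containing a 2-sample class necessarily leaves a single positive
  in some training folds, so the LOO path accepts 1-sample classes and
  replaces cross-validated calibration by a fixed sigmoid of the SVM margin
  for such heads; direct `train_br` calls still require ≥ 2 per class.

## Synthetic benchmark

The generator is the package's stand-in for the original paired
HPA/Swiss-Prot benchmark and defines the study conditions of every test:

* sequences from per-class first-order Markov chains whose stationary
  composition and transition tilts are exponential perturbations of the
  Swiss-Prot background, scaled by `separation`; lengths uniform on
  (50, 800) — within the protocol's 50–5000 filter at realistic protein
  lengths;
* PSSMs as a scaled one-hot of the sequence (+8 own residue, −1 elsewhere)
  plus rounded Gaussian noise, clipped to [−10, 12];
* images as band-pass-filtered Gaussian noise fields with class-specific
  dominant spatial frequency and stained-area density (both interpolating
  to a common value at `separation` 0), thresholded into a DAB
  concentration field, plus a shared low-frequency nucleus-like
  haematoxylin field, mixed through the same stain basis the unmixer
  inverts. The default image side is 512 px — the smallest size carrying
  one full sliding-window patch — keeping desk-scale runs tractable while
  the full 3000×3000 patch geometry is exercised separately.

At `separation` 0 the four classes are statistically identical by
construction, so end-to-end accuracy must be indistinguishable from 0.25;
at the default `separation` 1 both signals are strongly informative. What
passing tests show is that the pipeline recovers planted class structure
and that its components match their definitions; they do not certify
performance on real IHC images, which differ in stain variability, tissue
morphology, label noise, and class imbalance, and which the shipped random
embeddings do not represent as a trained CNN would.

## Numerical conventions

Fixed alphabet and class orders throughout; inclusive thresholds;
zero-variance statistics defined 0; near-constant quantization guard at
1e−12 relative; NNLS solved exactly per pixel for the two-stain case; all
randomness flows from explicit integer seeds (dataset generation, fold
shuffling, penalty CV, SVM internals), so identical inputs and seeds
reproduce bit-identical feature tables, reports, and run manifests
(timing excluded).

## Problem sizes used in the shipped checks

The acceptance checks run the five-voter protocol at 40/class (single
fixed seed) and 10/class (five seeds) at separation 1, and 8/class at
separation 0 across five seeds pooled into a binomial test against chance;
selection recovery uses n = 200, p = 100, a planted support of 5 and mean
shifts of one noise standard deviation. The acceptance script reports a
20/class run. These sizes are the package's desk-scale defaults.

## Known limitations

* The shipped embeddings are untrained; absolute accuracies on real data
  are not comparable to a pretrained-CNN pipeline.
* Only 3 of the 18 PSSM descriptor family members are implemented; the
  registry accepts more.
* No cross-slide color normalization or tissue segmentation beyond the
  intensity rule.
* The greedy clustering is O(n²) alignments in the worst case; adequate for
  benchmark-scale inputs, not for proteome-scale redundancy removal.
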
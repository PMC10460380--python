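# Methods

This note documents the model, the defaults, the synthetic-data
generator and the numerical choices, including the places where the
design was genuinely open and a choice had to be made.

## Counting model

A ligation-probe assay produces fixed-length inserts, so target matching
is pure Hamming distance on the target region — no indel alignment.  A
read is assigned to the unique minimum-distance target when that
distance is at most `max_mismatches` (default 5, inclusive: a read at
exactly 5 mismatches is assigned, at 6 it is not).  Ties at the minimal
distance are conservative rejections (`ambiguous`, logged) rather than
arbitrary assignments, and `N` bases count as mismatches.

Molecule identity is *exact* UMI identity per target: every distinct UMI
with at least `umi_read_threshold` supporting reads contributes one
molecule (default threshold 1; higher thresholds are useful for very
deep libraries and are exposed as a flag).  No 1-edit UMI merging is
performed.  Two consequences worth knowing:

* raising the threshold can only lower counts (monotonicity, tested);
* a sequencing error inside a UMI would mint a phantom molecule.  The
  read simulator therefore confines per-base errors to the target
  region, which is the quantity the mismatch tolerance is about; UMI
  read-out is treated as error-free.  Real data with appreciable UMI
  error rates would need threshold > 1 or UMI-collapse preprocessing
  upstream of this package.

The default read layout is `[UMI-4][target][UMI-4]` with the 8-nt
concatenated UMI as key (65,536 states); the layout is configurable for
other probe designs.  With ≤ a few hundred molecules per target the
birthday-bound collision probability is far below 1% (a warning fires
when it is not).

## Normalization and scaling

Per sample, counts are divided by the geometric mean of the housekeeper
counts (computed in log space).  This makes normalization exactly
equivariant to library size: scaling a whole sample row by c > 0 leaves
its normalized row unchanged.  A housekeeper count of zero means the
assay failed for that sample; the sample is flagged QC-fail and excluded
rather than pseudocounted.

Two downstream paths exist, and a state flag enforces their order:

* statistics path: `linear → shifted-log`, x ↦ ln(x + 1).  The shift
  constant is 1.0 by default (the natural choice that maps 0 to 0) and
  configurable.
* model path: `linear → scaled`, z-scoring with development-set mean and
  sd (ddof = 1).  Test samples are always scaled with development
  parameters, never their own.  Whether a log belongs before the scaling
  on the model path is a genuinely open design point; the default is
  no log (scaling of normalized counts), with `log_before_scale=True`
  as the alternative.  Zero-variance genes are dropped and listed.

## Reference model

PCA is computed by SVD of the scaled development matrix; eigenvector
signs are fixed (largest-magnitude loading positive) so fits are
bit-reproducible.  Horn's parallel analysis decides k: the null
distribution is 100 column-wise permutations of the observed data
(preserving marginals, destroying correlation), a component is kept
while its eigenvalue exceeds the 95th percentile (quantile parameter
0.05) of the matching null eigenvalue, counting stops at the first
failure, and a floor of k = 1 is enforced.  Permutation rather than
Gaussian resampling makes the null robust to the heavy right tails of
expression data.

Phase labels collapse to the three reference classes (PE and ESE are
both pre-receptive; MSE is receptive; LSE is post-receptive).  Each
class contributes a centroid in component space.  The Mahalanobis
covariance is the *pooled within-class* covariance: with 10–36 samples
per class, per-class covariances are too unstable, and pooling matches
the implicit assumption that classes share dispersion (a per-class mode
would be a small extension).  A ridge ε = 10⁻⁶·trace(Σ)/k guarantees
positive definiteness; ε is recorded in the model file.

## Classification

For a projected test sample, squared Mahalanobis distances to the three
centroids are referred to χ²(k).  The outlier rule defaults to the
*upper* tail at α = 0.025 — a sample far from every centroid does not
resemble any reference group and its call is flagged "interpret with
caution" (the call is still reported).  A lower-tail and a two-tail mode
exist because distance-based outlier conventions differ between
implementations; the choice is recorded in the model file.

The hierarchical second stage compares only temporally adjacent classes:
the closest class selects among the pairs (pre, receptive) and
(receptive, post) — both, with the smaller summed distance winning, when
receptive itself is closest; a full tie falls back to the earlier pair.
The pair's relative probability is the Gaussian kernel exp(−d²/2)
normalized over the two classes — the canonical likelihood ratio under
the model's own equal-covariance Gaussian assumption — computed in
logistic form so it is stable for astronomically large distances.  With
decision boundaries (θ_lo, θ_hi) = (0.25, 0.75): leading probability
≥ θ_hi gives the leading reference class, anything strictly between the
boundaries gives the transitionary class between the pair
(early-receptive between pre and receptive, late-receptive between
receptive and post).  The boundaries are not canonical constants; they
are configurable and echoed in every report.  Exactly one final class is
emitted per sample.

## Evaluation statistics

* **Cross-validation**: 5 folds × 100 repeats.  Folds are random
  near-equal partitions, rejection-resampled until every test fold
  contains at least one sample of each reference class.  The entire
  model — scaling, Horn's k, centroids, covariance — is refitted on each
  training split (an internal guard errors if a test sample ever
  appears in its own training split).  Inside CV, test samples receive
  the most probable of the three reference classes (no transitionary
  calls), and "macro accuracy" is the unweighted mean of per-class
  recall averaged over repeats; micro accuracy is reported alongside.
* **Concordance accounting**: predictions are tabulated against the
  phase expected from biopsy timing.  ESE expects pre-receptive, LSE
  expects post-receptive, MSE expects any in-range class
  (early/receptive/late — transitionary calls at MSE count as normal
  WOI variability and are reported as an "in-range shift" percentage
  relative to the MSE group).  "Displaced" means the WOI is shifted: a
  pre-/post-receptive call where receptive was expected, or an in-range
  call where pre-/post-receptive was expected.  Percentages are exact
  integer ratios reported to one decimal.
* **Group comparison**: lower-tailed Fisher's exact test — with margins
  fixed the first cell is hypergeometric and p = P[X ≤ x₁₁].
* **Differential tests**: per-gene independent t-tests on shifted-log
  expression (Welch by default; pooled-variance by flag) with Bonferroni
  (default) or Benjamini–Hochberg adjustment; genes constant in both
  groups get t = 0, p = 1 rather than NaN.  Two-way ANOVA per gene uses
  type II sums of squares with the interaction F-test; genes with an
  empty design cell are skipped with a warning.

## Synthetic data

The generator exists so that every module is testable with known ground
truth; its defaults describe one fixed study design, not a tuning
surface.

* Panel: 72 genes — housekeepers SDHA, CYC1, TBP, HMBS; the 11 named
  WOI-relevant genes; 57 placeholder biomarkers (`RB01`–`RB57`) standing
  in for the published receptivity biomarker set, whose identities are
  not part of this package.  Target sequences are fixed random 50-mers
  (internal seed, so the panel is a constant artifact).
* Cohort: n = 18 (PE), 18 (ESE), 17 (MSE), 10 (LSE).
* Expression: biomarker log-means follow a 3-factor latent trajectory
  (factor 1 tracks cycle progression, factors 2–3 add curvature), with
  loadings ~ N(0, 0.55²/0.35²/0.25²) and base means log-normal around
  150; housekeeper means are phase-constant at 500, so housekeeper
  normalization is the correct de-noising.  Adjacent phase-mean profiles
  are ≥ 4 pooled standard deviations apart in aggregate (tested).
* Counts: negative binomial with size 25 (the standard overdispersed
  count model for expression data) times a per-sample log-normal
  library-size factor (σ = 0.15).
* Reads: per molecule, a uniform UMI, a geometric PCR duplicate count
  (mean 5 reads/molecule), substitution errors in the target region at a
  configurable rate.

What passing on this data does **not** show: the generator is
structural, not biological.  Real effect sizes, gene–gene correlation
beyond three factors, batch effects, RNA degradation and the actual
biomarker identities are all absent, so synthetic accuracies
characterize the pipeline's correctness and its behavior under the
stated separation — not clinical performance.

## Problem sizes and determinism

All simulations in the test suite and the acceptance script run at the
cohort sizes above (63 training samples, 100 CV repeats, ≤ 1,000-read
counting fixtures, 100-seed Horn noise panels) — small enough to run
anywhere in minutes, large enough for the Monte-Carlo bounds used in the
tests.  Every stochastic step takes an explicit seed (numpy `Generator`);
identical inputs and seed give bit-identical models, classifications and
reports.  Model files are versioned JSON; a version mismatch is an
explicit error, never a silent reinterpretation.

## Known limitations

* Sample demultiplexing and paired-end merging are out of scope; input
  is one FASTQ per sample.
* No detection of pathologically *disrupted* (as opposed to displaced)
  receptivity profiles.
* The χ² outlier gate assumes d² is χ²(k) under the reference model —
  adequate for flagging, not calibrated for small per-class n.
* Quality scores are ignored during matching.
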
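# Methods

`pepstrat` implements a stratification analysis for whole-plasma
peptidome fingerprints acquired by linear-mode MALDI-TOF mass
spectrometry in the 2,000–20,000 Da window. The pipeline turns raw
profile spectra into a sample × peak matrix, reduces it to binary
presence/absence features, ranks peaks by their ability to separate
experimental groups, and quantifies both unsupervised structure
(clustering, PCA) and supervised predictive performance
(cross-validated classifier grids). This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not demonstrate.

## Preprocessing

Each spectrum is processed in a fixed order:

1. **Trim** to the analysis window `[2000, 20000]` Da (inclusive).
2. **Square-root transform** of intensities. Detector counts have
   roughly Poisson-like variance; the square root stabilises it so a
   single per-spectrum noise scalar is meaningful.
3. **Savitzky–Golay smoothing** — each point is replaced by the
   centre value of a least-squares polynomial fit over a window of
   `2·half_window + 1` points. Defaults `half_window = 10`,
   `polyorder = 3`, the conventional values for linear-TOF profile
   data; the window/order are configurable, and edges are handled by
   polynomial extrapolation from the first and last full window
   (`scipy.signal.savgol_filter(mode="interp")`). A warning is issued
   when the m/z grid spacing varies by more than 1%, since the filter
   assumes a uniform grid.
4. **SNIP baseline estimation** over 100 iterations: starting from
   the signal itself, for window size *i* = 1…100 every point is
   clipped to `min(b_j, (b_{j−i} + b_{j+i})/2)` with boundary indices
   clamped. The plain-intensity variant with an increasing window is
   used (no log-log-sqrt pre-transform); the variant choice matters
   mostly for very high dynamic range spectra. The baseline is
   subtracted and negative residuals are clipped to 0, because peak
   detection assumes a non-negative signal. The baseline is pointwise
   non-increasing in the iteration count and never exceeds the input
   signal — both properties are tested.

No total-ion-current normalisation is applied by default: the
downstream binarization is threshold-based and absorbs monotone
per-peak intensity rescaling (a tested invariance). A TIC option
exists for completeness.

## Peak calling and the peak matrix

**Noise** is a single robust scalar per spectrum: the
Gaussian-consistent scaled median absolute deviation
`1.4826 · median(|x − median(x)|)` of the baseline-corrected signal.

**Detection**: a point is a peak iff it is the strict maximum of the
window of ±40 points and its intensity is at least `SNR × noise` with
`SNR = 4` ("equal or higher" at the boundary). Equal neighbouring
maxima resolve to the lower-mass point, deterministically.

**Binning** aligns peaks across spectra by divisive gap-splitting:
the pooled sorted masses are recursively split at the largest gap
until every bin satisfies `max |mz − mean(bin)| / mean(bin) ≤
tolerance`; the bin reference mass is the member mean, and if one
spectrum contributes several peaks to a bin only its most intense is
kept. The tolerance is *relative*; the package default is `0.002`
(0.2%, about 10 Da at 5 kDa — consistent with linear-TOF mass
accuracy), while `PipelineConfig.protocol_profile()` keeps the literal
protocol constant `0.2`. A relative 0.2 would merge peaks 20% apart
in mass and is not usable for profile comparison; we interpret the
protocol value as a transcription of the toolchain argument without
units and default to the toolchain's own 0.002.

**Replicate averaging**: technical replicates (duplicate spots) of a
sample are averaged arithmetically, with an absent peak counting as 0;
replicates flagged as excluded for quality are dropped first, and a
sample with a single surviving replicate passes through unchanged.
Averaging is idempotent.

**Occurrence filter**: bins present in fewer than 33% of the averaged
sample rows are removed (strictly-less-than convention, so 26/76 =
34.2% survives and 25/76 = 32.9% does not). The filter is applied
after averaging; it is monotone in the threshold.

## Binary features and discriminant ranking

**Dichotomization**: each peak is reduced to presence/absence against
its pooled per-peak mean intensity — cell = 1 iff intensity ≥ mean.
The pooled threshold keeps the binary value independent of the sample
label, so it is computable at prediction time; a "mixture of class
means" threshold is available as a config option.

**BDA t-scores**: for bin *j* and group *g* with `n_g` of `n`
samples, group presence frequency `p̂_gj` and pooled frequency `p̂_j`
(shrunk into `[ε, 1−ε]` with `ε = 1/(2n)` to avoid division by zero
at degenerate frequencies):

    t_gj = (p̂_gj − p̂_j) / sqrt( p̂_j (1 − p̂_j) (1/n_g − 1/n) )

A positive score means the peak is over-present in that group. Peaks
are ranked by the aggregate `Σ_g t_gj²` (descending, ties broken by
mass order), and a peak is flagged significant when any class reaches
`|t| ≥ 2.5`. The weighted deviations `Σ_g n_g (p̂_gj − p̂_j)` cancel
by construction — a tested identity. Note the `1/n_g − 1/n` factor
makes peaks of larger groups score systematically higher at equal
frequency contrast.

**Random-forest ranking**: impurity-decrease importance of a seeded
500-tree forest (`max_features = √p`) trained on the same binary
matrix — the alternative ranking criterion. The ensemble is
scikit-learn's; determinism given the seed and importance export are
part of this package's contract.

Feature rankings record the IDs of the rows they were computed on.
Supervised evaluation *refuses* a ranking whose rows overlap the test
set; the leakage guard is structural, not advisory.

## Unsupervised structure

**Binary distance** (asymmetric Jaccard): discordant positions over
positions where at least one vector is 1; two all-zero vectors are at
distance 0. Symmetry and the triangle inequality are property-tested.

**Hierarchical k-means** (`hkmeans`): pairwise binary distances →
Ward.D2 agglomeration (the Lance–Williams update applied to the
supplied dissimilarities; verified equivalent to R's
`hclust(method="ward.D2")` partition on fixtures) → cut into *k*
groups → standard Euclidean k-means on the raw 0/1 rows started from
the within-group means. The k-means loop runs in Euclidean space
because a centroid is not well-defined under the binary distance; the
hierarchical stage carries the binary-distance semantics, and the
refinement can only decrease the within-cluster sum of squares of its
own initialisation (tested). Should k-means empty a cluster, the
centre is re-seeded at the farthest row (scikit-learn's relocation
rule). The default is `k = 3`, matching a three-group design;
`protocol_profile()` sets 4.

**Composition metrics**: cluster × group counts; homogeneity =
dominant-group share of the cluster; coverage = share of a group
captured by the cluster. Reported as integer percentages rounded
half-up (85, 77, 91, 64 from 29/34, 20/26, 20/22, 16/25); unrounded
values are kept alongside, and the unrounded coverages of a group sum
to 100% across clusters.

**PCA**: columns mean-centred, no scaling; components from the SVD of
the centred matrix, explained fraction per component = eigenvalue
share of the covariance trace. Identities against a direct
eigendecomposition are tested.

## Supervised evaluation

The evaluation design: a stratified random 60/40 split at the sample
level (both replicates stay on one side; per-group train counts are
the rounded group fraction, never emptying a class). For each
algorithm (BDA, RF) × top-k (5, 10, 15, 20) cell: peaks are ranked on
the training rows with that algorithm's own ranker, the top-k are
selected, CV-mean metrics are estimated by 5-fold × 20-repeat
stratified cross-validation inside the training set, the model is
refitted on the full training set and scored once on the held-out
test set. Both the held-out table and the CV-mean table are emitted
and labelled, since a single protocol often reports either.

**The BDA classifier** is a Bernoulli discriminant: per class and
peak the Laplace-smoothed presence frequency
`q̂_gj = (count_gj + 1)/(n_g + 2)`, prediction by maximum of
`log π_g + Σ_j [x_j log q̂_gj + (1−x_j) log(1−q̂_gj)]` with empirical
priors; ties go to the lexicographically first class label and are
logged. The model is bound to the peak subset and thresholds it was
trained on and refuses other inputs. **The RF classifier** is a
seeded scikit-learn forest on the same binary features.

**Metrics**: accuracy, sensitivity, specificity, PPV and NPV in
percent with one-decimal rounding. The multi-class confusion is
collapsed to positive vs negative before the ratios are computed;
with groups CTL/IS/LPS the default positive set is the non-control
states {IS, LPS}. This convention reproduces, from integer confusion
counts on a 31-sample test set (11 negative, 23 positive), the metric
row 94.1/95.7/90.9/95.7/90.9 — the consistency check that locks the
convention in the test suite. A macro-averaged one-vs-rest mode is
available. Ratios with zero denominators are reported as missing
(NaN), never as 0.

## Synthetic data generator

The generator emulates a three-group design of 25/22/29 samples
acquired in duplicate (152 spectra, 76 samples) on a uniform 3-Da
grid over 2,000–20,000 Da. Its structure:

- **70 template peaks** on a 234-Da lattice from 2,300 Da: 40 shared
  by all groups (presence 0.95) and 10 enriched per group. Enriched
  peaks follow a severity gradient CTL < IS < LPS: presence 0.9 in
  their own group, 0.3 in the adjacent state and 0.1 in the far one
  (IS-enriched peaks sit at 0.2 on both sides), mean out-group
  presence 0.2. Graded signatures mimic inflammation markers that
  rise or fall monotonically with disease state; they also keep a
  top-5 peak set informative about all three groups even when the
  ranking concentrates on one group's peaks, which the `1/n_g`
  size-bias of the t-score makes likely for the largest group.
- **Biology once per sample**: peak presences (Bernoulli) and
  intensities (lognormal, median ≈ 150 counts, log-sd 0.35) are drawn
  per sample and shared by its replicates, so replicate averaging is
  meaningful. Each replicate adds technical variation only: Gaussian
  peak shapes (σ = 18 Da) at masses jittered by N(0, 1.5 Da), an
  exponential matrix baseline (amplitude 5 counts at the low-mass
  edge — about 5× the noise, so baseline correction is non-trivial —
  decay constant 3,000 Da) and i.i.d. Gaussian noise (σ = 1 count),
  clipped at zero.
- A per-sample truth table is returned for recovery tests, and the
  whole dataset is byte-identical for a fixed seed.

**What passing tests show — and what they do not.** The generator
produces well-separated, correctly calibrated class structure: peaks
are resolved, jitter is far below the binning tolerance, and presence
probabilities dominate the signal. Tests against it demonstrate that
the pipeline recovers planted structure faithfully (template masses
exactly at zero noise; detection frequencies correlating r ≥ 0.9 with
planted probabilities; every cluster ≥ 75% homogeneous; every grid
cell ≥ 85% accurate; permuted labels falling to the no-information
rate). They do not demonstrate performance on real plasma spectra,
where peak shapes are asymmetric, baselines are not exponential,
noise is heteroscedastic and mass calibration drifts within a run.
Accuracy degrades monotonically as the generator's noise approaches
the peak intensity scale (tested at σ = 1 → 250 → 600 counts).

## Numerical choices and degenerate inputs

- Tolerances: float comparisons in oracle tests at `rtol ≈ 1e-9`;
  statistical assertions use explicit bands stated in each test.
- Binning termination: a single-mass bin always satisfies the
  tolerance, so the divisive recursion terminates.
- Detection on an all-zero spectrum returns an empty peak list (the
  `x > 0` guard, since `SNR × 0 = 0`).
- Dichotomization of a constant bin yields all ones (equal-or-higher
  convention).
- An occurrence filter that would drop every bin raises with advice
  to lower the threshold rather than returning an empty matrix.
- Savitzky–Golay requires the spectrum to be longer than the window;
  SNIP requires iterations ≤ half the spectrum length.
- Problem sizes in the test suite: the session-wide reference run
  uses the full 76-sample / 152-spectrum design; auxiliary property
  tests (noise curve, CLI) run on 6–12 samples per group with reduced
  CV settings.

## Known limitations

- Bruker fid/acqus raw files are not parsed; spectra enter as
  two-column text or plain profile mzML. The mzML path prefers
  pyteomics and falls back to a built-in decoder for uncompressed or
  zlib-compressed 32/64-bit float arrays.
- The binarization threshold, computed on the full matrix before the
  train/test split (matching the protocol's listed order), is a mild
  information leak shared by the original design; the structural
  leakage guard covers feature *ranking*, which is the dominant risk.
- `hkmeans` composition metrics require true labels; without labels
  only assignments and centres are returned.
- The t-score's `1/n_g − 1/n` variance factor favours larger groups
  in ranking; this is inherent to the class-vs-pooled contrast, not
  corrected here.
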
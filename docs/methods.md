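# Methods

## Pipeline overview

A scan is an `X × T` matrix of regional signals (rows = regions,
columns = timepoints; the defaults emulate a 234-region parcellation with
T = 190 at TR = 2 s, band-passed upstream). Every analysis starts from the
Hilbert amplitude envelope `H(t) = |x(t) + i·Hilbert(x)(t)|`, computed per
row with `scipy.signal.hilbert`. No edge tapering or padding is applied and
no per-series standardisation is performed before the envelope; both are
deliberate fidelity choices, and the untreated FFT edge effects are a
documented caveat for short series.

### Lempel-Ziv compressibility (LZC)

Each envelope row is binarised at its own mean (ties map to 1), the binary
matrix is stacked column-wise (each consecutive `X`-bit block is one
timepoint's spatial activation pattern), and the LZ76
exhaustive-history phrase count is computed: scanning left to right, the
current phrase is extended while it occurs as a substring of everything
before its final symbol, and closed at first novelty (a final
still-reproducible suffix counts as one phrase). The count is divided by
the count for a surrogate in which every binarised row is independently
permuted, so structureless data normalise to ≈ 1. Shuffling the binarised
rather than the raw rows is equivalent in distribution because the row
mean is permutation-invariant. One surrogate with a fixed seed is the
default (`n_surrogates` averages more).

The parser is a Numba kernel that finds, for each phrase start `i`, the
longest match of `s[i:]` beginning at any `j < i` (overlap into the phrase
allowed); phrase length is `maxmatch + 1`. It is verified exhaustively
against a naive substring-search parser on all binary strings of length
≤ 12 and on 1,000 random longer strings.

### Sample entropy

`SampEn = −log(A/B)` with embedding `m = 2` and tolerance `r = 0.3·σ`
(population SD of the series). `B` counts ordered pairs (`i ≠ j`, both
indices ≤ `N − m − 1`) of `m`-templates within Chebyshev distance `r`; `A`
the same for `(m+1)`-templates over the same index set, which guarantees
`A ≤ B`. Matching is non-strict (`≤ r`): the strict reading would make the
constant series [1, 1, 1, …] have undefined rather than zero entropy, and
non-strict matching is the standard convention. Self-matches are excluded.
`A = 0` yields +inf (flagged and excluded from scan averages with a
warning); `B = 0` is flagged undefined. The implementation is vectorised
over template pairs and is checked for exact `A`/`B` agreement against an
explicit O(n²·m) loop oracle.

### Hurst exponent (rescaled range)

For window sizes `n` (powers of two from 8 to N/2; at least 3 required)
the series is cut into `⌊N/n⌋` non-overlapping segments; per segment the
cumulative departure from the segment mean is accumulated and
`R/S = (max − min of the profile) / SD(segment)`; zero-SD segments are
skipped. `H` is the slope of `log mean-R/S` against `log n`. The classical
small-sample bias of plain R/S (≈ +0.05 at these lengths for white noise)
is accepted and documented rather than corrected; measured recovery on
exact fGn at n = 1024 is within 0.05 of truth for H ∈ {0.6, 0.7, 0.8}.

### Higuchi fractal dimension

The canonical construction: for stride `k = 1…k_max` and offset
`m = 1…k`, the decimated curve length
`L_m(k) = [Σ|x_{m+ik} − x_{m+(i−1)k}|]·(N−1)/(⌊(N−m)/k⌋·k) / k`
is averaged over offsets, and `D` is the negative slope of `log⟨L(k)⟩` vs
`log k`. `k_max` can be fixed or selected automatically by the stability
sweep over powers of two 2…128: candidates violating `N > 2k` are
excluded, and the smallest candidate in the longest contiguous run where
successive mean-dimension estimates change by < 0.05 is returned.

A note on ground truth: the `D = 2 − H` law holds for the graph of
fractional Brownian *motion*; fractional Gaussian *noise* itself has
`D ≈ 2` for every H because its lag-k increments have bounded variance.
Parameter-recovery tests therefore run Higuchi on the cumulative sum of
the exact fGn generator, where recovery at n = 1024 is nearly unbiased.

### PCA compressibility

Timepoints are observations and regions are features (so the count is
bounded by the region count); features are standardised to mean 0 / unit
variance (zero-variance features are centred only, with a warning), and
the reported value is the smallest number of principal components whose
cumulative explained-variance ratio reaches 0.95. The orientation
(timepoints-as-observations) is one of two defensible readings and is
fixed here; with the transposed convention the count would be bounded by T
instead.

### Functional connectivity and graph measures

The envelope rows are correlated pairwise (Pearson); the diagonal is
zeroed and negative entries are set to zero, yielding a simple nonnegative
weighted graph. At each threshold k ∈ {10, 20, …, 90} the strongest
`ceil(k%·E)` of the `E = X(X−1)/2` possible edges are retained (the cutoff
is the weight of the `ceil(k%·E)`-th strongest edge; ties at the cutoff
are all included, so realised density can slightly exceed k%). Per
threshold graph we compute

* **algebraic connectivity**: λ₂ of `L = D − A` by dense symmetric
  eigendecomposition (exact at X ≤ a few hundred); eigenvalues below 1e-9
  report as 0, and λ₂ = 0 iff the graph is disconnected;
* **graph compressibility**: the LZ76 phrase count of the row-major
  flattened adjacency (row-major is fixed for bit-exact reproducibility;
  the matrix is symmetric so the choice is low-stakes).

Each nine-point curve is integrated by the trapezoid rule with spacing 10
(threshold-percent units); any constant spacing rescales all scans
identically and cannot change rank statistics.

### Higher-order analysis

Profiles are pooled across conditions (pooling is what yields enough rows
— e.g. 16 subjects × 2 conditions = 32 — for a stable seven-variable
PCA). The inter-metric matrix is the Pearson correlation across pooled
profiles with the diagonal masked. For the overall-complexity component
the seven metric columns are standardised first — their raw scales span
five orders of magnitude (LZ_Graph ~10⁵ vs LZC ~1), so unstandardised PCA
would be degenerate — and PC1's sign is fixed by convention so the LZC
loading is negative; explained variance is invariant to any column's sign
or scale, which the tests assert exactly. Condition effects use
Kruskal-Wallis (omnibus) and paired Wilcoxon signed-rank tests with the
exact small-sample null when n ≤ 25 and there are no ties or zeros (the
smaller signed-rank sum is reported as W; all-zero difference vectors
report p = 1). Dose relationships are Pearson correlations over sedated
(dose > 0) scans only; Spearman is not currently exposed. No
multiple-testing correction is applied by default, matching common
practice of reporting uncorrected pairwise p-values in small cohorts.

## The synthetic cohort generator

`gen_cohort` emulates the *design* of a paired sedation study, not its
haemodynamics. Region `i` in community `q` follows

    x_i(t) = sqrt(c) · z_q(t) + sqrt(1 − c) · e_i(t)

with `z_q` and `e_i` unit-variance stationary AR(1) processes sharing
coefficient φ. A per-condition complexity grade `g ∈ [0, 1]` maps linearly
to φ ∈ [0.25, 0.80] and `c` ∈ [0.15, 0.65]: higher grade means slower,
more predictable signals (LZC, SampEn, Higuchi fall; Hurst rises) and
stronger community structure (fewer PCA components; more modular, more
compressible thresholded graphs, hence lower algebraic connectivity and
graph LZ). The effective grade per scan adds a persistent subject shift
(SD 0.03) and a per-scan draw (SD 0.05) shared with the dose covariate,
so dose correlates with realised complexity within sedated scans. Signals
are shifted strictly positive (envelope-like domain) before output. Eight
communities and 234 × 190 scans are the defaults; 16 subjects × two
conditions (grades 0 and 0.8, the deep-sedation-like end chosen to give a
strong, unambiguous paired effect) mirror a deep-anaesthesia study's
shape, and a 14 × 3 mild/moderate design is a one-line spec change.

What the generator does **not** emulate: haemodynamic convolution and its
band-limited spectrum, scanner noise and motion artefacts, spatially
heterogeneous effect sizes, negative correlations between regions, or
empirically calibrated per-condition effect sizes (no public data exist to
calibrate against). Passing the directional tests therefore shows the
estimators respond correctly to known changes in signal predictability and
coupling — not that real BOLD data would show effects of this magnitude;
absolute metric values here (e.g. SampEn ≈ 1.5–1.8, PCA-n ≈ 70–120) are
properties of the synthetic process, not predictions for fMRI.

`gen_fgn` produces exact fractional Gaussian noise by circulant embedding
(order 2n; eigenvalues via FFT of the embedded autocovariance
`γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`). A negative embedding
eigenvalue beyond numerical tolerance raises rather than truncating.
Moment calibration (variance, lag-1 autocorrelation vs closed form) is
tested over 20 seeds.

## Problem sizes and runtime choices

Full-scale scans (234 × 190) are used by the analysis scripts and the
acceptance script (~2 minutes for 32 scans on one CPU; the LZ76 kernel is
the dominant cost and is Numba-compiled). The 20-seed directional
replication in the test suite uses 60 regions × 160 timepoints — the
directional structure is scale-free by construction, and this keeps the
sweep around three minutes. Estimator-recovery tests use n = 1024 series
and 20 seeds.

## Known limitations

* Plain R/S Hurst estimation is biased upward for short memoryless series;
  window configuration is exposed but no Anis–Lloyd-type correction is
  applied.
* Hilbert envelope edge effects are untreated.
* LZC of an all-constant matrix is degenerate (surrogate equals the
  original); it is flagged rather than defined to a value.
* The paired Wilcoxon falls back to the normal approximation when ties or
  zeros occur, or n > 25.
* Dense eigendecomposition at every threshold is O(X³) per graph and is
  the right tool only up to a few hundred regions.
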
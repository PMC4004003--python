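# Methods

## The analysis model

An e-nose measurement is a matrix of conductance ratios R_i(t) = G/G0 for
sensors i = 1..S over n time points at interval Δt. Each curve is summarised
by its mean differential coefficient

    D_ave = (1/(n−1)) Σ_{z=1}^{n−1} (x_{z+1} − x_z)/Δt = (x_n − x_1)/((n−1)Δt),

the average slope of the response. The telescoped closed form is the
production path (O(1) and exact); the literal sum is kept as a test oracle.
No baseline subtraction or smoothing is applied.

PCA is computed on the **covariance** of the unstandardized feature matrix
(divisor n−1). No correlation scaling: D_ave values for a metal-oxide array
share units and their raw scale is meaningful; typical eigenvalues then fall
in the 1e-5…1e-11 range. Eigenvector signs are fixed by making the
largest-magnitude loading entry positive (ties to the lowest index) so
results are identical across linear-algebra backends. The model is fitted on
all samples, train and test together, because pair selection and score
plotting precede the classifier split in this workflow; the mild information
leakage this implies for the reported test accuracies is a property of the
workflow being modelled, and is stated rather than silently changed.

For a candidate set of m components, the within-class scatter D and total
scatter A are accumulated as plain sums of cross products of deviations from
class means and the grand mean respectively, and the dispersion ratio is the
Wilks lambda statistic Λ = det(D)/det(A). Small Λ = well separated classes.
The **improved variant** replaces each off-diagonal cross-product term by its
absolute value before summation. Motivation: deviations along two components
can disagree in sign sample by sample, cancelling in the off-diagonal sums
and masking genuine within-class association; the absolute value prevents
the cancellation. Diagonal entries (squares) are identical between variants.
Consequences worth knowing:

* regular Λ ∈ [0, 1] always (A = D + between-class scatter, both PSD);
* improved Λ is **not** bounded by 1; values above 1 are reported and
  flagged, never clamped;
* for 2×2 matrices both improved determinants are ≥ 0 (Cauchy–Schwarz on
  absolute products).

The pair search evaluates Λ for every unordered pair (optionally every
triple), selects the minimum at full precision, and breaks exact ties by
lexicographically lowest pair. Reported tables should be rounded to 4
decimals for display; selection never uses rounded values.

Class separation in a selected 2-PC plane is quantified by Mahalanobis
distances between class centroids, whitened by the **pooled within-class
covariance** with divisor N − c. Pooling is the standard discriminant-
analysis choice and makes distances comparable across PC pairs; published
per-study distance tables computed with an unstated covariance convention
are therefore not expected to be reproduced numerically, only ordinally.

The PNN stores one pattern neuron per training sample — a stated layer size
that disagrees with the training-set size in some descriptions of this
workflow is resolved in favour of the standard one-neuron-per-sample PNN.
Kernels:

* `dot_product` — patterns and queries unit-normalized,
  g(z) = exp((z − 1)/σ²) with z the inner product; on unit vectors this is
  the Gaussian kernel exp(−‖x − w‖²/(2σ²)). Activations lie in (0, 1].
* `euclidean` — exp(−‖x − w‖²/(2σ²)) on raw vectors, the radial-basis
  behaviour of MATLAB's `newpnn`. This is the pipeline default, because
  2-D PC score vectors carry class information in their magnitude, which
  unit normalization would discard.

Class scores are plain sums of activations (uniform priors), prediction is
arg-max with ties resolved to the lowest class index and flagged. The spread
grid is the ten values 1e-5, 2e-5, …, 1e-4; the selected model maximizes
(train accuracy, test accuracy) lexicographically, preferring the smallest
spread on ties. The train/test split is per-class head/tail (first 15 train,
last 5 test by stored order, configurable), matching sequentially acquired
measurements rather than a randomized split.

## Synthetic data generator

Curves follow first-order rise kinetics R(t) = 1 + (θ* − 1)(1 − e^{−t/τ})
with per-sample asymptote θ* = θ[g, s] + N(0, within_sd[s]) and i.i.d.
Gaussian measurement noise per time point, clipped below at 1e-6. The
baseline ratio is 1 (sensor in zero gas). Defaults: 6 classes × 20 samples,
10 sensors, 80 points at Δt = 1 s, τ = 15 s, within_sd = 0.02, noise_sd =
0.005, asymptotes between roughly 1.2 and 2.3 — magnitudes chosen so the
feature eigenvalue spectrum lands in the 1e-5…1e-11 range typical of D_ave
features from metal-oxide arrays. Because D_ave is linear in θ*, the class
geometry designed in θ maps into feature space with the known scale factor
(e^{−Δt/τ} − e^{−T/τ})/((n−1)Δt), which the tests exploit as a closed-form
oracle.

`hidden_discriminant` construction: sensors 1–2 receive large class-
independent within-class variability (sd 0.09 and 0.06) and dominate PC1 and
PC2; the six class means sit on a 3 × 2 grid spanned by two orthonormal unit
directions over the quiet sensors 3–10 (grid steps 0.035 and 0.017, quiet
within-sd 0.003, noise_sd 0.0015). Both grid directions are needed to tell
all six classes apart, so exactly one PC pair — the two quiet-plane
components, in practice (3, 4) — is jointly discriminative, and its between-
class spread is ≈4× the within-class spread. The eigenvalue ladder is kept
well gapped (ratios ≥ ~3 around the discriminative components) so
finite-sample eigenvector mixing does not leak loud-sensor variance into
them; with crowded spectra the selected pair becomes unstable and the
phenomenon washes out.

What the generator does **not** emulate: sensor drift, humidity/temperature
effects, autocorrelated noise, the multi-phase flush/injection cycle of a
real instrument, and non-exponential kinetics. Passing tests therefore show
that the selection machinery behaves as designed under its own model
assumptions, not that any particular real dataset will yield a specific
selected pair or accuracy.

## Numerical choices

* 2×2 determinants for Λ are accumulated in extended (long double)
  precision before the subtraction ad − bc.
* det(A) below 1e-300 raises a singularity error naming the offending pair;
  a singular pooled covariance raises with a regularisation hint
  (ε·I, ε = 1e-12 · trace).
* PNN activations that underflow to zero for an entire query (very small
  spreads) are recomputed with max-shifted exponents; the shift rescales a
  query's activations by a common factor, leaving class-score ratios and the
  arg-max unchanged, so the σ → 0 nearest-neighbour limit holds numerically.
* CSV IO writes floats with `%.17g` and reads with round-trip parsing, so
  datasets survive write/read cycles bit-exactly.
* Eigenvalues are clipped to 0 from round-off negatives; degenerate
  eigenvalue ties leave the within-tie subspace rotation backend-dependent
  (documented, not normalized).

## Problem sizes

Tests and the acceptance script run the full-size synthetic study
(6 × 20 samples, 10 sensors, 80 time points) for end-to-end checks, and
small randomized instances (2–4 classes, 3–6 samples per class, 2–3
components, ≥100 repetitions) for oracle-equivalence and property suites —
sizes at which the brute-force enumeration oracles are exact and fast.

## Known limitations

* The improved-variant Λ lacks the distributional theory of the regular
  Wilks statistic; it is used purely as a ranking score, and no significance
  testing (Rao/Bartlett F approximations) is provided.
* Mahalanobis tables depend on the pooled-covariance convention; comparisons
  with tables computed under other conventions are ordinal only.
* PCA-before-split leaks test information into the projection; accuracies
  are comparisons between PC pairs, not unbiased generalization estimates.
* The wide CSV dialect assumes Δt = 1 s; use the long dialect for any other
  sampling interval.
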
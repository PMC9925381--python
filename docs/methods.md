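# Methods note

This note records the statistical models, parameter choices, numerical
decisions and limitations of `chicdyn`. It makes no empirical claims beyond
the properties the test suite and `scripts/acceptance.py` actually compute.

## 1. Quantification (`quantify`)

Cut positions are assigned to non-overlapping genome regions by binary
search over sorted per-chromosome region starts. Coordinates are 0-based
half-open: a cut at position *p* belongs to bin [s, e) iff s ≤ p < e.

- **Bins**: fixed width, default 50,000 bp, tiling each chromosome; the
  final bin is truncated at the chromosome end.
- **TSS windows**: ±5,000 bp (default) around a strand-validated TSS;
  duplicate gene ids are disambiguated with a `.1` suffix. Overlapping
  windows are rejected by default (`overlap_policy="reject"`) or counted in
  every overlapping window (`"count_in_all"`).
- **QC**: per-cell cut totals; fraction of cuts in peaks (FRiP, computed
  against a possibly-overlapping peak set with a running-max-end sweep);
  Gini coefficient of per-region counts via the sorted-rank formula
  Σᵢ(2i − n − 1)x₍ᵢ₎ / (n Σ x); signal enrichment = FRiP divided by the
  genome fraction covered by peaks.
- **Cell filtering**: minimum cut count (pipeline default 100) and optional
  minimum FRiP; filtering everything is an error, not a silent empty result.
- **Background bins**: per-region log₁₀ totals are fit with a Gaussian KDE;
  the threshold is the density valley between the two largest modes
  (bimodal signal/background totals). A unimodal distribution keeps all
  bins with a warning; `manual_cutoff` overrides the KDE.

## 2. Topic model and latent space (`topics`)

Cell count vectors are modeled as a mixture of K region distributions
(latent Dirichlet allocation viewed as a hierarchical multinomial): topic
weights θⱼ per cell, region weights φₖ per topic. Fitting uses seeded batch
variational inference (`scikit-learn`), priors α = 1/K on θ and β = 0.1
on φ, 200 iterations by default. α = 1/K keeps the document prior sparse
and within the fitter's accepted range. K is a user choice; the pipeline
default is the number of simulated types when known.

- **Imputation**: Ỹ = log(φᵀθᵀ), the log posterior-mean probability of each
  region in each cell — a denoised, depth-free signal.
- **Clustering**: seeded k-means on θ (identical cells collapse to one
  cluster).
- **Batch correction** operates on any latent representation (topic weights,
  log-odds, PCs): for the model value ~ cluster + cluster:batch, the OLS
  solution is, per (cluster, batch) cell group, subtraction of the group
  mean deviation from its cluster mean, weighted by group size. This
  removes batch offsets within clusters while preserving each cluster mean
  exactly (verified to 10⁻⁸ in tests). Clusters observed in a single batch
  are skipped with a warning — their batch term is unidentifiable.
- **PCA** uses full SVD on centered cells × regions data so results are
  deterministic given the input.

## 3. Differential regions (`diffmark`)

Per region r, counts y_rj ~ Poisson(λ exposure_j) with exposure_j = total
cuts of cell j (log offset). The null fits one rate; the alternative one
rate per cell type. Both MLEs are closed-form — summed counts over summed
exposure per group — so no iterative solver is needed; the fit matches a
`statsmodels` Poisson GLM with offset to relative tolerance 10⁻⁶ (test
oracle). The likelihood-ratio statistic (deviance difference) is referred
to χ² with df = n_types − 1. All-zero regions get p = 1 and zero fold
changes by convention. Multiple testing uses Benjamini–Hochberg.

- **Dynamic-region thresholds** are per-mark: q < 10⁻⁵⁰ for H3K4me1,
  H3K4me3 and H3K27me3; q < 10⁻⁹ for H3K9me3, whose broad domains and lower
  signal-to-noise warrant a laxer cut. Unknown marks raise rather than
  silently defaulting.
- **Fold changes** are log₂ rate ratios versus a reference type, either
  from the GLM coefficients or from a depth-normalized pseudobulk ratio.
- **Fate independence**: for each (type, direction ∈ {gain, loss}) the
  changing set is {dynamic regions with sign-matching |log₂FC| > min_effect
  in that type}; a region is fate-independent when it changes the same way
  in every non-reference type. Reported as n_changing, n_fate_independent
  and their fraction (NaN with a warning when nothing changes). Verified
  against brute-force set enumeration.
- **Top depleted regions**: the k = 150 regions with the lowest fold
  change, stable-sorted by (fold, region id) for determinism.

Low per-cell counts make the χ² approximation to the LRT anti-conservative
in the extreme tail; calibration is checked at α = 0.05 with ≥ 2 expected
counts per cell, not at the 10⁻⁵⁰ operating point.

## 4. Motif activity (`motifact`)

Ridge regression Ỹ = N·A + ε: N is the regions × motifs site-count design,
Ỹ the imputed signal (centered per region so motif activities describe
deviations, not baseline coverage), A the motifs × cells activity matrix.
Columns of N are standardized so one penalty is meaningful across motifs;
all-zero motif columns are dropped with a warning. λ is selected from a
13-point log grid spanning 10⁻³–10³ times the mean diagonal of NᵀN by a
seeded 80/20 region-split cross-validation, shared across all cells.
Standard errors use the sandwich G⁻¹(NᵀN)G⁻¹σ̂²_c with G = NᵀN + λI and a
per-cell residual variance; a 10⁻²⁴ floor prevents division by zero in
exact-fit cases. A motif is called active when z = √(mean_c (A/se)²) > 0.7.

## 5. Double-incubation deconvolution (`dblsplit`)

Observed counts of a double-incubated cell: y ~ Multinomial(N, w·p_c +
(1−w)·q_l) with cluster profile p_c, landscape profile q_l, mixing weight
w ∈ [0, 1]. Reference profiles are pseudocounted (default 1.0) so they are
strictly positive. ℓ(w) = Σ y log(w p + (1−w) q) is concave, so
golden-section search (tolerance 10⁻⁴, with explicit boundary candidates)
finds the global MLE; when p = q on the support of y the likelihood is
flat and w = 0.5 is returned with a flag. Pair assignment maximizes the
profile likelihood over all (c, l) pairs; the posterior is the softmax of
pair log-likelihoods (uniform pair prior); exact ties break
lexicographically with a warning.

## 6. Cell typing (`celltyper`)

Per-type profiles pool labeled reference cells plus a pseudocount. A query
cell's score for type t is log p_tᵀ y + log prior_t; the posterior is the
max-subtracted softmax, numerically safe at depths ≥ 10⁷. Zero-count cells
get a uniform posterior and a flag.

## 7. Trajectory and chromatin velocity (`trajvel`)

- **FACS imputation**: a cell may miss at most one marker; it is filled
  with the mean of its k = 10 nearest neighbours (Euclidean on observed
  markers) among complete cells.
- **Ternary coordinates** embed three marker intensities on the 2-simplex.
- **Pseudotime** is the rank transform (rank/(n−1) ∈ [0, 1]) of the leading
  axis of the two selected PCs, orientation-flipped so the designated start
  population sits near 0. Ranks make pseudotime invariant to monotone
  distortions of the latent axis.
- **Splines**: per-region signal vs pseudotime is fit with a clamped cubic
  B-spline — knot vector [0,0,0,0, interior, 1,1,1,1], interior knots at
  quantiles, df ≥ 4 basis functions (df − 4 interior knots), least-squares
  coefficients. Needs at least df + 2 cells. Predictions clip pseudotime
  to [0, 1].
- **Velocity**: forward finite difference (f(t+δ) − f(t))/δ with δ = 0.01,
  switching to a backward difference where t + δ > 1. Velocity vectors are
  projected onto PC loadings (Lᵀ·V) for vector-field display; projection
  and differentiation commute because both are linear.

## 8. Synthetic data generator (`synthio`)

All randomness flows through a counter-based RNG (Philox) with substreams
keyed `(seed << 8) | operation_tag`, so adding a new operation never
perturbs existing draws and every output is reproducible from one integer
seed.

The generator emulates: per-type multinomial region profiles with
gamma-distributed baselines; planted dynamic regions with specified fold
changes, assigned round-robin so each type owns distinct regions;
log-normal per-cell depths (median 3,000 cuts, matching shallow
single-cell coverage); plate assignment and optional per-plate log-shift
batch effects; double-incubated mixtures with known (c, l, w);
Poisson-distributed motif site counts with sinusoidal activities for the
first n_active motifs and exactly-zero null activities; and
three-marker FACS trajectories with exact-count random masking.

It does **not** emulate: read-level artifacts (duplicates, mapping error),
chromatin contact structure or spatial autocorrelation between bins,
zero-inflation beyond multinomial sparsity, cell-cycle effects, or doublets
other than the intentional double-incubation design.

## 9. Pipeline (`pipeline`)

`validate_config` rejects unknown keys by name and checks path existence
before any work. Defaults: 50 kb bins, ±5 kb TSS windows, min 100 cuts per
cell, per-mark q thresholds as above, motif z threshold 0.7, k = 10 for
FACS imputation, δ = 0.01 for velocity, seed 0, mark H3K4me1. Outputs are
TSV/Matrix Market/JSON with a manifest of per-file SHA-256 checksums;
reruns with the same config are bit-identical (asserted in tests).

## 10. Open design decisions

- Problem sizes in tests and the acceptance script (hundreds of regions,
  tens to hundreds of cells) are package choices tuned to finish in
  seconds while leaving the statistical properties testable; all sizes are
  parameters.
- The variational topic fit is a local optimum; seeds are fixed and tests
  assert recovery on well-separated data rather than global optimality.
- The shared ridge penalty assumes comparable noise across cells; per-cell
  penalties were rejected for identifiability and speed.
- Closed-form Poisson group MLEs replace iterative GLM fitting; this is
  exact for the one-factor-with-offset model used here and would need
  revisiting if covariates were added.

## 11. Limitations

- χ² p-values far in the tail (the 10⁻⁵⁰ threshold regime) rely on an
  asymptotic approximation that is untestable by simulation at feasible
  sample counts.
- Batch correction assumes batch effects are additive within clusters in
  latent space; interactions with continuous covariates are out of scope.
- Deconvolution assumes exactly two components and known reference
  profiles; it does not estimate profiles from the mixed cells.
- Pseudotime assumes a single linear trajectory; branching topologies are
  not modeled.
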
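# Methods

## Model

A mixture (one bulk sample or one spatial spot) is a non-negative
combination of cell-type expression profiles. With S the genes × types
signature matrix on the CP10K scale (every column sums to 10⁴), c the
per-type RNA-content coefficients and x the cell-number fractions, the
observed marker-gene vector is modeled as

    y_i = Σ_j c_j x_j s_ij + ε_i,    x_j ≥ 0,  Σ_j x_j = 1.

The product c_j x_j is the *RNA share* of type j. Fitting only relative
expression identifies shares, not x; the whole point of the c
coefficients is to convert shares into cell fractions.

### Signature construction

The reference count matrix (spike-in rows excluded) is summed per cell
type and column-normalized to CP10K, giving the full profile matrix S̃.
Markers are found per type by a one-vs-rest two-sided Wilcoxon rank-sum
test on log1p(CP10K) per-cell values; a gene is kept when
log2((mean CP10K in type + 1)/(mean in rest + 1)) ≥ 0.25 and its
Benjamini–Hochberg-adjusted p-value is below 0.01 (raw p selectable).
Within a type, markers are ranked by ascending p-value, ties broken by
descending fold change then gene id, for full determinism. Candidate
signatures take the union of per-type top-N markers for N ∈
{50, 100, 150, 200} (configurable); a gene that is a top marker for
several types occupies one matrix row but is recorded in every owning
marker set. The retained candidate is the one whose deconvolution
reconstructs the observed mixtures with the highest mean per-mixture
Spearman correlation (ties → smaller N). Per-mixture averaging, rather
than one pooled correlation over the flattened matrix, was chosen so
that no single deep mixture dominates the selection.

### Initialization: sectional linearity

If marker i belongs exclusively to type j, then y_i = c_j x_j s_ij, i.e.
log y_i = u_j + log s_ij with u_j = log(c_j x_j). For each type, u_j is
the intercept of the slope-1 log-log fit over its markers positive in
both vectors — the mean of log y_i − log s_ij. Types with fewer than
`min_markers` (default 3) usable markers get u_j = −∞ and start absent.
The softmax of u gives RNA-share estimates δ and the initial
reconstruction t = Sδ.

### Weights, capping, IRLS

Gene weights are w_i = 1/(|y_i − t_i|^β · t_i^(1−β))², with both factors
floored at eps = 10⁻⁸ so an exactly-fit gene keeps a finite weight. β
balances residual size against expression level: β = 1 is pure
robust-reweighting, β = 0 down-weights highly expressed genes. β is
selected per mixture from {0, 0.5, 1} by the Spearman correlation
between the reconstruction ŷ_i = Σ_j c_j x̂_j s_ij and y (ties prefer
larger β). When weight capping is enabled (recommended for
cross-technology mixtures, e.g. microarray vs an RNA-seq reference), the
cap q is the τ-quantile of the weights, τ searched over
{0.01, …, 1.00}; τ = 1 is the identity. Quantiles everywhere use type-7
linear interpolation.

Each IRLS iteration recomputes t_i = Σ_j c_j x_j s_ij from the current
proportions (un-normalized, so the residual responds to the c-weighted
scale), refreshes the weights, optionally caps them, and re-solves.
Convergence is ‖X⁽ᵗ⁾ − X⁽ᵗ⁻¹⁾‖₂ ≤ 0.01 (the norm is Euclidean by
choice), with a max_iter = 100 guard; non-convergence returns the last
iterate with a warning rather than failing.

### The constrained solve

The weighted problem is solved in z_j = c_j x_j, where the simplex
constraint becomes Σ_j z_j / c_j = 1. The equality is enforced inside
the optimization — appended to the non-negative least-squares system as
a heavily weighted row, then polished to machine precision by solving
the equality-constrained KKT system on the detected active set (falling
back to the penalized solution if the polish leaves the feasible cone).
Enforcing the constraint inside the solve, rather than normalizing
afterwards, matters: with post-hoc normalization the solution, the
weights and the reconstruction are all mathematically invariant to c,
which would make reconstruction-score-based selection of size
coefficients impossible.

A consequence of the hard constraint is scale sensitivity: a mixture
whose overall scale is inconsistent with Σ_j c_j x_j gets a
shape-distorting fit. Relative-abundance data (library-size-normalized
bulk, spatial spots) carries no scale information, so the pipeline entry
points calibrate each such mixture to the signature cone first (an
unweighted cone fit fixes the free scale; `calibrate_scale=True`).
Intensity-calibrated data — e.g. spike-in-normalized bulk, whose total
signal tracks mean RNA content per cell — is fitted at its native scale,
because there the deviation is real signal. Cell-size vectors are
rescaled to mean one at the pipeline boundary; only ratios matter.

### Cell sizes

*Spike-in estimator.* Per cell, endogenous counts are divided by the
75th percentile of that cell's ERCC counts (spike-ins are added in equal
amounts per cell, so their level is a purely technical yardstick); the
cell's absolute RNA content is the sum of the normalized endogenous
counts, and c_j is the mean over cells of type j. Cells with a zero
spike-in upper quartile are dropped. The estimator is invariant to any
per-cell sequencing-depth rescaling.

*Computational estimator* (no spike-ins), three stages per mixture:

1. **Screen.** Fit at uniform sizes, form the residual R = Y − SX̂, and
   compute the Spearman correlation ρ_j between R and each signature
   column. Types with |ρ_j| > 0.25 and initial proportion above 5% are
   flagged. Residuals at floating-point noise level are treated as
   carrying no rank information.
2. **Validate.** For each flagged type alone, scale its coefficient by
   1 + λ(1 − exp(−2(ρ_j − τ)/(ρ_max − τ))) over λ ∈ {0.5, …, 3} and keep
   the type only if some λ strictly improves the reconstruction
   Spearman. ρ_max is the largest flagged ρ (its magnitude when all
   flagged correlations are negative, so the saturation scale stays
   positive); signed ρ is used, so a negative correlation shrinks the
   coefficient, floored at 0.05. β is re-selected at each candidate
   coefficient vector — altering c changes which weighting regime fits
   best, and holding the baseline's β makes the score-vs-λ profile
   erratic.
3. **Joint optimization.** One shared λ ∈ {0, 0.5, …, 3} over the
   validated set, chosen by reconstruction score; λ = 0 reproduces
   uniform sizes, so the final score never falls below the baseline.

An identifiability caveat worth stating plainly: a noiseless
relative-scale mixture is *exactly* representable at uniform sizes (the
RNA shares lie on the simplex), so a single such mixture contains no
information about c at all and the λ = 0 fallback correctly returns
uniform sizes. The residual-driven procedure has signal only when the
mixture's scale or shape genuinely deviates from the uniform-size
model — intensity-calibrated mixtures being the clean case, which is what
the synthetic validation uses.

### Spatial enrichment gating

Spots hold few cells, so most types are absent from most spots. Per
gene, a fold change is computed against its cross-spot mean — or, for
markers of *prevalent* types (median absolute marker score above the
global 75th percentile and median relative score within 0.1 of one),
against its 25th percentile, since ubiquitous expression leaves
mean-referenced fold changes near one everywhere. Per spot and type,
Z = (f_j − μ)√n_j/σ, where f_j averages the fold changes of the type's
expressed markers (expression > 0), n_j counts them, and μ, σ are the
mean and sample standard deviation of the spot's fold changes over all
genes of the mixed-reference matrix (one pass, no re-referencing).
A type is enriched if Z > 0, if it has the spot's top Z (ties all kept —
this criterion guarantees a non-empty set), or if its per-spot
standardized Z is positive. Deconvolution then runs per spot on the
signature restricted to the enriched types; non-enriched types get
exactly zero. Cell-size correction is off by default for spatial runs.
Spots are processed independently; no spatial smoothing.

## Synthetic data

The generator is the package's test bed and defines its study
conditions. Each cell type's expected profile is a shared log-normal
baseline with a disjoint block of planted markers multiplied by
`marker_strength` (default 8×, `marker_frac` = 5% of genes). A cell of
type j draws Poisson counts around profile × base_counts (2000) ×
content_j × a per-cell log-normal capture efficiency (sd 0.3). Spike-in
rows receive a fixed expected total (500) scaled only by capture
efficiency — equal spike-in input per cell. Bulk mixtures are
Σ_j x_j c_j p_j with optional per-gene log-normal noise, emitted either
CP10K-normalized ("cp10k") or with totals tracking mean RNA content per
cell ("content", emulating spike-in-calibrated bulk). Spatial spots sum
real cell count vectors on a grid (pure / layered / Dirichlet-random
patterns), optionally multinomially downsampled to a target depth
(1500 in the spatial benchmarks, mimicking shallow spot capture).

What the generator does *not* emulate: ambient RNA, doublets, batch
chemistry, gene-length bias, platform-specific saturation (available
only as an optional `saturation` knob, off by default), or biological
heterogeneity within a type. Passing benchmarks on this generator shows
the estimator mechanics are correct under the stated model, not that
real cross-platform data will behave as cleanly.

## Benchmark design and problem sizes

The experiment battery (`celldecon.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) uses a few hundred
genes, 30–50 cells per type and 20 seeds per condition — sizes chosen so
the full battery completes in minutes while every qualitative effect
remains measurable. Highlights:

- noiseless mixtures y = S diag(c) x are recovered to solver precision
  for K ∈ {2, 3, 5};
- the constrained weighted solve never loses to a 0.01-step simplex
  grid search;
- uniform-size fits overestimate a large type monotonically in the
  content ratio (2, 4, 6.5), and spike-in-estimated sizes remove ~95%
  of the mAD;
- a true 4× content ratio is recovered from spike-ins within a fraction
  of a percent on average (sd-0.3 capture noise, 100 cells/type);
- the residual screen flags a planted size-inflated type essentially
  always on intensity-calibrated mixtures, and the Stage-3 score never
  drops below baseline;
- signature from one reference draw deconvolves noisy mixtures from an
  independent draw at R ≈ 0.998 (K = 5);
- on 200-spot grids, pure spots are assigned perfectly, mixed spots
  reach R ≈ 0.9, and the 6-nearest-neighbour variance of the estimates
  localizes the layered tissue's heterogeneity at R ≈ 1.

## Known limitations

- **Partial computational size correction.** On two-type
  intensity-calibrated mixtures the residual-driven correction reduces
  proportion mAD by roughly 27–58% depending on the ratio, short of
  halving it uniformly. Two mechanical reasons: the scale factor
  saturates at 1 + 3(1 − e⁻²) ≈ 3.59, so a 6.5× content ratio cannot be
  fully undone; and when both types are abundant both get flagged with
  positive residual correlations, compressing the corrective *ratio*.
  When spike-ins are available the direct estimator is strictly better;
  prefer it.
- Cell sizes are per type, not per cell or per gene; a type whose size
  varies across states is averaged.
- The marker test assumes exchangeable cells within a type; donors are
  not modeled as a random effect.
- Enrichment gating zeroes genuinely present minor types in mixed spots
  by design; ungated deconvolution scores higher on dense simulated
  spots but transfers worse to sparse real spots.
- β, cap and size selection all maximize reconstruction Spearman, a
  rank statistic: on very few markers (< ~30 genes) its resolution
  limits model selection.
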
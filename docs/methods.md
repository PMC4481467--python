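# Methods

## Model and estimation protocol

The regional association model treats the dosages of `m` ordered
variants as discrete observations of a continuous genotype function on
the scaled region [0,1], and the per-position effect as a smooth curve
β̃(t) = ψᵀ(t)β_F on `K_β` basis functions.  With a GVF basis the
working design is `GW`, `W = Φ(ΦᵀΦ)⁻¹W₂`, `W₂ = ∫₀¹φ(t)ψᵀ(t)dt`; with
effect-smoothing only it is `GΨ`.  Relatedness enters through the
polygenic random effect `h ~ N(0, σ_h²R)` with `R = 2 × kinship`, so a
sample of unrelateds reduces to ordinary fixed-effects regression and
σ_h² is the additive polygenic variance in the usual sense.

Estimation follows a two-stage protocol: the null model
`y = Xα + h + e` is fitted once per phenotype by maximum likelihood
(not REML), and α̂ and Ω̂ = σ̂_h²R + σ̂_e²I are then held fixed for every
region.  The fit eigendecomposes `R = UDUᵀ` once and profiles the
likelihood in h² = σ_h²/(σ_h²+σ_e²): given h², α and the total variance
have closed forms in the rotated frame, and h² is found by a coarse
grid (9 points) followed by bounded Brent search on [0, 1−10⁻⁶] with
tolerance 10⁻⁸.  Boundary solutions are accepted, and the h² = 0
boundary is preferred on ties so that `R = I` yields the OLS solution.
REML is available behind a flag (`fit_null(..., reml=True)`); on the
default sample it moves ĥ² by O(1/n).  ML carries a small downward
bias in ĥ² (≈ 0.007 at n = 688 with an intercept-only design); REML is
unbiased to Monte-Carlo precision.

## Test statistics

All statistics whiten with Ω̂^{-1/2} through the cached
eigendecomposition, so weighted sums of squares are ordinary sums of
squares of whitened vectors (verified against dense Ω⁻¹ algebra in the
tests).  For a region with effective whitened design Z (rank r):

- **F**: `RSS₀ = (y−Xα̂)ᵀΩ̂⁻¹(y−Xα̂)`; β_F is the GLS estimate on Z;
  `F = ((RSS₀−RSS₁)/r)/(RSS₁/(n−r−1))`, referred to F(r, n−r−1).
- **LRT**: the fixed-Ω Gaussian profile form `n·log(RSS₀/RSS₁)`,
  referred to χ²_r (a full H₁ variance refit is available behind
  `lrt_refit=True`).
- **Score**: `UᵀV⁻¹U` with `U = ZᵀΩ̂^{-1/2}(y−Xα̂)` and V the
  covariate-projected variance `ZᵀZ − ZᵀX̃(X̃ᵀX̃)⁻¹X̃ᵀZ`, referred to
  χ²_r.

**Covariate projection.**  By default the tested design is projected
onto the orthocomplement of the whitened covariates before the GLS fit
(`TestConfig(project_covariates=True)`).  Fitting β_F against raw null
residuals without this projection double-counts the overlap between
`GW` and `X` and makes the F-test conservative — measured at about
0.9× the nominal level on the default null protocol even with Ω known,
versus 1.00× with the projection.  The projection is algebraically the
same as estimating α jointly under H₁, while α̂ and Ω̂ themselves are
never re-optimized; the unprojected variant remains available for
comparison.  The score test uses the matching projection in its
variance, since ignoring α estimation there inflates the type I error.

**Degrees of freedom.**  The denominator df is `n − r − 1` with r the
effective rank; the covariate count is not subtracted (the conservative
`n − r − c − 1` convention is behind `df_subtract_covariates=True`).

## Basis systems and K reduction

Fourier is the orthonormal system {1, √2 sin(2πkt), √2 cos(2πkt)}, K
odd; B-splines are cubic with K−4 equally spaced interior knots and
repeated boundary knots.  Cross-integrals W₂ use composite
Gauss–Legendre quadrature (20 nodes per piece) on the union of the
spline knot partitions, refined so at most about one oscillation of the
trigonometric factors falls in each piece; entries agree with adaptive
quadrature to 10⁻¹⁰.

Requested K (defaults 15 B-spline / 25 Fourier) is reduced per region:
capped at m, Fourier to the largest odd value, B-spline to at least 4,
and K_β ≤ K_G when a GVF basis is present.  Two further rules handle
degeneracies the basic cap cannot:

- at K = m the model is replaced by the saturated multiple-regression
  mixed model on the raw dosages, to which it analytically reduces;
- a GVF evaluation matrix Φ that is rank-deficient at the observed
  positions (clustered variants can violate the spline interleaving
  condition, and the periodic Fourier rows at t = 0 and t = 1 always
  coincide) triggers stepwise reduction of K_G (B-spline −1, Fourier
  −2) until ΦᵀΦ is invertible, saturating as a last resort.

Rank deficiency of the final design (duplicated rare-variant dosage
patterns are common) is handled by pivoted-QR column dropping at
tolerance 10⁻⁸ × leading singular value; the effective rank is the
reported df₁.  Regions reduced to one variant fall back to a Wald test
of the single dosage.  Exact position ties are separated by even
spacing between the neighbouring distinct scaled values; a region whose
variants all share one coordinate is mapped to an even grid on [0,1]
(the affine map is undefined there); a single variant maps to t = 0.5.

## Synthetic data generator

The generator emulates a mini-exome family study and defines the
conditions under which the statistical claims are checked:

- **Pedigrees**: 8 three-generation families — founder couple, 7
  married children (spouses are founders), 10 grandchildren per couple
  — 86 individuals each, n = 688 in total, emulating a ~700-individual
  eight-family sample.  The relationship matrix comes from the standard
  kinship recursion.
- **Genotypes**: per region, H = 100 pool haplotypes carry alleles at
  target frequencies drawn from Beta(0.2, 20) truncated to
  [0.001, 0.35]; allele counts in the pool are clipped to at least one
  carrier so the rare tail survives the polymorphism filter.  Founder
  haplotypes sample the pool with replacement (this sharing creates
  within-region LD) and whole haplotypes are gene-dropped through the
  pedigree — a gene-sized region essentially never recombines within a
  family, so no recombination is modelled.  Realized sample MAFs have
  median ≈ 0.016 (range ≈ 0.001–0.35).  The Beta parameters were
  calibrated once against the generator's stated target spectrum
  (median ≈ 1%, range 0.1%–35%) and are scenario-configurable.
- **Mini-exome**: 1,702 regions with sizes 2–60, geometric with mean
  ≈ 7.4, matching ~12,600 variants over ~1,700 gene regions.
- **Traits**: y = Gβ + h + e with var(h)/(var(h)+var(e)) = h² = 0.29
  and unit non-genetic variance; h is drawn through the
  eigenfactorization of R.  Causal variants are ⌈causal_fraction·m⌉
  uniform draws (restricted to MAF ≤ 0.03 under `rare_only`), with
  |β| = ln(c)|log₁₀MAF|/2 and sign + with probability
  `unidirectional_fraction`.

What the generator does **not** emulate: recombination and
mutation within regions, population stratification between families,
covariate structure (age/sex effects are supported in the model but the
simulated X is an intercept), non-Gaussian trait noise, and
genotyping error.  Calibration and power results under these
conditions therefore demonstrate correctness of the statistical
machinery on idealized family data, not robustness to real-data
artefacts.

## Experiment drivers and problem sizes

`run_type1_experiment` fixes the sample and region set, redraws null
traits, refits the null model per replica, and pools regional F-test
p-values; the per-region rotated designs are precomputed once so a
replicate costs O(n²) for the trait plus O(n·r²) per region.  The
package's own calibration runs use 12–60 replicas × 1,702 regions
(2×10⁴–10⁵ pooled tests), sizes chosen to make the binomial error bands
a small fraction of the nominal levels while keeping a run in the
minutes range on one CPU.  `run_power_experiment` fixes one 50-variant
region and redraws traits (200–1,000 replicas per scenario point);
with `paired=True` causal sets, signs and noise are common random
numbers across the scenario grid, so power comparisons along c or the
unidirectional fraction are paired and the Monte-Carlo ordering noise
largely cancels.  Power uses the exome-wide threshold 2.5×10⁻⁶.

## Numerical notes

- Eigenvalues of R are clipped at 0 (PSD up to roundoff); σ_e² > 0 is
  guaranteed by the h² < 1 bound, so Ω is always invertible.
- Batched and per-region code paths share the same projection and rank
  rules and agree to machine precision (tested).
- Constant phenotypes, rank-deficient covariates, monomorphic regions
  and non-finite inputs raise immediately with specific messages;
  per-region failures inside `run_genome` become NA rows and the run
  continues.
- All experiment randomness flows from one seed through
  `numpy.random.SeedSequence` spawning, so every table in the README
  and tests is reproducible.
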
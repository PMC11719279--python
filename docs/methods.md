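# Methods

This note states the quantities `mipca` computes and the conventions it
commits to, in the order the pipeline applies them.

## 1. Genotype input and additive encoding

A cohort is an `m x n` matrix `G` of `m` samples typed at `n` biallelic
SNPs. Entry `G[i, j] ∈ {0, 1, 2}` counts copies of the locus's **minor
allele** — the allele that is rarer *in this cohort*; exact frequency ties
break to the lexicographically smaller allele label, so encodings are
deterministic. VCF input (via `cyvcf2`) keeps only biallelic SNP records,
treats half-calls as missing, and flips the ALT dosage whenever ALT is the
cohort's major allele. PLINK `traw` input likewise flips any locus whose
`COUNTED` allele is the majority. Missing genotypes are `NaN` carried in an
explicit mask.

QC runs in a fixed order, each locus removed at the first test it fails:

1. missingness rate > `missing_max` (default 0.10),
2. monomorphic in the cohort,
3. minor-allele frequency < `maf_min` (default 0.01),
4. Hardy–Weinberg equilibrium Pearson chi-square (1 df, expected counts
   `p², 2pq, q²` from the sample allele frequency) with p-value below
   `hwe_alpha` (default 1e-6).

Remaining missing entries are imputed by the locus mean before
standardization.

## 2. Standardization and decomposition

Each **sample row** is centered by its mean (divisor `n`) and scaled by its
standard deviation (divisor `n − 1`), giving `Z` with `mean(z_i) = 0`,
`sd(z_i) = 1`. The sample correlation matrix is `C = Z Zᵀ / (n − 1)`.

The thin SVD `Z = U S Vᵀ` gives the eigenpairs of `C` without forming it:
`λ_j = S_j² / (n − 1)`, eigenvectors the columns of `U`. Component scores
(rows of `P = Uᵀ Z`) satisfy `cov(P) = diag(λ)`. Eigenvector signs are fixed
by making each column's largest-magnitude entry positive. Eigenvalues below
`1e-12` relative to the largest are flagged null and their axes zeroed.

**Loadings identity.** With the whitened (matrix-normalized) correlation

```
M = [cov(Z, Zᵀ)]^(-1/2) · cov(Z, Pᵀ) · [cov(P, Pᵀ)]^(-1/2)
```

one has `M = U` identically; `correlation_loadings` computes `M` through
this definition and verifies the identity to `1e-8` at runtime. Note the
*entrywise* Pearson correlation is `cor(z_i, p_j) = √λ_j · U_ij`, not
`U_ij`; only the matrix normalization removes the `√λ_j` factor. A unit
test documents this distinction.

An alternative `snp` centering mode (column centering) is provided; there
`1ᵀZ = 0` forces per-axis score sums to zero, a property that does **not**
hold under row centering.

## 3. The signed information rescaling

For bivariate Gaussians, mutual information is `I(ρ) = -½ log(1 − ρ²)`
(nats; divide by `log 2` for bits). The **signed rescaling**

```
r(ρ) = -sgn(ρ) · ½ log(1 − ρ²)
```

is odd, strictly increasing, and has `|r(ρ)| = I(ρ)`. Applied entrywise to
the loadings `U`, it yields the information map with coordinates
`r(U_ij) · √λ_j` alongside the conventional `U_ij · √λ_j`. Because `r` is
strictly monotone, per-axis sample order is preserved exactly; distances,
however, become information-valued: coordinates contract below
`|ρ| ≈ 0.96` and expand beyond it. `|ρ| = 1` is clamped to `1 − 1e-12`
with a warning (or raises in strict mode).

**Heavy tails.** For the elliptical bivariate Student-t with tail
parameter `α`, `I_t(ρ, α) = -½ log(1 − ρ²) + λ_α` with a ρ-independent
excess

```
λ_α = (α+1)[ψ((α+1)/2) − ψ(α/2)] + log α + 2 log B(α/2, ½) − log 2π − 1 − 2/α,
```

which vanishes as `α → ∞`. The implementation evaluates the equivalent
harmonic-number/cosecant form at 50 decimal digits (`mpmath`) because in
double precision the `csc(πα)` term loses ~6 digits near integer `α`; the
digamma form above serves as the independent cross-check in tests.

**Estimators.** `empirical_mi` provides the Kraskov–Stögbauer–Grassberger
kNN estimator (algorithm 1, Chebyshev metric, deterministic — no noise
injection) and a Freedman–Diaconis binned plug-in with Miller–Madow bias
correction.

## 4. Cluster separation and the critical threshold

Let two clusters have center-of-mass correlations `0 < ρ₁ ≤ ρ₂ < 1` with a
component of eigenvalue `λ`, pooled within-cluster standard deviation `σ`
on that axis. The linear separation is the 1-D Mahalanobis distance
`Δμ = |μ₂ − μ₁| / σ`. The normalized squared MI-scaled distance is

```
(σ²/λ) · Δμ̃² = ¼ [ln((1 − ρ₂²)/(1 − ρ₁²))]² = (r(ρ₂) − r(ρ₁))²,
```

to be compared with the normalized linear square `(ρ₂ − ρ₁)²`. For nearby
centers their difference linearizes to

```
(ρ₁²/(1 − ρ₁²)² − 1) · (ρ₂ − ρ₁)²,
```

whose coefficient changes sign at the **critical threshold**

```
ρ* = sqrt((3 − √5)/2) = 0.6180339887…  (the inverse golden ratio),
```

the positive root of `ρ² = (1 − ρ²)²`. Below ρ\* the information scale
*contracts* cluster gaps; above it, it *expands* them. A one-tailed
Fisher-z gate test, `z = (atanh(r) − atanh(ρ*)) √(n − 3)`, assesses whether
an estimated center correlation credibly exceeds ρ\*.

**Estimating ρ_k.** The primary estimator correlates each cluster's mean
standardized genotype row with the component score vector (one observation
per locus), which can reach the high-correlation regime. Averaging member
loadings is available as a fallback when only an embedding table exists,
but since loadings of an orthonormal column are `O(1/√m)`, that route
cannot approach ρ\* for realistically sized panels. Axis orientation being
conventional, both-negative center correlations reflect the axis; mixed
signs are rejected.

## 5. Synthetic cohorts and checks

The Balding–Nichols generator draws, per locus, an ancestral frequency
`p ~ U(0.05, 0.5)` (configurable), a per-population frequency
`p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)` — mean `p`, variance
`F_k p(1−p)`, so `F_k` is the population's FST — and genotypes
`Binomial(2, p_k)`. Per-locus streams are spawned from a root
`SeedSequence`, making any locus subset independently reproducible.

The divergence is recovered from output by the Hudson FST estimator
(ratio of averages, averaged over population pairs). The expected count of
segregating sites is computed as `4 N_e μ Σ_{k=1}^{N} 1/k`; the sum runs to
`N` as specified upstream, although Watterson's estimator conventionally
stops at `N − 1` — the difference is a single term `1/N`.

## 6. Units and reproducibility

All information quantities carry an explicit unit (`nats` or `bits`;
conversion is division by `ln 2`, applied only to information-valued
columns). Embedding TSVs store coordinates, raw loadings, eigenvalues and
the unit at 17 significant digits and round-trip losslessly. Every CLI run
writes a JSON manifest with the full configuration; identical inputs and
seeds produce byte-identical outputs.
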
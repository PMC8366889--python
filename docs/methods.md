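# Methods

This note documents the models, estimators and design choices in
`crowntraits`, in the spirit of a package vignette: what is computed, under
which assumptions, and what a green test does and does not establish.

## 1. Trait retrieval

**Biochemical traits.** Crown spectra are the per-band arithmetic mean of
all sun-lit pixels whose centroid falls inside (or on the boundary of) the
crown polygon. A pixel counts as shaded when its mean reflectance over
780–850 nm falls below a threshold (default 0.15); shade weakens the signal
multiplicatively, so a pure NIR-level test separates it cleanly. The three
indices are narrow-band formulas on nearest-available bands (±10 nm lookup
tolerance, errors name the missing band):

| trait | formula | bands (nm) | units |
|---|---|---|---|
| CHL | (R₇₅₀−R₇₀₅)/(R₇₅₀+R₇₀₅) | 750, 705 | unitless, (−1, 1) |
| CAR | 1/R₅₁₀ − 1/R₅₅₀ | 510, 550 | 1/reflectance |
| LWC | (R₈₆₀−R₁₂₄₀)/(R₈₆₀+R₁₂₄₀) | 860, 1240 | unitless, (−1, 1) |

The index registry is a plain dict; replacing an entry swaps the formula
without touching the pipeline. A non-positive denominator yields an explicit
missing value, never a silent zero.

**Architectural traits.** Returns are assigned to the crown polygon that
contains them (ties between overlapping crowns go to the nearest crown
centre). CH is the maximum non-ground return height — a percentile variant
exists but is off by default. PAI inverts the Beer–Lambert gap fraction:
gap = (returns below 2 m)/total, floored at 1/(2·total) so closed canopies
stay finite; PAI = −ln(gap)/k with extinction coefficient k = 0.5; at least
10 returns are required. FHD is the Shannon entropy of non-ground return
counts in 5-m layers indexed from the terrain up to the crown's top return.

**Environment per crown.** Numeric covariates take the mean over pixel
centroids inside the polygon; categorical covariates the median of their
ordinal codes with ties resolved to the lower code (aspect is coded
N=1 … NW=8; circularity is deliberately ignored to match the aggregation
rule the analysis is built around). Crowns containing no centroid fall back
to the nearest pixel with a warning.

## 2. Variance partitioning

`TraitVarianceModel` fits a general linear model by block Gram–Schmidt
orthogonalisation in the fixed term order: class, species, the environmental
block (soil type, soil rocks, soil depth, PAR, aspect, elevation, slope,
curvature, herbs, understory — the order matters and is documented because
Type-I SS depend on it), class×{PAR, elevation} and species×{PAR, elevation}
interactions, then the 90-m and 40-m occupied-grid-cell factors. Each term's
SS is the drop in residual SS when the term joins the model; the shares are
additive by construction. Rank detection via SVD gives aliased terms 0 df
and 0 SS with a flag instead of an exception. F statistics test each term
against the residual mean square.

Backward elimination removes, one at a time and refitting in between, the
least significant removable term with p > α (default 0.05). Class and
species are never removed, and a main effect is not removable while any
interaction containing it remains (marginality).

The multivariate variant standardises each trait to unit variance, fits the
six sequential models on complete cases, and sums SS per term; %SS is taken
against the summed total. This is a deliberate, clearly-labelled surrogate
for a MANOVA variance share: it weights traits equally, keeps additivity,
and is invariant to trait units.

**df-aware recovery expectation.** A fitted Type-I model absorbs i.i.d.
residual variation into every fitted degree of freedom (expected SS
σ²·df), so the fitted residual share is biased low by df_model/(n−1) — a
property of least squares, not an estimation error.
`expected_recovered_shares` converts generative shares into the expectation
of the fitted shares; recovery tests compare against that.

## 3. Phylogenetic distances

The F84 model (unequal base frequencies, distinct transition/transversion
rates) has the closed-form pairwise ML distance

    A = π_C π_T/π_Y + π_A π_G/π_R,  B = π_C π_T + π_A π_G,  C = π_R π_Y
    d = −2A ln(1 − P/2A − (A−B)Q/2AC) + 2(A−B−C) ln(1 − Q/2C)

from the observed transition (P) and transversion (Q) proportions over
pairwise-complete sites (gaps/N excluded per pair) and empirical base
frequencies estimated once from the whole alignment. This estimator is the
exact ML solution of the identical/transition/transversion trinomial
likelihood jointly over distance and the transition/transversion parameter —
the test oracle maximises that likelihood numerically with matrix
exponentials and agrees to < 1e-8. At equal frequencies the formula reduces
to the K80 two-parameter distance. Note that PHYLIP's DNADIST instead
conditions on a user-fixed ratio; because the closed form estimates the
ratio implicitly per pair, no ratio parameter is needed here. Saturated
pairs (non-positive log arguments) report an infinite distance with a flag.

Bootstrap CIs resample alignment columns with replacement (the same column
draw for all pairs within a replicate) and take 2.5/97.5 percentiles over
replicates. Rescaling of any distance matrix is the linear min–max map of
the off-diagonal entries to [0, 1]; it is idempotent, order-preserving, and
undefined (an error) for constant matrices.

## 4. Species distances and Mantel tests

Species with at least `min_n = 10` individuals enter the between-species
analyses; with the stand's mapped counts this retains exactly 8 of the 13
species (the largest excluded species has 9 individuals). Species trait
means are computed over non-missing values; species mean spectra weight
each crown equally. Trait distances: each trait min–max rescaled across
species, Euclidean distance, then matrix-rescaled to [0, 1]. Spectral
distances: Euclidean over bands in half-open windows [low, high) — VIS
400–700, NIR 700–1,300, SWIR 1,300–2,500 nm — so shared endpoints count
once; bands are used raw by default (a per-band standardisation switch
exists).

The Mantel statistic is the Pearson correlation of the strictly-lower
triangles; rows and columns of the second matrix are permuted jointly, and
the one-sided (greater) p-value uses the add-one estimator
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) with a fixed seed. Under
independence the p-values are uniform on the permutation lattice, which the
calibration test checks by Kolmogorov–Smirnov over 1,000 seeds.

## 5. Discriminant assignment

Classic equal-covariance Gaussian LDA: class means, pooled within-class
covariance (ridge ε·trace/p added if the condition number exceeds 1e8),
priors proportional to class frequencies by default (uniform optional).
Crowns are assigned to the arg-max log posterior. Accuracy is reported for
resubstitution *and* leave-one-out, because resubstitution is optimistically
biased — visibly so on permuted-label noise, where only LOO sits at 1/k.
Only the eight abundance-filtered species are used by default.

## 6. The synthetic stand

The generator is a stated world, fixed once:

* 13 species with the mapped relative abundances (0.396, 0.193, 0.129,
  0.083, 0.080, 0.040, 0.033, 0.030, 0.007, 0.006, 0.002, 0.001, 0.001 —
  the printed percentages round their counts slightly unevenly and sum to
  1.001; they are normalised internally), three of them conifers.
* Environmental ranges: elevation 655–810 m (south→north ramp), PAR
  525–8,414 W m⁻² day⁻¹ (smooth random field clipped to range), slope
  3.9–58.4°, curvature −0.387–0.287 (smooth fields), and categorical
  aspect/soil/understory/herb layers in ~30-m patches.
* 2-m pixels, 284 bands spanning 400–2,424 nm, 40 returns/m².
* Crowns are circles (lognormal radii ≈ 1.8–4.5 m) placed by dart-throwing
  with at most 10% pairwise overlap, on a 260×260 m scene. The real 5.5-ha
  stand is denser than circle packing allows, so the synthetic stand is
  slightly sparser; crown counts and abundances are preserved.
* True traits follow mean + slopes·covariates + species-specific PAR-slope
  deviations + 90-m and 40-m cell effects + Gaussian residual. Component
  SDs were solved analytically — once, before any test was run — from
  qualitative aggregated shares (taxonomy ≈ 15–28% for biochemical, ≈ 4–8%
  for architectural traits; environment ≈ 30–40% for PAI/CH; spatial
  ≈ 12–13%): e.g. the species-mean dispersion is total_SD·√share with a
  fixed species pattern standardised to abundance-weighted unit variance.
  The within-species trait SD per species is not known from data and is a
  calibration choice, flagged here.
* Grid-cell effects are drawn orthogonal to the numeric environmental
  covariates: the grids represent spatial variation *not explained* by
  environment, and because the covariate fields are themselves spatially
  structured, raw cell effects would otherwise leak into the earlier-fitted
  environmental terms under Type-I ordering.
* Forward models are exactly invertible: index-band reflectances are solved
  per crown from the target CHL/CAR/LWC on a smooth class-specific leaf
  template; one lidar return is pinned at CH; ground returns are Binomial
  with probability exp(−k·PAI); canopy returns follow a geometric-family
  5-m-layer mixture whose entropy equals the target FHD (canopy heights are
  kept above the 2-m ground cutoff so PAI sees only true ground returns).
  Shaded pixels are scaled by 0.2 and labelled.
* `truth_partition` is the sequential projection of each trait onto the
  realised generative component vectors (taxonomy → environment →
  interaction → spatial, residual as remainder) — the exact %SS structure
  the recovery tests compare against.
* A synthetic 13-taxon alignment evolves by F84 (κ = 2) along a fixed
  class-consistent tree (topology invented; only the conifer/angiosperm
  split is meaningful), so the Mantel stage has a self-contained,
  positively-correlated phylogeny.

**What the generator does not emulate:** radiative transfer and BRDF or
topographic illumination, irregular crown shapes, multi-date phenology,
spatially autocorrelated residuals beyond the two grids, DTM errors, or
sensor noise structure beyond i.i.d. Gaussian reflectance noise. A green
recovery test therefore establishes correctness of the estimators and
plumbing, not field validity of the retrieval formulas.

## 7. Numerical choices and degenerate inputs

* Nearest-band lookup ±10 nm; beyond that, a named error.
* Gap fraction floored at 1/(2·total); PAI ≥ 0 by construction.
* Aliased ANOVA terms: 0 df/0 SS, flagged, never an exception; %SS
  additivity holds to 1e-9.
* Rescaling a constant distance matrix, a Mantel test with < 3 labels or
  zero triangle variance, fewer than 3 retained species, fewer than 2
  classes with ≥ 2 complete cases — all explicit errors.
* Two-species distance matrices cannot be meaningfully rescaled to [0, 1];
  the pipeline requires ≥ 3 species.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces every artifact bit-identically (content hashes
  in the run manifest).

## 8. File formats

GeoJSON crowns; ENVI (BSQ float32 + text header with wavelengths and map
origin) cubes; CSV point clouds (x, y, height_above_ground, is_ground);
CSV trait tables with explicit NA; PHYLIP square distance matrices; FASTA
alignments (underscores in files stand for spaces in taxon names); YAML
generator configs; JSON manifests. Every writer has a matching reader and
round-trips.

## 9. Known limitations

* The multivariate partition is a standardised-sum surrogate, not a
  Pillai/Wilks MANOVA; it is labelled as such everywhere.
* Aspect's circular nature is ignored by the ordinal-median rule; "median"
  for nominal soil classes may equally well have been intended as mode.
* Resubstitution accuracy overstates separability; prefer the reported
  leave-one-out figure.
* With overlapping crowns, returns in shared lens regions are assigned to
  one crown by centroid proximity; exact CH recovery is only guaranteed at
  zero overlap.
* Mixed-effects variance components are intentionally out of scope; the
  partition is fixed-effects %SS, whose order dependence is documented and
  tested rather than hidden.
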
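# Methods

This note documents the statistical models, estimators and design choices
behind `spudgwas`, and what the synthetic panels used by the test suite do
and do not establish about real data.

## Data model

A panel is a markers × samples matrix of autotetraploid allele dosages
(integers 0–4) with an explicit boolean missing mask; the file sentinel is
the literal string `NA`.  Marker metadata carry a chromosome (1-based bp
positions) and a genome-region class derived from per-chromosome
pericentromeric heterochromatin boundaries; the boundary interval is
inclusive on both ends, so a marker at `het_start` or `het_end` is
heterochromatic, and a pericentric chromosome (`het_start = 1`) simply has
no short arm.  Phenotypes are per-clone BLUEs (one column per trait,
missing allowed); samples are aligned by identifier everywhere.

## QC and diversity

Allele frequency is `sum(dosages) / (4 × called samples)` over non-missing
calls only.  The marker filter retains `missing_rate < 0.20` **and**
`MAF > 0.05`; both boundaries are excluded, so a marker at exactly 20%
missing or exactly 5% MAF is removed.  Two PIC variants are provided:
expected heterozygosity `1 − p² − q²` (default, maximum 0.5) and the
Botstein form `1 − p² − q² − 2p²q²` (maximum 0.375 for biallelic markers).
Both are exposed because reported PIC ranges for biallelic SNP panels often
reach 0.5, which only the heterozygosity form can produce; the choice is a
config switch.  Near-duplicate clones are flagged when their Gower
similarity strictly exceeds 0.99.

## Kinship and structure

The genomic relationship matrix is the Gower similarity
`S_ij = mean over shared markers of (1 − |d_i − d_j|/4)`, a [0, 1]
similarity with unit diagonal, computed pairwise-complete under
missingness.  It is used directly (unscaled, uncentred) as the kinship `K`
of the mixed model.

Structure covariates come from three sources. PCA: eigenvectors of the
double-centred relationship matrix, eigenvalue-ordered, with a
deterministic sign convention (centring is a config dialect; uncentred is
available).  nMDS: SMACOF majorization with isotonic regression on
dissimilarity ranks (Kruskal stress-1), initialised from the classical
(Torgerson) scaling solution so the result is deterministic; random
restarts are seeded and opt-in.  The default dissimilarity is the Euclidean
embedding `D_ij = sqrt(S_ii + S_jj − 2S_ij)`, which is a valid metric for
any positive semi-definite similarity; `1 − S` is a selectable dialect.
External membership matrices (for example from a model-based clustering
tool) are read from TSV.  The stress screeplot (`nmds_scan`) reports stress
per dimension and suggests the largest-second-difference elbow, but the
dimension choice is left to the analyst.

Hierarchical clustering follows the `ward.D2` convention (Ward variance
criterion applied to the supplied distances, scipy's `ward` on a condensed
matrix), with merge heights non-decreasing; dendrograms export to Newick
with height differences as branch lengths.  Differentiation uses Nei's
(1972) standard distance on per-subpopulation allele frequencies and
Hudson-style Fst as a ratio of marker-averaged numerators and denominators
with the finite-sample frequency-variance correction (allele count = 4 ×
called samples), which is close to unbiased under Balding–Nichols
divergence.

## Mixed-model GWAS

The model is `y = Xβ + sα + Qv + u + ε` with `Var[u] = σ_g²K` and
`Var[ε] = σ_e²I`; `s` is the raw additive dosage 0–4 of the tested marker.
Four variants: Naive (no `Q`, no `K`), K, Q, QK.

Variance components are estimated by restricted maximum likelihood,
profiling the ratio `δ = σ_e²/σ_g²` on the spectral decomposition of `K`
(eigenvalues clipped at zero; an indefinite `K` beyond tolerance is an
error): an 81-point grid over `log δ ∈ [−10, 10]` followed by bounded local
refinement, which is deterministic and was verified against a brute-force
two-parameter restricted-likelihood optimizer to ~7 significant digits.

Marker tests use P3D by default: the null-model `(σ_g², σ_e²)` are fixed
and every marker is tested by generalized least squares in the eigenbasis
of `K`, vectorized across markers.  Missing dosages are mean-imputed per
marker for testing only; markers monomorphic after imputation are omitted
with a reason.  Inference is a two-sided Wald t test with
`df = n − rank(X) − 1`, chosen for finite-sample calibration at n ≈ 300;
an exact per-marker REML refit is available for verification on small
panels.  Samples missing the trait are dropped per trait with `K` and `Q`
subset accordingly.  With `K = I` (or the Naive/Q variants) the scan is
numerically identical to ordinary least squares.

Two known P3D properties worth remembering: a strong QTL inflates the null
σ_g² and therefore attenuates its own score relative to an exact refit; and
putting kinship eigenvectors into `Q` can drive the QK REML to the
`σ_g² = 0` boundary (the QK model then collapses onto Q), the over-fitting
regime in which Q-containing models become conservative.

Model fit per trait is summarised by λ_GC = median(qchisq(1−p, 1))/0.4549364231.
λ_GC is a sample median: at ~2000 markers its null sampling sd is ≥ 0.05
even for independent markers, so calibration claims are made about means
over replicate panels, not single draws.  Models are ranked by ascending
|λ_GC − 1| (deflated models rank by the same closeness-to-1 rule), ties
broken toward the smaller λ and then by name.  Q-Q tables pair sorted
observed −log10 p with expected quantiles `(i − 0.5)/m`; hits are markers
whose score strictly exceeds `−log10(α/m)` (α = 0.05 genome-wide), with the
per-trait top hit flagged.

## LD decay

LD is the squared Pearson correlation of dosage vectors over jointly called
samples (at least 30 shared calls per pair, pairwise-complete), always
intra-chromosomal, partitioned into short arm, long arm, euchromatin (both
arms, cross-arm pairs included), heterochromatin, and whole chromosome.
Distances are |Δbp|/10⁶ Mb; co-located pairs are excluded from fits.

The decay curve is fitted to the 90th percentile by minimizing the pinball
loss at τ = 0.9 over a deterministic multi-start grid refined with
Nelder–Mead.  The default functional form is the Hill–Weir drift
expectation with `C = a·d` and a fitted amplitude,

    E[r²] = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],

with `n` the (median) shared-sample count; `r0·exp(−d/δ)` is the
alternative form, and both are recorded in the output metadata because the
functional form behind published quantile-regression LD fits is rarely
stated.  From the fitted curve: `r²_max,90` is the value at the smallest
observed pair distance (not extrapolated to zero, where Hill–Weir is
unstable), and `LD_1/2max,90` / `LD_1/10,90` are the smallest distances at
which the curve reaches half of `r²_max,90` and 0.1, solved by root
bracketing and reported as undefined when no crossing occurs within 10× the
observed range — which is the expected outcome for the non-recombining
heterochromatin partition.  A least-squares fit of the same expectation to
pointwise mean r² provides the average-LD comparator (`LD_1/10` on the
mean).

## The synthetic panel generator

The generator emulates the statistical structure of a tetraploid
association panel; its defaults are the package's study conditions.

* **Genome**: 12 chromosomes of 60 Mb with a centred pericentromeric block
  occupying 35% of the length; 170 markers per chromosome (~2040 total)
  placed uniformly, with marker density inside the block reduced to 0.4× the
  arm density, mirroring the euchromatin (gene) bias of transcript-derived
  SNP arrays.  1 Mb ≈ 1 cM in euchromatin; genetic distance does not accrue
  inside the block, so crossovers are suppressed there and founder LD is
  frozen across it.
* **Frequencies**: ancestral p ~ U(0.1, 0.9); subpopulation frequencies
  follow the Balding–Nichols beta model with divergence Fst (default 0.10,
  3 subpopulations — weak structure).
* **Founder haplotypes**: along each chromosome a latent standard-normal
  AR(1) chain with correlation `exp(−Δd/decay_scale)` (scale 2 Mb; exactly 1
  across the het block) is thresholded at each marker's subpopulation
  frequency.  This Markov construction preserves every marker's allele
  frequency exactly — a copying chain that flips alleles with
  distance-dependent probability would not — while producing monotone
  distance-decaying LD.
* **Meiosis**: the four homologs pair into two random bivalents; each
  bivalent receives Poisson crossovers along the genetic map and contributes
  one chromatid; gametes carry two chromatids and offspring dosage is the
  allele sum.  Double reduction is not modelled (random bivalent pairing
  only); this is the simplest tetrasomic model adequate for scoring the
  estimators and is noted as an extension point.  The single-locus gamete
  law (duplex parent → dosage {0, 1, 2} with probabilities {1/6, 4/6, 1/6})
  is checked against exhaustive enumeration.
* **Pedigree**: panels are either founders-only (unrelated) or offspring of
  within-subpopulation founder crosses (default 45 founders, 10 offspring
  per family, 300 offspring — prominent family kinship with ~30 sib
  families); multi-generation chaining is supported.
* **Traits**: `y = Σ b·dosage + u + shift(subpop) + ε` with
  `u ~ N(0, σ_g² K)` where `K` is the Gower kinship of the generated panel
  (so the REML estimand is exactly matched), `σ_g² = h²/(1−h²)·σ_e²`, and
  optional per-subpopulation mean shifts for structure confounding.  With
  `qtl_var_fraction` set, QTL effects are rescaled from the realized dosage
  variance so the QTL explains exactly the stated share of trait variance.
* **Determinism**: one seed feeds named SeedSequence streams (frequencies,
  haplotypes, pedigree, meiosis, missingness, traits), so stages are
  independently reproducible and `resample_traits` can redraw traits on a
  fixed panel.

The truth record (subpopulation labels, pedigree, per-trait QTL effects and
variance components, founder frequencies) suffices to score every estimator.
For LD, the generator supplies its own implied 90th-percentile r² curve:
the binary correlation of thresholded bivariate normals at latent
correlation `exp(−d/scale)`, quantiled over the frequency law, optionally
convolved with Fisher-z sampling noise at the panel's sample size (the
estimator necessarily sees observed r², whose quantiles sit above the
population curve at finite n).

**What the simulations do not capture**: array ascertainment bias, genotype-
calling error and allele-dosage miscalls, double reduction and preferential
pairing, selection and realistic demography, linkage between the QTL and a
polygenic background confined to the same region, and the long-tailed
relatedness continuum of a century of breeding (the generator's kinship is
block-structured sib families over an unrelated background).  Passing tests
therefore establish internal correctness of the estimators under a faithful
tetrasomic sampling model, not field-data performance.

## Statistical properties worth knowing

* With raw Gower similarity as `K`, the heritability ratio
  `h² = σ_g²/(σ_g²+σ_e²)` is weakly identified at n = 300: the similarity's
  large shared background is absorbed by the intercept and the residual
  identifiable contrast gives `sd(ĥ²) ≈ 0.15` (Fisher-information
  calculation, confirmed by simulation) regardless of the family layout.
  Parameter-recovery statements therefore average trait replicates on a
  fixed panel, and null (`h² = 0`) estimates up to ~0.3 occur regularly.
* λ_GC at ~2000 markers has null sd ≥ 0.054 (independent markers;
  correlated blocks make it heavier-tailed), so single-panel λ values
  outside [0.9, 1.1] do not by themselves indicate miscalibration.
* The number of structure covariates matters: for a panel with `k`
  subpopulations, `k − 1` leading eigenvectors capture the structure; extra
  eigenvectors increasingly absorb family components, pushing the Q model
  toward the over-corrected regime and the QK fit toward the `σ_g² = 0`
  boundary.

## Problem sizes

The acceptance analyses use n = 300 clones with ~2000 filtered markers on
12 chromosomes (10 seeds for calibration and confounding, 20 power
replicates, 50 trait replicates for variance-component recovery, 5 seeds
for LD recovery with 200-clone founder panels); unit tests use compressed
panels (tens of samples, a few hundred markers).  These sizes reproduce the
study-scale statistical behaviour while keeping a full run of tests plus
the acceptance script within a few minutes on one CPU.
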
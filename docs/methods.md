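# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of `boablup`, in the spirit of the model
documentation of packages like msprime or statsmodels.

## The origin-split mixed model

The core model treats the phased genome of an admixed individual as a
mosaic of haplotype segments, each descending from one of K genetic groups
(breeds); group 1 is the target breed. Writing `h_im^pat, h_im^mat ∈ {0,1}`
for the phased alleles and `o_im ∈ {1..K}` for their origins, the
origin-split allele count is

    Z_Aimk = h_im^pat [o_im^pat = k] + h_im^mat [o_im^mat = k],

so that `Σ_k Z_Aimk` is the ordinary dosage. The phenotype model is

    y = X β + Σ_k Z_Ak a_k + e,     Cov(a) = Σ ⊗ I,     Cov(e) = σ_e² I,

with X the N×K matrix of genetic contributions `c_ik` (here computed as
the fraction of the individual's 2M retained-marker alleles assigned to
group k, so rows sum to 1) and Σ the K×K per-marker effect covariance.
The Kronecker prior is the essential ingredient: the same marker's effects
in different origin groups are correlated with correlation r, so
information flows between breeds in proportion to r while still allowing
origin-specific LD between markers and causal variants.

Estimates solve Henderson's mixed-model equations; the GEBV of a
(validation) individual is the marker part only, `Σ_m Σ_k Z_Aimk â_mk`.
Fixed effects are deliberately excluded from the breeding value.

Baselines are within-breed and multi-breed SNP-BLUP, `y = β1 + Z a + e`
with `a ~ N(0, σ_a² I)` and no breed fixed effect (none is simulated).
SNP-BLUP is used instead of an explicit genomic-relationship-matrix GBLUP;
the two are equivalent for `G = Z Z' σ_a²`, and the equivalence is asserted
in the test suite rather than assumed.

### Variance components

No REML machinery is included. Marker-effect variances use the
deterministic heterozygosity heuristic

    σ_Ak² = V_A / Σ_{m ∈ retained} 2 p_mk (1 − p_mk),

with `p_mk` the allele frequency in breed k (pooled frequencies for the
baselines), off-diagonals `σ_Akl = r √(σ_Ak² σ_Al²)`, and
`σ_e² = V_P − V_A` (defaults 1 − 0.3 = 0.7). The across-origin correlation
r is a tuning input; `grid_search_correlation` selects it by 5-fold CV
accuracy (ties toward the larger r, since pooling information is the safer
default), with the default grid {0.05, 0.15, …, 0.95, 1−10⁻⁶}. The
operating default r = 0.75 reflects that with causal loci excluded from the
marker set, marker-effect correlations are substantially below the
QTL-effect correlation.

### Solver

The MME are assembled densely and solved by Cholesky when the system
dimension (K·M + #fixed) is ≤ 6,000; rank-deficient systems (e.g. constant
contribution columns) fall back to a minimum-norm least-squares solution.
Above the dense limit a matrix-free conjugate-gradient solver applies the
MME operator through X, the Z blocks and `(Σ⁻¹ ⊗ I)` without forming them
(rtol 1e-10). Diagnostics (solver used, MME residual norm, condition
estimate for small systems) are attached to every result.

## Genome simulator

Real 50k-chip founder genotypes of the two breeds are not distributable,
so founders are synthetic:

* **Divergence.** Ancestral allele frequencies ~ Uniform(0.05, 0.95);
  breed frequencies Beta-distributed around them (Balding–Nichols) with
  F_ST = 0.10 by default.
* **Within-breed LD (optional).** With `n_pool_haplotypes = H` set, each
  breed is founded from H haplotypes drawn from its frequencies and
  expanded by `n_ld_generations` (default 4) rounds of random mating at the
  target census size. The finite pool creates haplotype sharing and
  background LD, which real chip data has and site-independent draws
  (the default, `None`) do not. The scenario runner uses H = 80: exact
  haplotype matching for origin assignment and marker–QTL LD both require
  sharing. Calibration checks (additive and phenotypic variance) use the
  site-independent default, where the linkage-equilibrium variance formula
  is exact in expectation.
* **Admixture.** A single pulse `admixture_generations_ago` (default 10)
  generations back replaces a fixed fraction (default 0.157, rounded to a
  whole count) of the target breed's haplotypes with *copies of donor-panel
  haplotypes*, followed by random-mating gene-dropping. Copying (rather
  than redrawing from donor frequencies) makes introgressed segments
  identical-by-descent with donor references — which is what a migrant sire
  produces, and what segment matching detects. Segment lengths emerge from
  recombination (mean ≈ 10 cM after 10 generations at 1 cM/Mb).
* **Meiosis.** Haldane model: per chromosome, crossover count ~
  Poisson(genetic length in Morgan), positions uniform on the genetic map,
  no interference, no mutation, no selection. The true origin of every
  transmitted allele travels with it through every crossover, so simulator
  truth is available at every marker.
* **One further generation.** `simulate_generation` breeds a recorded
  generation with n_sires equal-size sire families (dams drawn at random),
  providing the half-sib family structure the cross-validation needs.

Defaults for desk-scale work are 3 chromosomes × 100 Mb × 1,000 markers at
1 cM/Mb. A full-scale run (29 autosomes, ~23k segregating SNPs, 3,000 +
6,000 individuals) is configurable but not exercised by the test suite;
problem sizes in the tests (≤ 2,500 markers, ≤ 10,000 individuals) were
chosen so the whole suite completes in a few minutes.

## Trait simulator

QTLs are sampled uniformly from the markers segregating in both breeds and
excluded from the prediction marker set. Effect pairs are bivariate normal
with correlation 0.95 and equal variances. Each breed's effect column is
rescaled by a single positive scalar so the linkage-equilibrium additive
variance `Σ_q 2 p_qk (1 − p_qk) a_qk²` equals V_A = 0.3 **exactly** in that
breed (per-breed scalars, because one shared scalar cannot hit both breeds'
targets; positive rescaling leaves the effect correlation untouched).
Frequencies are taken from the generation entering the analysis. True
breeding values sum origin-specific effects over origin-specific allele
counts (using the simulator's *true* origins); phenotypes add
N(0, V_P − V_A) noise, V_P = 1, one record per individual, no dominance or
epistasis.

## Segment-based origin assignment

The assigner estimates origins for admixed haplotypes from purebred
reference panels. Windows of exactly `min_markers` (default 20) consecutive
markers slide along each admixed haplotype (step 1, never crossing a
chromosome boundary); a window is foreign-supported for group k if it
matches at least `min_foreign_matches` (default 1) group-k reference
haplotypes *exactly*. Maximal runs of positions covered by supported
windows become candidate segments, accepted when they span ≥ `min_markers`
markers and ≥ `min_length_bp` (default 1.5 Mb, measured last-marker minus
first-marker position, 1-based inclusive). Everything else is
target-origin, so origins always partition the genome. With K > 2,
overlapping candidates from different donors are resolved by window
support, then segment length, then lower group index — deterministic and
documented in the output.

Two deliberate choices:

* **No native-haplotype veto by default.** An optional veto
  (`max_native_matches`) can reject windows that also occur in target-breed
  references. It is off by default because the veto window shrinks together
  with `min_markers`, which would let a *stricter* rule assign *more*
  foreign positions; the foreign-match-only classifier is exactly monotone
  under rule tightening. On simulated data the veto raises overall
  agreement with truth from ≈ 0.90 to ≈ 0.93 — available, but not the
  default.
* **Exact matching.** Near-matches are not scored; this is deterministic
  and testable, and adequate when introgressed segments are
  identical-by-descent with donor references. It is *not* an HMM
  local-ancestry method and is expected to degrade with genotyping error or
  very distant reference panels (both out of scope here).

## Cross-validation and scenarios

Sires are shuffled and dealt round-robin into 5 folds; every individual
inherits its sire's fold, so folds never share sires (with 50 equal
families: 10 sires, and exactly one fifth of the individuals, per fold).
Within-breed models fit on the target-breed reference folds; multi-breed
and origin-split models add the entire donor panel. Held-out phenotypes
never enter any fit (asserted by a mutation test). Accuracy is
cor(GEBV, TBV) in the held-out fold; a zero-variance GEBV vector yields a
missing value with a warning. Accuracies are averaged over folds within a
replicate first; the reported sd is across replicate means and
se = sd/√(replicates), with the all-folds sd reported alongside
(`sd_fold`).

The named scenarios hold the donor panel at 6,000 and vary the target
breed: 750 / 1,500 / 3,000 individuals, giving validation sets of
150/300/600, within-breed references of 600/1,200/2,400 and multi-breed
references of 6,600/7,200/8,400 (9.09/16.67/28.57 % target-breed). The
sire and dam counts of the simulated mating design are not fully
constrained by the experimental description; 50 sires is implied by
10 sires per fold × 5 folds and is the default.

## What passing tests do and do not show

The simulator reproduces the *structure* of the motivating data — two
diverged breeds, one-way introgression at a genome-wide fraction of
≈ 0.157, mosaic segments ≥ 1.5 Mb, equal sire families, V_A ≈ 0.3 at
V_P = 1 — but not real 50k-chip LD, allele-frequency spectra, or
pedigree depth. Desk-scale genomes (≈ 1,000 markers, 3 chromosomes) carry
far less marker–QTL LD than a 50k chip, so absolute cross-validation
accuracies (~0.15–0.25) are well below a real analysis (~0.4–0.55), and
the *within-breed* baseline is relatively stronger here than it would be
with realistic donor-breed LD. The qualitative claims that are checked —
the origin-split model is at least as accurate as multi-breed SNP-BLUP,
and all models gain from larger target-breed references — are stable
across replicates at this scale; exact accuracy levels are not
transferable to real data.

## Numerical details and degenerate inputs

* All randomness flows through `numpy.random.Generator`; every public
  simulation entry point takes a seed or generator, and scenario replicate
  j uses `seed + j`.
* Effect sampling uses an eigendecomposition square root with eigenvalues
  clipped at zero, so the degenerate r = 1 case is handled exactly.
* `VarianceSpec` requires symmetric positive-semidefinite Σ; the MME solver
  requires strict positive definiteness (use 1 − 10⁻⁶ instead of 1).
* Monomorphic-in-a-breed QTLs make the per-breed scale factor undefined and
  raise; likewise an empty marker set after filtering, non-divisible
  equal-family designs, unphased or multiallelic VCF records, and
  single-fold CV plans.
* Output tables carry `#` headers with the package version, seed and a
  config hash; floats are written at 17 significant digits and parsed in
  round-trip mode, so deterministic stages re-run bit-identically.
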
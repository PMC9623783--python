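# Methods

This note documents the models, algorithms, numerical choices and synthetic
data behind `igpipe`, and what the tests do and do not establish.

## The evaluation model

Phenotypes follow a (multi-)trait repeatability animal model

    y = Xb + W a + W p + e,

with one fixed factor (contemporary group), additive genetic effects `a`
with Var(a) = H ⊗ Σ_a, permanent-environment effects `p` (fitted whenever
the PE covariance is nonzero; required for repeated records) with
Var(p) = I ⊗ Σ_pe, and residuals Var(e) = I ⊗ Σ_e. Unknowns are ordered
entity-major (levels, animals, PE terms), each entity carrying a block of
`n_traits` values. Records with missing traits are grouped by observed-trait
pattern; each group uses the inverse of the corresponding residual-covariance
submatrix embedded back into trait space. The algebra is dimension-generic;
in practice the package is exercised with 1–3 traits (the multi-trait code
paths are verified by separability against single-trait solves).

### H inverse

`H^-1 = A^-1 + scatter(G^-1 − A22^-1)` is never formed: it is a linear
operator combining (i) the sparse `A^-1` from Henderson's rules with
inbreeding (Mendelian-sampling variance 0.5 − 0.25(F_s + F_d) with both
parents known, 0.75 − 0.25 F_p with one, 1 with none), (ii) a dense or APY
`G^-1`, and (iii) a dense `A22^-1`. Inbreeding is read off the tabular-A
diagonal; at the package's desk scale (up to a few tens of thousands of
animals) the O(n²) tabular method, JIT-compiled, is simpler and fast enough,
so the memory-optimal recursive algorithms are not used. Unknown parents are
treated as unrelated non-inbred base animals; no unknown-parent groups are
fitted.

### Genomic relationships

`G = (1−β)·ZZ'/k + β·A22` (identity when no pedigree submatrix applies),
with `z_ij = m_ij − 2p_j`, missing calls imputed at `2p_j`, and
`k = 2 Σ p_j(1−p_j)`. Blending with default β = 0.05 guarantees
invertibility when animals outnumber markers or genotypes repeat; β is
recorded on every product. Allele frequencies are always computed from the
full genotyped pool and reused for every subset (evaluation set, backsolving
subset, prediction targets) so that centered contents — and therefore SNP
effects and indirect predictions — live on one scale. No base "tuning" of G
toward A22 (mean adjustment) is applied.

The APY inverse keeps a direct inverse of the core block `G_cc` plus, per
noncore animal, the coupling row `P_i = g_ic G_cc^-1` and the conditional
variance `m_i = g_ii − g_ic G_cc^-1 g_ci`; implied entries between two
noncore animals are exactly zero and the dense noncore block is never
formed. A noncore `m_i ≤ 1e-8` (a genotype fully explained by the core,
e.g. a duplicate) is an error naming the animal. Core animals are drawn
uniformly at random with a recorded seed; the eigenvalue criterion
(`estimate_core_size`) returns the smallest k whose top-k eigenvalues reach
a target share — 98–99% — of trace(G).

### Solver

Preconditioned conjugate gradients with a zero start vector (determinism
over warm starts) and a block-diagonal preconditioner: one
`n_traits × n_traits` block per fixed level, per animal (data block plus
`diag(H^-1)_ii · Σ_a^-1`), and per PE term. The convergence statistic is the
squared relative residual `c = ‖b − Cx‖²/‖b‖²` with default tolerance
1e-12 and a non-convergence flag past `max_iter`. At that tolerance the
solution carries a relative error around 1e-5–1e-6; oracle-equivalence tests
that assert 1e-8 agreement therefore solve at tighter tolerances (1e-16 to
1e-20), which the contract exposes.

## Backsolving and indirect prediction

`û = λ Z' G_s^-1 â` with D = I and `λ = 1/k` (the marker-effect to additive
variance ratio under the scaling above — the consistent choice when G is
ZZ'/k). The subset's `G_s` is built from the subset rows of Z with the pool
frequencies, blended β toward the **identity** (no pedigree submatrix is
involved at this stage) and inverted directly — at subset sizes of a few
thousand no sparse approximation is needed. With β = 0 and a full-rank
subset, `Z û` reproduces `â` exactly; blending perturbs the fitted values by
at most the factor 1/(1−β).

`IGP = Z_targets û`; missing genotypes contribute zero through centered
imputation. Because the marker effects inherit the backsolving set's genetic
base, raw IGP sit a fraction of a genetic SD below the benchmark GEBV of
young selected animals. Validation (the regression `GEBV = b0 + b1·IGP`,
absolute-difference summaries and trend correlations) is computed on the
**raw** predictions — b0 and MEAN then expose the base gap, which is what
makes them correlate with the genetic trend — while the delivered
predictions are base-adjusted (mean-difference mode by default; an
intercept mode applies b0 + b1·IGP from the reference regression).
Standardization divides b0, MEAN, MAX and ΔG by the per-trait genetic SD;
b1 and R² are scale-free and never standardized. ΔG is defined
operationally as the per-year slope of cohort means (an approximation to
published genetic-progress figures, which use more elaborate definitions);
per-generation trends follow by multiplying with the generation interval.
Report rounding: 2 decimals for b0/b1/ΔG/MEAN/MAX and correlations, 3 for
R².

## The synthetic population

The generator emulates the structure of a large dairy evaluation, not any
particular population:

- **Pedigree and selection.** Discrete generations; parents are the top
  fraction of each sex by selection-weighted true breeding value (weights 0
  = random). Defaults keep 40% of females and 10% of males — dairy AI
  practice, giving an effective population size near 10² — so a clear
  genetic trend of roughly `(i_m + i_f)/2 · σ_a` per generation arises.
  Selection acts on true values, not estimates, so the trend is controllable
  without iterating evaluations. Offspring sexes alternate deterministically,
  guaranteeing both sexes per generation.
- **True values.** Each trait has phenotypic variance 1 (so σ_a² = h²). A
  fraction `marker_variance_fraction` (default 0.8) of the additive variance
  is carried by infinitesimal normal effects on every marker — `α ~ N(0,
  f_m Σ_a / k_base)` — and the rest by a polygenic term following the
  pedigree recursion `a = (a_s + a_d)/2 + m`, `Var(m) = 0.5(1 − F̄)Σ_a`,
  with exact inbreeding tracked by growing the tabular A generation-blockwise.
  The marker-linked share is what lets genomic relationships genuinely beat
  pedigree expectations at truth recovery; with `f_m = 0` genomic data are
  pure noise for the truth (though the IGP-vs-GEBV algebra is unaffected).
- **Genome.** Biallelic markers in `n_linkage_blocks` haplotype blocks
  (default 200) that segregate as units: complete linkage within, free
  recombination between. Founder gametes draw each block from a finite pool
  of ancestral block haplotypes (default 20). Together these give the genome
  a finite number of independent segments — the regime in which a
  backsolving subset of a few thousand animals suffices and an APY core well
  below n captures most of G's variation. `None` for either field recovers
  fully independent markers / unrelated founder gametes. There is no genetic
  map, no QTL architecture, no genotyping error or imputation.
- **Phenotypes.** Females only (type-trait style recording), probability
  0.5, 1–3 records each; contemporary group = recording year (birth year +
  age at first record + record number − 1), so repeated records of one cow
  connect adjacent cohorts — with birth-cohort groups the genetic trend
  would be confounded with the fixed effects. Group effects are i.i.d.
  normal (SD 0.5 phenotypic SD).
- **Partition.** Genotyped animals with phenotypes or progeny form the
  direct-GEBV class; genotyped animals with neither, born at/after the
  cutoff year, are the IGP targets. Genotyped animals with neither but older
  than the cutoff remain in the GEBV class (they would stay in an
  evaluation). The partition is exhaustive and disjoint by construction.

Determinism: every stage draws from an independent child stream of the
config seed, so identical configs give bit-identical populations regardless
of which stages are run.

What passing tests therefore show: the algebra (relationship matrices,
APY, MME, PCG, backsolving, prediction, validation statistics) is correct
against independent oracles, and the workflow's statistical behaviour —
accuracy and dispersion of IGP versus subset size, base-gap/trend
correlations, core sizes well below n — reproduces on populations with
dairy-like structure. What they do not show: behaviour under real linkage
disequilibrium patterns, genotyping error, multi-breed structure, or
selection on estimated (rather than true) breeding values.

## Problem sizes and runtime choices

The standard study conditions (frozen once, used by the acceptance checks
and `scripts/acceptance.py`) are 400 founders, five generations with 7
offspring per dam (≈4,400 animals, ≈3,700 genotyped: ≈2,700 GEBV-class,
≈950 targets), 2,000 markers, h² = 0.3, repeatability 0.45. One full study
(two PCG solves plus relationship matrices) takes ≈20–30 s on one CPU; the
test suite's ten-population sweep runs in ≈3–4 minutes and the acceptance
script (three populations) in ≈2 minutes. The analysis scripts use the same
or smaller configurations so each finishes in well under a minute.

## Known limitations

- Desk scale: dense A, A22 and G limit populations to a few tens of
  thousands of animals; the memory-efficient large-scale algorithms the
  production programs use are intentionally out of scope.
- The block-haplotype genome is a caricature of recombination; segment
  counts, not LD decay curves, are the emulated feature.
- No reliability/accuracy approximation is provided for IGP animals.
- Variance components are inputs (the generator's true values are used);
  no REML estimation.
- Genetic groups / unknown-parent groups are not fitted.
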
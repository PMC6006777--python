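# Methods

`eqtmscan` implements a genome-wide *expression quantitative trait
methylation* (eQTM) analysis: every CpG's methylation level is tested for
association with every transcript's expression, the resulting eCpG-transcript
pairs are classified by genomic configuration, corroborated within and
between studies, and interrogated for chromatin-feature enrichment. This note
records the models, the numerical choices, and what the synthetic cohorts do
and do not establish.

## The association model

For transcript *k* and CpG *j*, with *n* samples:

    y_k = μ_k + M_j a_jk + X β_jk + u_k + ε_jk
    u_k ~ N(0, σ²_g H),   ε_jk ~ N(0, σ²_e I)

`y_k` is log expression, `M_j` the vector of methylation β-values (fractions
in [0, 1]), `X` the fixed covariates (age in years, sex as 0/1, plus an
intercept), and `u_k` a random effect whose covariance `σ²_g H` captures
inter-individual correlation induced by unmeasured confounders such as
cellular heterogeneity. The effect of interest is `a_jk`, in log-expression
units per unit β.

**Intersample correlation matrix.** `H` is estimated from the expression
data itself: each transcript row is standardized to mean 0, sd 1 (n−1
denominator), giving `Z` (m × n), and `Ĥ = ZᵀZ/m`. This is the
"inter-sample correlation emended" (ICE) construction — the expression
analog of a kinship matrix. Two small-`m` caveats are handled explicitly:

* *Rank deficiency.* When n > m, `Ĥ` is singular; eigenvalues are clamped
  from below at `1e-6 × λ_max` before use. The estimator's intended regime
  is m ≫ n (tens of thousands of transcripts), where this never binds.
* *Proximal contamination.* A transcript being tested is itself one of the
  rows that built `Ĥ`, so its phenotype lies exactly in the row space of
  `Z`. With small m its own rank-one contribution `z_k z_kᵀ/m` is not
  negligible: the profile likelihood then drives the variance ratio toward
  the random effect, which absorbs the phenotype and deflates every test
  statistic toward zero (on a pure-null desk-scale cohort we observed median
  GIF ≈ 1e-4). The scan therefore removes the tested transcript's
  contribution by a rank-one downdate, `Ĥ₋ₖ = (mĤ − z_k z_kᵀ)/(m−1)`,
  re-decomposed per transcript — the same logic as leave-one-chromosome-out
  kinship in genetic association. With the downdate the same cohort gives
  median GIF ≈ 1.02 and type-I error 0.051 at α = 0.05. At m ≫ n the
  downdate is numerically irrelevant; it can be disabled
  (`scan(..., leave_one_out=False)`), and it never applies when a
  pre-computed `H` is supplied.

**Estimation.** After one spectral decomposition `H = U S Uᵀ`, all vectors
are rotated by `Uᵀ` and the covariance becomes diagonal,
`σ²_g diag(S + δ)` with `δ = σ²_e/σ²_g`. `δ` is profiled by maximum
likelihood on 100 log-spaced points in [1e-5, 1e5] followed by a parabolic
refinement in log δ; the returned likelihood is always ≥ the best grid
point. `δ` is treated as a per-fit nuisance (EMMA-style). For each
transcript the fits over all CpGs are vectorized: the covariate block is
solved once per δ and each CpG enters through a Frisch–Waugh residual
regression, so a 200 × 500-pair scan at n = 300 runs in well under a minute.

**Inference.** The Wald statistic is `T = â/SE(â)` with the residual
variance estimated on n − rank(design) degrees of freedom, and p-values come
from the t distribution with the same df. With `H = I` this collapses
*exactly* to ordinary least squares, which the tests use as a closed-form
oracle. A t reference (rather than normal) is the conservative choice at
moderate n. Degenerate fits (singular rotated design) raise; noiseless fits
floor the p-value at machine tiny with the effect still reported.

**QC.** Per transcript, the genomic inflation factor is
`GIF = median(T²)/0.4549` (0.4549 = median of χ²(1) to four decimals);
transcripts with GIF > 2 are removed after the scan, before classification.
Significance tiers are strict: suggestive p < 1e-5, significant p < 1e-11
(Bonferroni for 5 × 10⁹ tests at FWER 0.05).

## Positional classification

Coordinates are 0-based half-open; a CpG is a point. Broad categories:
**cis** (CpG < 50 kb from the associated gene's span; inside counts as 0),
**distal** (same chromosome, ≥ 50 kb), **trans** (different chromosome). The
50 kb rule is applied to the gene span, not the TSS, so gene-body CpGs are
always cis.

Detailed cis categories are assigned with the precedence *near promoter*
(within 2,500 bp of the TSS, inclusive) → *in gene body* (> 2,500 bp
downstream of the TSS and upstream of the TES, strand-aware) → *closest
downstream gene* / *closest upstream gene* (the associated gene's TSS
resp. TES is nearer to the CpG than any other gene; ties go to the
TSS-side gene) → the non-canonical configurations (*closer 5′*, *closer 3′*,
*gene between*, *in different gene*), with *multiple closer/between* when
more than one of the last four holds. Putting the promoter window ahead of
the gene body resolves their 2,500 bp overlap zone in favor of the promoter.
"Closest up/downstream" compares against *other* genes only — the
associated gene is excluded from its own comparison set. The classifier is
exhaustively checked for one-label-per-pair and for invariance under genome
mirroring (coordinate reflection plus strand flip).

Gene-body CpGs are subclassified as exonic/intronic with first/last exon in
transcription order. Multi-location expression probes are resolved by:
annotatable-to-a-gene first, then proximity to the CpG, then match rank
(primary > secondary > other), then lowest start coordinate.

## Corroboration

*Between studies*: a pair replicates when CpG ID, probe ID, probe location
and correlation sign all match exactly. Chance replication is assessed by
shuffling probe IDs — jointly with their locations, since a location is a
property of the probe — within each (study, category) stratum, as a
permutation without replacement, recomputing the overlap per shuffle.

*Within a study*: for windows of 100–2,000 bp to each side, among eCpGs
with ≥ 1 neighboring eCpG in the window (the site itself excluded, boundary
inclusive): the fraction sharing an associated gene with some neighbor, the
fraction sharing a gene with the same correlation sign, and the fraction
whose neighbors *all* share gene and sign. Gene sharing uses gene IDs after
probe resolution. The three fractions are nested by construction, and the
all-congruent fraction can only fall as the window grows when the
denominator set is fixed.

## Enrichment

Shores are the 1.5 kb bands flanking CpG islands; shelves the next 1.5 kb;
both are clipped at chromosome bounds and subtracted from inner layers, so
island/shore/shelf are pairwise disjoint. Tracks are merged interval sets
with binary-search point membership (start inclusive, end exclusive).

Fisher 2×2 tests run in the two designs used for chromatin features: over
all tested CpGs (feature × eCpG status, each CpG once) and within
significant pairs (classification × feature, each unique pair once). The
p-value is the exact two-sided test on raw counts; the odds ratio is the
cross-product ratio with a Haldane–Anscombe +0.5 correction on zero cells
(applied to OR and CI only, never to p), and the 95% CI is
`exp(log OR ± 1.96·SE)`. Intermediate methylation is mean β in [0.2, 0.8],
boundaries inclusive. The gene-body sign analysis contrasts negatively vs
positively correlated gene-body eCpGs across ChromHMM promoter states 1–3
and enhancer states 4–8 (that analysis's convention; the chromatin-feature
figures use strong 4–5 / weak 6–7 enhancers and insulator 8 — both
groupings are exposed as constants). Term enrichment is the one-sided
hypergeometric upper tail per term with Benjamini–Hochberg FDR across
terms; the term map is a flat term → gene-set input.

## Power arithmetic

Power of the two-sided single-predictor test is computed from the
noncentral F(1, n−2) distribution with noncentrality `λ = n·r²/(1−r²)`;
covariates are deliberately ignored (a ±1-df toggle exists). The minimal
detectable r² is found by bisection to 1e-6. At α = 1e-11 and 80% power
this gives 15.9% of expression variance at n = 333 and 4.73% at n = 1202 —
16% and 4.7% at two significant figures. The exact formula behind the
published detectability claim is not specified anywhere; the noncentral-F
form is the standard choice and reproduces both numbers to printed
precision, which is the only check available.

## Synthetic cohorts

The generator produces what the analysis assumes, with known ground truth:

* **Toy genome.** ≥ 2 chromosomes (trans pairs need two). Genes sit on a
  jittered grid with a long gene-free tail (> 50 kb placements); the first
  chromosome carries a 40 kb anchor gene with a second gene nested inside
  it, which instantiates the overlapping-gene (promoter-of-one /
  body-of-the-other) and in-different-gene configurations. Anchor CpGs
  guarantee promoter, first-exon, last-exon, intronic, flank, distal and
  trans placements; a uniform fill at the requested sites/kb adds the rest.
  Every detailed category is realizable by at least one (CpG, gene) pair —
  verified by exhaustive sweep.
* **Methylation.** A fraction of CpGs (default 0.8) is bimodal: each such
  CpG is hypo- or hyper-methylated (coin flip per CpG) with samples drawn
  from Beta(0.5, 10) or its mirror, so per-CpG *average* β concentrates
  near 0 or 1 — the bimodal landscape of average methylation seen on real
  arrays. The remainder draws from Beta(5, 5) (intermediate). Planted eCpGs
  are always intermediate, mirroring the empirical observation that eCpGs
  are intermediately methylated and giving planted effects usable
  inter-individual variance.
* **Confounders.** K shared per-sample latent factors (standard normal
  loadings) enter expression with per-transcript N(0,1) weights and
  methylation with small per-CpG N(0, 0.05) weights (β clipped to [0, 1]).
  Cellular heterogeneity perturbs both assays; loading only the expression
  side would leave per-pair OLS perfectly calibrated and there would be
  nothing for the mixed model to correct.
* **Covariates.** Age ~ Uniform(18, 78), sex ~ Bernoulli(0.5), with small
  effects (age N(0, 0.01)/year, sex N(0, 0.3)) on a random 10% of
  transcripts.
* **Planted effects.** For a requested variance-explained r², the
  coefficient is calibrated against the *realized* sample variances,
  `a = ±sqrt(r²/(1−r²)·Var(rest)/Var(β))`, so the realized r² matches the
  request to Monte-Carlo accuracy (±0.05 at n ≥ 500 over 20 seeds).
* All randomness flows through one `numpy.random.default_rng(seed)`; output
  is bit-identical for identical inputs.

What the cohorts do **not** emulate: probe chemistry, batch and plate
effects, detection p-values, realistic β-variance spectra, LD-like local
correlation between CpGs, or covariance between methylation and genotype.
Passing tests therefore establish the statistical machinery (calibration,
confounder correction, recovery, classification), not performance on any
particular real array.

## Problem sizes and numerical conventions

The calibration checks use a 200-transcript × 500-CpG scan at n = 300 (the
smallest configuration at which the GIF and type-I bands are meaningfully
narrow); confounder-correction comparisons use 20 replicates of 60 × 120 at
n = 150; recovery and power checks use 300 replicates per effect size at
n = 500 with H = I. Ties and boundaries: significance comparisons are
strict (<), the promoter window and intermediate-β band are inclusive,
distance ties between flanking genes go to the TSS-side gene, congruence
windows are boundary-inclusive. The off-diagonal structure of `Ĥ` carries a
−1/(n−1) floor from row centering (its rows sum to zero), so "off-diagonals
vanish" only as both m and n grow.

## Known limitations

* Pure-ML variance components (no REML option); at scan sample sizes the
  difference is absorbed by the n − rank(design) residual-df convention.
* The δ grid spans [1e-5, 1e5]; fits whose optimum lies outside return the
  boundary value.
* `classify_pair` is O(#genes) per pair; adequate for toy genomes and array
  -scale gene sets, not optimized for exhaustive genome-wide sweeps over
  full annotation databases.
* The permutation null shuffles probe IDs within study and category only;
  it does not model shared genomic structure between studies beyond the
  matched key.
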
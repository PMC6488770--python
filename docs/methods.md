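# Methods

## Model

For a pair of diploid individuals a and b genotyped at L unlinked
biallelic sites, the four gene copies (a1, a2, b1, b2) at a site fall into
one of nine condensed identity-by-descent configurations once parental
origin is ignored: the set partitions of {a1, a2, b1, b2} ranging from all
four copies IBD (state 1) to no copies IBD (state 9).  The genome-wide
frequencies of these configurations are the condensed Jacquard
coefficients J = (J1, …, J9), a point on the 8-simplex.  Familiar
quantities are linear in J: relatedness r_ab = J1 + J7 + 0.75(J3 + J5) +
0.5 J8, kinship θ = J1 + 0.5(J3 + J5 + J7) + 0.25 J8, the inbreeding
coefficients F_a = J1 + J2 + J3 + J4 and F_b = J1 + J2 + J5 + J6, and the
identity/fraternity/zygosity decomposition.  When neither individual is
inbred only (J7, J8, J9) — the Cotterman coefficients (k2, k1, k0) — can
be positive.

The data at a site are the two individuals' genotype likelihoods
P(D | G = 0, 1, 2) (counts of the allele whose population frequency f is
supplied), not called genotypes, which is what makes the method usable at
low coverage.  The likelihood of J is a 9-component mixture per site:

    L(J) = prod_l sum_m J_m · P(D_a, D_b | state m, f_l),

with emissions obtained by integrating the genotype-pair prior
P(G_a, G_b | f, m) against the likelihoods.  The prior for state m is
generated programmatically from the state's set partition: each IBD block
independently draws one allele (Bernoulli f), and the genotype pair is
read off the block memberships.  The published 5-row emission table is
kept as a regression test; generating all 81 entries per state from the
partitions removes transcription risk and covers the rows the table
truncates.  With one-hot (certain) genotype likelihoods the model reduces
to the classical called-genotype formulation, and with inbreeding states
excluded it reduces to the non-inbred three-coefficient estimator.

Sites are treated as independent.  Under linkage the product above is a
composite likelihood; its maximizer remains consistent but relationships
can be overestimated, and no LD correction is attempted here.

## Optimization

The maximum-likelihood Ĵ is found by EM on the simplex: the update is the
mean posterior state distribution over sites, implemented as two
matrix–vector products per step.  Acceleration follows the squared
iterative (S3) scheme: from two plain EM steps with increments r and v,
the step length is α = −‖r‖/‖v‖ and the proposal J − 2αr + α²v (α = −1
recovers the plain double step).  A proposal is used only if it stays in
the simplex and its log-likelihood is at least that of the plain double
step; otherwise the double step is taken, so accepted iterates never
decrease the log-likelihood.  Infeasible proposals are rejected outright
rather than clipped onto the boundary: clipping can pin a coefficient that
belongs in the interior to a tiny floor, from which multiplicative EM
regrowth is slow enough that a log-likelihood stopping rule halts at a
worse optimum.

Defaults: convergence when the absolute log-likelihood change falls below
1e-9, at most 5,000 EM-step evaluations, 5 restarts from independent
Dirichlet(1, …, 1) start points (uniform on the simplex), keeping the best
solution.  After convergence the boundary of the parameter space is
examined automatically: coefficients below 1e-5 are clamped to exactly 0
and the vector renormalized; the clamped solution replaces the interior
one unless it costs more than the convergence tolerance in log-likelihood.

With biallelic markers the nine coefficients are not identifiable in every
pedigree: under symmetric inbreeding (e.g. repeated full-sibling mating)
the likelihood has a ridge of equally likely J vectors.  The linear
combinations R, F_a, F_b, θ, 2-3-IBD and F_diff are constant along the
ridge, which the test suite demonstrates directly: restarts reaching equal
log-likelihoods differ by up to ~0.05 in individual coefficients while
those six statistics agree to ~1e-6.

## 2D-SFS and IBS statistics

The pairwise 3×3 joint genotype-class distribution (2D-SFS) is estimated
from genotype likelihoods alone — no allele frequencies — as a 9-cell
mixture maximized with the same accelerated EM (uniform start, tol 1e-9,
max 5,000 steps; the start is deterministic, so no seed is consumed unless
extra restarts are requested).  With the spectrum oriented so rows are
individual a's genotype (0, 1, 2) the cells are labelled A..I row-major,
making E the double heterozygote and C, G the opposite homozygotes; the
IBS statistics are then R0 = (C+G)/E, R1 = E/(B+D+H+F+C+G) and KING
kinship = [E − 2(C+G)]/(B+D+H+F+2E).  These assume non-inbred individuals;
zero denominators yield NaN rather than an error so multi-pair tabulation
continues.

## Bootstrap

Confidence intervals for every per-pair statistic use a site-level
bootstrap: L sites drawn with replacement per replicate (consistent with
the independence assumption; no block structure), re-estimating J, its IBD
summaries and optionally the IBS statistics each time, and taking
percentile intervals (default 200 replicates, 95%).  Percentile intervals
of skewed statistics may exclude the point estimate; lower ≤ upper always
holds.  Replication is deterministic given the seed.

## Simulator

The generator reproduces the validation conditions for this kind of
estimator.  Site frequencies are Uniform(maf, 1 − maf) — the MAF filter is
applied at the source, equivalent in distribution to post-hoc rejection
and cheaper.  Founders receive Hardy-Weinberg genotypes (two Bernoulli(f)
draws); each non-founder inherits one uniformly chosen allele per parent
per site.  Founder-allele labels ride along so realized IBD states are
known exactly.  Sequencing: per site per individual, read depth is
Poisson(d), each read samples one of the two carried alleles uniformly and
is flipped with probability e; the genotype likelihood of g is
p_g^n1 (1 − p_g)^(k − n1) with p_g = (g/2)(1 − e) + (1 − g/2)e, a flat row
at zero coverage.  Defaults follow the validation design: e = 0.001,
depths 1–16×, 10,000–50,000 sites, MAF filter 0.05 or 0.1.  Not modelled
(deliberately): linkage disequilibrium, recombination maps, mutation,
selection, sex chromosomes, non-symmetric error.  Passing tests therefore
demonstrate correctness of the estimator under its own assumptions —
unlinked sites, known frequencies, symmetric error — not robustness to LD
or frequency misspecification in real data.

`expected_jacquard` computes exact condensed identity coefficients by
enumerating all 4^n transmission patterns over the n non-founder ancestors
of the pair (two binary meiosis choices each), classifying the label
partition of (a1, a2, b1, b2) per pattern.  The default budget of 20
meioses (~1M patterns) keeps this under a minute; deeper pedigrees get an
error pointing to Monte-Carlo gene dropping.

### Scenario pedigrees

The three built-in validation scenarios share a grandparental founder
couple with two children P1 and P2 (full siblings), making the focal
individuals cousins:

1. Outbred first cousins: A = P1 × F1, B = P2 × F2 (F1, F2 founders).
   Exact (J8, J9) = (1/4, 3/4), R = 1/8.
2. B's parents in a parent-child relation: B = P2 × GM, so F_B = 1/4.
   Exact (J5, J6, J8, J9) = (1/16, 3/16, 3/8, 3/8), R = 15/64 ≈ 0.23.
3. Additionally A2 = P1 × H with H = GM × F3 a maternal half-sibling of
   P1 (parental kinship 1/8, the kinship of a grandparent–grandchild
   pair), so F_A2 = 1/8; the focal pair is (B, A2).  Exact R = 49/128 ≈
   0.38, F1 = 1/4, F2 = 1/8.

These structures are pinned by the expected-coefficient table: each was
validated against every printed row entry before being frozen, and the
alternatives (e.g. building scenario 2 from a child-of-P2 mating) provably
give different J8/J9.  The published scenario-3 row contains one
internally inconsistent entry (its J6 conflicts with the same row's F2 and
makes the row sum exceed 1); the frozen pedigree satisfies the row's F2,
F1, R and all remaining coefficients exactly.

## Numerical choices

* Genotype likelihoods are relative; every table is max-normalized per
  site on read, and the log-likelihood is reported on that scale.
* A frequency outside (0, 1) drops the site (logged); an all-zero GL row
  in a file is treated as missing and becomes a flat row, while an
  all-zero row reaching the emission computation raises with the site
  index.
* Tie-breaks: restarts keep the first-seen best log-likelihood; the
  boundary clamp prefers the sparser solution when log-likelihoods are
  within tolerance.
* All randomness flows through a single integer seed per operation;
  identical options give bit-identical results, and results are invariant
  to how sites or pairs are chunked across workers (per-pair arithmetic is
  worker-independent, pairs are emitted in input order).

## Problem sizes used in validation

The replicated-recovery checks run 25 replicates per scenario at 50,000
sites, mean depth 8, error 0.001, MAF 0.1, with 2 restarts per estimate —
sizes at which the mean recovered R and F2 sit well inside ±0.02 of their
exact values while a full validation run stays in the low minutes.  The
optimizer-agreement checks use 50 random-emission datasets (interior
optima, where per-coefficient comparison at 1e-6 is well defined) plus
pedigree-simulated data for log-likelihood-level agreement; the
identifiability demonstration uses 20,000 sites at depth 16 on a
three-generation full-sib-mating pedigree.

## Known limitations

* Population allele frequencies are assumed known; no joint estimation,
  and misspecified frequencies bias the coefficients.
* No LD modelling anywhere (estimator or simulator); block bootstrap for
  linked data is out of scope.
* IBS statistics assume non-inbred individuals by construction.
* Genotype likelihood computation from raw reads (BAM/CRAM pileups) is
  delegated to external callers; this package consumes GL/PL fields or
  beagle tables.
* Individual coefficients are reported even where non-identifiable; users
  working with complex inbred pedigrees should rely on the invariant
  combinations.
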
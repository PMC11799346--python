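# Methods

## Scope and model overview

demekin analyses a cohort of N individuals genotyped at M biallelic SNPs
through genotype likelihoods (never hard calls, except where the user asks
for them), plus an aligned mitogenome per individual.  Two inferential
tracks are kept deliberately separate because they answer different
questions: population-based statistics (PCA, admixture, mtDNA φ_ST)
integrate drift over many generations, while kinship-based statistics
(Jacquard coefficients, IBS ratios, relatedness clustering) see migration
that happened within the last generation or two.

## Genotype likelihoods and allele frequencies

A likelihood triplet GL(g), g ∈ {0, 1, 2} copies of the derived allele, is
stored normalized to max 1 per (individual, site); three equal values mean
"missing".  Per-site allele frequencies are maximum-likelihood under
Hardy–Weinberg, by EM: f ← Σ_i E[g_i | GL_i, f] / 2N, converged at
|Δf| < 1e−6 or 200 iterations.  On one-hot likelihoods this collapses to
the allele-count estimator (tested).  A site is called polymorphic when its
minor-allele frequency exceeds 1/(2N) — at least one expected copy in the
sample; the filter threshold is a parameter, because the upstream study
design fixes only the panel (1346 sites, of which roughly a quarter
segregate in a typical cohort).  Individuals below a mean-depth threshold
(default 2×) are excluded before any analysis, with every exclusion logged.

## Condensed Jacquard EM

For a dyad, the per-site joint genotype distribution is a mixture over the
nine condensed identity states; the 9 × 3 × 3 conditional tables are exact
polynomial functions of the site frequency.  EM maximizes
Σ_s log Σ_m Δ_m L_s(m) on the 9-simplex with
L_s(m) = Σ_{gx,gy} GL_x(gx) GL_y(gy) P(gx, gy | m, f_s).  The likelihood is
concave in Δ, so the uniform start suffices; random restarts (default 3)
are retained as a guard and the best likelihood is kept.  Convergence:
Δlog-likelihood < 1e−6, cap 5000 iterations.  Monomorphic and missing
sites contribute a constant and are skipped; estimates from fewer than 20
informative sites are flagged unreliable.  A 3-state mode (k2, k1, k0
only) exists for outbred questions and for speed.

Derived quantities use the closed forms given in the README.  r_xy is
reported raw and clamped to [0, 1] only when building clustering
distances.  On the simplex, r_xy ≤ 1 algebraically — the numerator
2Δ1 + Δ3 + Δ5 + Δ7 + Δ8/2 can reach the denominator only at Δ-vectors
where it equals exactly 1 — so the bound test is an invariant of the
representation, not a tolerance.

Measured behaviour worth knowing: at 1000 sites the 9-state model diffuses
roughly 0.03–0.05 of posterior mass from a true boundary state into the
inbred states (k1 of a parent–offspring dyad averages ≈0.96); the 3-state
model recovers class means within ±0.03.  This is the ordinary behaviour
of boundary MLEs at finite data, not an implementation artifact, and it is
why the recovery tests assert the outbred mode.

## IBS ratio statistics and the parent–offspring rule

Joint genotype-combination counts are expected counts under each
individual's posterior genotype probabilities (GL × HWE prior), or hard
calls on request.  Only sites informative in both individuals enter.  The
parent–offspring anchors hold per site, for any allele frequency p
(q = 1 − p): under one shared gamete, P(both heterozygous) = pq,
P(discordant) = 2pq, P(opposing homozygotes) = 0, and each individual's
heterozygosity is 2pq in expectation — hence R0 = 0 exactly, R1 → 0.5 and
KING → 0.25 as ratios of sums.  The decision rule is deliberately
conservative: ranges of all eight metrics (r_xy, k0–k2, θ, R0, R1, KING)
are calibrated on known mother–offspring pairs, and a candidate is called
parent–offspring only when inside every closed interval; any undefined
metric rejects the candidate.

Contamination screening flags individuals whose R1 exceeds the cohort
median by 2 median absolute deviations against ≥ 90 % of partners.
The simulator provides read-level mixture contamination for testing this:
reads drawn with allele probability (1−w)p(g_target) + w p(g_source)
produce the genome-wide heterozygote excess that elevates R1 toward
everyone.  Averaging two individuals' likelihood vectors — an obvious but
wrong surrogate — does not produce that signature (two confident opposite
homozygote GLs average to a hom/hom split with no heterozygote mass), and
is kept only as a weak-elevation check.

## Relatedness clustering and AU support

Clustering runs on D = 1 − clamp(r_xy, 0, 1) with average linkage (UPGMA;
scipy's implementation behind an order-invariant wrapper that sorts leaves
lexicographically; node heights use the ultrametric convention, i.e. half
the merge distance, so two leaves at distance 1 merge at height 0.5).  A
`profile-euclidean` mode reproduces tools that recompute Euclidean
distances between the dissimilarity matrix's columns.

Cluster support is multiscale bootstrap: at each scale ρ² ∈ {0.5, …, 1.4}
(10 scales), nboot resamples of round(ρ²·n) feature rows are drawn with
replacement, the columns reclustered, and the bootstrap probability BP of
each original cluster (exact leaf-set identity) recorded.  The model
Φ⁻¹(1 − BP) = dρ + c/ρ is fitted by weighted least squares with binomial
weights, AU = 1 − Φ(d − c).  Numerical choices: BP values pinned at 0 or 1
carry no curvature information and, clipped, drag the fit toward ½, so the
fit uses informative scales only; a cluster at the boundary at (almost)
every scale gets AU = 1 − 0.5/nboot (or 0.5/nboot); a cluster never seen
gets AU = 0 with a degenerate flag.  The root is excluded from
significant-cluster extraction — it is recovered by construction in every
resample and would otherwise mask every real cluster under the maximality
rule.  Significant clusters are maximal nodes with AU above the threshold
(default 0.95); individuals in no such node are reported unassigned.  The
default nboot is 1000 in tests (10,000 is the full-scale setting); a
node-depth column is emitted so users can separate deep (spatial) from
shallow (family) clusters.

Diet×cluster association uses an exact r×c Fisher test: full enumeration
of tables with the observed margins, summing multivariate hypergeometric
probabilities ≤ the observed table's (relative tolerance 1e−7), bounded at
5×10 with a seeded Monte-Carlo fallback.  Note the exact test is
conservative on small sparse tables (discreteness), so its realized type-I
rate sits below the nominal 5 %.

## PCA and admixture

PCA: expected genotypes e_is under individual-frequency priors π_is
(initially the pooled f_s) are standardized as
(e_is − 2f_s)/√(2f_s(1−f_s)); the covariance C = RRᵀ/M is
eigendecomposed; π is reconstructed from the top n_components (default 2)
eigenvectors and the loop repeats until the covariance moves < 1e−5
(Frobenius).  Centering is by the pooled frequency — centering by the
individual frequency would subtract precisely the structure the components
must capture (the residual covariance oscillates and loses the deme
signal; verified empirically).

Admixture: π_is = Σ_k Q_ik A_ks, genotypes Binomial(2, π), data enter via
likelihoods; EM attributes posterior expected derived/ancestral allele
counts to ancestries in proportion to Q_ik A_ks/π_is and
Q_ik(1−A_ks)/(1−π_is).  Log-likelihood is non-decreasing (asserted in a
test); A is clamped to [1e−5, 1−1e−5]; convergence Δll < 1e−4, cap 2000
iterations, seeded initialization.  K = 1 reduces exactly to the
pooled-frequency model (tested to 1e−2 log-units at tight tolerance).
compare_k_runs reports best log-likelihood, across-seed dispersion and
mean pairwise Q agreement after Hungarian label alignment; it makes no
automatic "true K" claim, because maximum likelihood always improves
substantially with K (an extra component adds ~N+K·M parameters and gains
~10² log-units even on panmictic data) — the informative signals are the
relative margin and the collapse of across-seed Q agreement under
panmixia, and those are what the tests assert.

Model evaluation: residuals e*_is = E[g | GL, π_is] − 2π_is, pairwise
Pearson correlation across sites (missing excluded pairwise; individuals
with < 20 informative sites dropped), with per-group-pair block means.
Two known properties are documented rather than "fixed": residuals against
estimated frequencies carry the classic −1/(N−1) pairwise correlation, and
the cited evaluation method's bias correction is not implemented — plain
Pearson correlation is reported, which is sufficient for the qualitative
block diagnostics (within-deme blocks under a K=1 misfit; family blocks
when close kin are sampled).

## Mitochondrial track

Variable alignment columns are tallied over unambiguous bases (N and '-'
are missing).  Any base carried by exactly one sequence is treated as a
putative sequencing error and masked; a variable column where masking
leaves fewer than two bases is a singleton column and excluded from the
diagnostic set.  This per-base rule guarantees the invariant that one
private mutation can never change the haplogroup partition, which a
per-site rule fails on triallelic columns.  Haplogroups are equivalence
classes over the diagnostic sites; sequences with masked/missing
diagnostic bases join the unique compatible haplogroup or are flagged
ambiguous.

The median-joining network starts from the union of all minimum spanning
trees on Hamming distances (an edge of weight w is kept iff its endpoints
are not connected by edges of weight < w − ε; ε default 0), adds sitewise
majority (median) vectors of connected triplets when they shorten the
minimum spanning length over the node set, and prunes medians that stop
helping.  The spanning length over the final node set never exceeds the
observed-node MST length (tested); the reported graph additionally keeps
alternative tied links, as is conventional.

AMOVA treats the mitogenome as one locus.  Pairwise distances are counts
of differing diagnostic sites (or 0/1 haplogroup identity on request) and
are used directly as the squared distances of the sums-of-squares
decomposition, the standard convention for nucleotide-difference data.
Variance components come from the usual expected mean squares with
n₀ = (N − Σn_g²/N)/(G−1); φ_ST = σ²_a/(σ²_a+σ²_b); significance from
permuting individuals among groups with the +1 correction,
p = (1 + #{φ* ≥ φ})/(n_perm + 1), so p is never exactly zero.  Groups
with fewer than two members are excluded with a warning; pairwise φ_ST
tests are Bonferroni-adjusted (α/#pairs).

## The simulator: what it emulates, and what it does not

Defaults mirror the study conditions: a 1346-site panel with polymorphic
fraction 348/1346, mean depth 40.75× with SD 24.80× across individuals
(truncated normal, floor 1×), base error 1 %, a 16,390 bp mitogenome with
9 deme-partitioning diagnostic SNPs, three demes on a divergence cline.
Deme founder frequencies follow Balding–Nichols
Beta(f(1−F)/F, (1−f)(1−F)/F) around ancestral frequencies drawn uniform on
[0.05, 0.95] for the polymorphic fraction (remaining sites fixed);
offspring are Mendelian; mothers are philopatric and fathers cross demes
with probability `migration_rate` (the male-mediated gene-flow hypothesis
encoded as ground truth); with probability `inbreeding_rate` the father is
drawn among males sharing a grandparent with the mother.  mtDNA is copied
from the mother with one private substitution per sequence at rate
`mt_singleton_rate`.  Diet labels are assigned per matriline with an
individual-level mixing rate and an "unknown" mask, both configurable,
since the study records diet as an individual covariate without a
generative model.  Reads per site are Poisson(λ_i), derived-allele reads
Binomial(d, p_g) with p₀ = ε, p₁ = ½, p₂ = 1 − ε, and GL(g) the binomial
pmf normalized to max 1; zero depth yields the missing triplet.

Not emulated: linkage, recombination maps, selection, read-level artifacts
beyond a uniform base-error rate, reference bias, and realistic killer
whale demography (generation overlap, age structure, social group
sampling).  Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not robustness
to the full messiness of field data.

Problem sizes used in the checked-in statistical tests were chosen to give
comfortable Monte-Carlo margins at desk scale: 500 parent–offspring dyads
× 1000 sites for the IBS anchors; 100 dyads per relationship class for
Jacquard recovery; 100 random 10-leaf matrices for the UPGMA oracle; all
2×3 tables with total ≤ 14 (plus 200 random larger ones up to 20) for the
Fisher oracle; 500 null data sets × 199 permutations for AMOVA
calibration; nboot = 1000 (scaled from the full 10,000) for clustering
power; cohorts of 40–80 at the full 1346-site panel for admixture checks.
The admixture "every non-admixed individual assigned with max-Q ≥ 0.9"
check runs at near-complete divergence (Balding–Nichols F = 0.5): with
only ~350 informative sites the per-individual ML ancestry estimate has an
irreducible spread of a few percent, so a bound on the *minimum* over ~80
individuals requires the strongly diverged regime by design margin
(mean − 4 SD above the threshold); at moderate divergence the fully
converged ML optimum itself places occasional individuals below 0.9.

## Reproducing the published trio at full scale (integration recipe)

The printed worked example (a mother–offspring pair with r_xy = 0.54,
θ = 0.28, R0 = 0.00, R1 = 0.50, KING = 0.25) comes from real sequencing
data deposited under accessions PRJNA1120234 and PRJNA956724.  Reproducing
it is not a desk-scale computation and is not part of the test suite; the
full-scale path is: download the raw reads, trim adapters, map to the
reference assembly, compute genotype likelihoods at the 1346-panel
positions with a GL caller, export beagle format, then run
`demekin prep`, `demekin relate --mode jacquard9` and compare the dyad's
row of `relatedness.tsv`.  The package consumes the beagle file; all
upstream steps use standard external tools.

## Known limitations

* The residual-correlation diagnostic omits the published bias correction
  (extension hook: a correction callable can replace plain Pearson).
* The Jacquard EM treats sites as independent (no LD); at panel scale this
  mainly widens the per-dyad spread.
* AU p-values inherit the known small-sample liberality of the multiscale
  bootstrap when few informative scales remain.
* The median-joining construction enumerates connected triplets greedily
  (first length-reducing median wins); for the small haplogroup counts of
  panel studies this is exact in practice, but it is not guaranteed to
  find a globally minimal network.
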
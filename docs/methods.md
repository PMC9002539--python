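# Methods

This note documents the models and procedures guildflow implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that affect results.

## Design and data model

The analysis targets a paired two-group design: subjects classified by PROP
taster status (NT non-taster / ST super-taster, with MT medium-tasters
excluded at screening), each sampled at two timepoints (pre / post an oral
rinse intervention). The primary input is an integer ASV count table
(samples × ASVs) with a rooted, branch-length-bearing phylogeny over the
ASVs, a per-sample design table (subject, taster status, timepoint, age,
gender, BMI), and real-valued phenotype tables (salivary proteins; sensory
intensity ratings of the high-polyphenol stimulus).

PROP classification follows the labeled-magnitude-scale disk protocol:
PROP < 15 mm → NT, PROP > 67 mm → ST, otherwise MT. Within ±5 mm of either
threshold the NaCl disk acts as a reference standard (NT rate NaCl above
PROP; ST the reverse; ties → MT). The ±5 mm band width is this package's
choice — the protocol defines the reference rule but not the band; the band
is deliberately narrow so that the primary thresholds govern all clear-cut
ratings.

## Diversity

Rarefaction subsamples each sample without replacement to a fixed depth via
the multivariate hypergeometric distribution; under-depth samples are
dropped, never padded.

Alpha metrics: observed ASVs; Shannon entropy in bits (base 2, the common
amplicon convention; configurable); Pielou evenness J = H / log2(richness)
(J := 0 at richness 1); Faith's PD as the branch length of the minimal
rooted subtree spanning the present tips *including the path to the root*
(conventions differ; the rooted form makes PD of a one-tip community equal
its root distance and makes PD monotone under taxon addition).

UniFrac is computed in one post-order pass that tabulates, per branch, each
sample's descending read mass. Unweighted = unique branch length / branch
length in either community (∈ [0,1]). Weighted (default) is the *raw* form
Σ len·|p_A − p_B|; the normalized form divides by Σ len·(p_A + p_B). Both
variants are verified against an independent per-branch oracle written on a
different tree library.

## Ordination and permutation inference

PCoA Gower-centers −½ D² and eigendecomposes; coordinates use positive
eigenvalues only, with `proportion_explained` taken over the positive sum
and negative-eigenvalue mass reported separately. aPCoA pre/post-multiplies
the Gower matrix by the residual maker H = I − X(XᵀX)⁻¹Xᵀ of a covariate
matrix (intercept added) before eigendecomposition — with subject indicator
covariates this removes inter-individual offsets so axes show
within-subject (e.g. intervention) structure.

PERMANOVA uses the standard distance-based decomposition (SS_total =
ΣΣd²/n; pseudo-F with k−1 and n−k df) with two permutation schemes:

- `free` — permute labels over all samples; appropriate when samples are
  exchangeable (one sample per subject, as in NT-vs-ST at one timepoint —
  label permutation then coincides with subject-level permutation).
- `stratified_by_subject` — permute timepoint labels independently within
  each subject, the exchangeable unit of a paired pre/post contrast;
  single-sample strata are held fixed (logged).

Monte-Carlo p-values use the (1+hits)/(1+N) convention and never return 0;
default N = 9,999. An `exact=True` mode enumerates all permutations (used
for oracle tests at small n). Type-I error is verified at nominal 5% over
2,000 null simulations in the acceptance suite.

Friedman's statistic is implemented directly (with the standard tie
correction) because the SciPy version requires ≥3 conditions while the
pre/post use case is k = 2, where Q reduces to n under a unanimous ordering;
the k = 3 case is cross-checked against SciPy.

## Guild construction

ASVs present in strictly more than half of the samples are "prevalent".
Association between two ASVs is the repeated-measures correlation
(Bland-Altman): Pearson correlation of residuals after subtracting each
subject's mean, df = N − k − 1, computed on arcsine-square-root transformed
proportions (proportions are always of the *whole* community, so prevalent
ASV values remain interpretable as community fractions). This is the
correlation of *within-subject* co-fluctuation — exactly the co-abundance
signal a paired design can estimate — and is invariant to arbitrary
per-subject offsets (verified to 1e-12). The implementation is checked
against pingouin's ANCOVA-based estimator.

Clustering maps r to d = (1 − r)/2 (anticorrelated ASVs maximally distant),
builds an average-linkage tree, and traverses it from the root
dichotomically: a node becomes a guild when the *minimum* pairwise r among
its members strictly exceeds a threshold, otherwise its two children are
visited. Accepted nodes below `min_guild_size` (default 2) and ASVs with
undefined correlation go to an unassigned pool. Guilds are numbered by
descending summed relative abundance, ties broken by input order; every
accept/split decision is kept in an audit record.

**Threshold default.** The acceptance threshold defaults to the one-sided
95% critical value of a correlation at the available df (≈ 0.38 at df 18),
not 0. With only ~18 within-subject degrees of freedom in a 39-sample /
20-subject design, the null sd of r is ≈ 0.24, so a threshold of zero is
crossed by sampling noise alone often enough to merge genuinely independent
co-abundance blocks (observed: 13 planted guilds collapse to 8–10). The
significance-based default asserts the scientifically intended property —
every pair in a guild is *positively correlated beyond chance* — and is a
function of the design's df, not of any dataset. An explicit numeric
threshold can be passed instead.

Guild abundance per sample is arcsin(√ Σ member proportions) — summed on
the raw proportion scale first, transformed second. Guild-level group
comparisons use the Wilcoxon matched-pairs signed-ranks test (pre vs post
within a taster group, complete pairs only, zero differences dropped by
Wilcoxon's rule) and the Mann-Whitney test (NT vs ST at a timepoint), with
significance flagged at p < 0.05 and a trend flag at p < 0.1.

## Associations and networks

Each (guild, phenotype variable) pair is fit as

    arcsine-sqrt guild abundance ~ variable + age + gender + BMI + (1 | subject)

by REML. Age and BMI are standardized; gender enters as a binary indicator.
Internally both endog and the variable are z-scored for optimizer
conditioning (the arcsine abundance scale is ~two orders of magnitude below
the covariates) and the slope is rescaled back to raw units. The optimizer
chain is Powell first, then L-BFGS: on these small random-intercept fits
the subject variance often sits on the boundary, where gradient-based
optimization hits singular score evaluations; Powell is gradient-free,
deterministic, and agrees with the gradient path to ~1e-6 in p when both
converge. Non-convergent fits (~4%) are flagged and excluded from FDR.

Benjamini-Hochberg adjustment runs separately within each pairing family —
guild-protein, guild-sensory, protein-sensory, guild-guild — and edges with
q strictly below 0.25 enter the per-taster-group network. The permissive
0.25 discovery threshold matches exploratory pilot-scale screening; FDR
calibration at that level is verified on all-null simulations. Guild-guild
and protein-sensory edges use repeated-measures correlation rather than the
mixed model. Nodes with no retained edge are excluded (a flagging choice
that matches how such networks are usually drawn and counted); guild-guild
edges are styled dashed, everything else solid, signs from the
coefficient/correlation sign. Sensory ratings are those of the
high-polyphenol stimulus only.

## Synthetic generator

The generator is a stated world, not a fit to data. Per sample s and guild
g a latent factor f[g,s] ~ Normal(μ[g,s], 1) is drawn i.i.d.; μ is 0 except
for two planted effects: guild 1 is shifted +0.8 in ST at both timepoints
(the baseline compositional difference) and guild 2 is shifted +0.8 in NT
post-intervention only. A prevalent ASV i in guild g has log-weight
base_i + λ_i·f[g,s] + ε, base_i ~ N(0, 0.5), λ_i ~ Uniform(0.5, 1) (times a
`loading_scale` knob), ε ~ N(0, 0.3). Non-prevalent ASVs occupy each sample
with probability 0.2 at log-weight N(−3, 1) — calibrated a priori so they
fall below 50% prevalence while the prevalent set carries ~95% of reads.
Counts are multinomial at depth 5,000 per sample (a desk-scale stand-in for
deep sequencing; a Dirichlet-multinomial overdispersion knob exists but is
off by default). One ST post sample is dropped to mirror a failed
extraction (n = 39).

Phenotypes are subject random intercept (sd 1) + planted treatment effect +
N(0, 0.5) noise; two proteins fall post-intervention and two rise
(mirroring the study's directional findings for amylase/MUC-5B vs two
S-type cystatins). Planted guild-factor → phenotype links at loading 0.8
are deliberately asymmetric — 12 guild-protein links in ST versus 1
guild-protein + 2 guild-sensory links in NT — a desk-scale rendering of the
published network asymmetry (dozens of ST guild-protein correlations versus
one in NT).

What the generator does *not* emulate: phylogenetic signal in guild
membership (independent by default; a flag couples them), taxonomic
structure, subject-level microbiome offsets (factors are i.i.d. across
samples, so aPCoA adjustment is demonstrated on constructed geometries in
the test suite rather than on the generator), compositional effects beyond
closure, and sequencing artifacts (chimeras, contamination). A green
recovery test therefore establishes that the *pipeline* recovers planted
structure of this kind at this noise scale — not that real saliva data have
such structure.

## Statistical power at the default effect sizes (honest limits)

With one guild of 13 shifted by 0.8 latent-sd at n = 10/group and
unit-variance factors in all 13 guilds, community-level PERMANOVA has only
~15–25% power for the baseline NT-vs-ST contrast (weighted UniFrac or
Euclidean-on-arcsine) and similar power for the within-NT stratified
contrast; the guild-targeted Mann-Whitney detects the shifted guild in
~40% of worlds. These are properties of the stated effect sizes, which are
kept as stated rather than inflated; the acceptance suite asserts the
qualitative-pattern criterion at a fixed seed anyway and documents the
expected failure of its two significance clauses. Detection of planted
guild-phenotype links by the mixed model is strong on the full 39-sample
design (within-subject df ≈ 18) and weak within a single 19-sample group
(df ≈ 8) under a 221-test BH family — the reason the network tests rely on
the many-link asymmetry rather than single-link significance.

## Numerical choices

- Eigenvalues below 1e-9 × spectral radius are treated as zero in
  PCoA/aPCoA; axis signs are arbitrary (tests compare up to sign).
- Distance matrices are symmetrized to machine precision on construction
  and validated (zero diagonal, non-negativity).
- PERMANOVA permutation comparisons use F_perm ≥ F_obs − 1e-12 to make tie
  handling deterministic.
- All randomness flows from a single seed: the pipeline derives named
  integer substreams (< 2³¹) per stage via `numpy.random.SeedSequence`;
  generator draws happen in a fixed sample order, so equal configs give
  byte-identical artifacts.
- Wilcoxon uses SciPy's exact distribution where applicable; zero
  differences are dropped and counted in the log.

## Known limitations

- The dichotomic acceptance rule is one concrete member of the family of
  "tree-based group identification" methods; other published variants
  (e.g. height-based cuts) give different partitions at equal data.
- The mixed model treats guild abundance as the response with the phenotype
  as predictor; with q < 0.25 screening this is a symmetric association
  screen, not a causal direction.
- aPCoA removes covariate effects linearly in the inner-product space;
  strongly non-Euclidean distance matrices (large negative eigenvalue mass)
  weaken its interpretation.
- Rarefaction to a single depth discards reads; no variance-stabilizing
  alternative is provided.
- The real study's headline p-values depend on undeposited phenotype data
  and database-version-dependent upstream processing and are not
  reproduction targets at desk scale.
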
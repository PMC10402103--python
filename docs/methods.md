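# Methods

This note documents the models, the numerical choices, and the design
decisions behind each stage of the pipeline, plus what the synthetic
data does and does not emulate.

## Genetic model and map construction

Genotypes at codominant F2 markers are coded as the count of B-founder
alleles (0/1/2). All map arithmetic uses the Haldane map function —
r = (1 − e^(−d/50))/2 and its inverse d = −50 ln(1 − 2r) — i.e. no
crossover interference. The same no-interference assumption underlies
the genotype HMM, so the simulator, the map builder and the scan are
mutually consistent; map lengths on real data with interference would
be mildly overestimated.

**Segregation distortion.** Chi-square goodness of fit of the
non-missing genotype-class counts against 1:2:1 (df = 2), dropping
markers at p < α/M with α = 0.01 and M the number tested. The test is
on genotype classes, not alleles, which is the standard choice for
codominant F2 markers. Z-linked markers segregate differently in an
intercross and are exempt; they are grouped in a separate run and
carried with a flag rather than modelled with a sex-specific likelihood
(a deliberate simplification — the Z groups should be interpreted with
care).

**Pairwise recombination.** r̂ maximizes the phase-known F2 two-locus
likelihood: gamete haplotype frequencies ((1−r)/2, r/2, r/2, (1−r)/2),
two independent gametes, giving a 3×3 joint genotype table whose
log-likelihood is maximized over r ∈ [0, 0.5] by bounded 1-D search
(xatol 1e-10) with explicit endpoint checks, so perfect co-segregation
returns r̂ = 0 exactly. Only pairwise-complete individuals enter; pairs
with fewer than 10 are flagged low-information. The linkage LOD is
log₁₀ L(r̂) − log₁₀ L(0.5). At n = 200 the estimator runs essentially at
the information bound; note the bound itself implies a mean absolute
error near 0.025 at r = 0.35, so accuracy targets for this estimator
are meaningful only pooled across the r range.

**Grouping and ordering.** Markers are linked iff r̂ ≤ 0.15 and
LOD ≥ 6; groups are connected components of that graph. Within a
scaffold, markers take their physical (bp) order. Scaffolds within a
group are chained greedily: starting from the largest scaffold, the
scaffold (and orientation, appended at either chain end) whose terminal
marker has the smallest r̂ to the chain terminus is attached next. This
automates what is otherwise a manual curation step; an explicit order
can be imposed by calling `order_and_space` per scaffold subset.
Adjacent spacings use the Haldane transform capped at 50 cM
(configurable); capped intervals are reported.

**Error-LOD cleaning.** For each typed genotype, the posterior over the
true genotype is computed by the HMM with that marker's own emission
replaced by a flat one (leave-one-out), so it reflects flanking markers
and the 1:2:1 prior only. The error LOD is
log₁₀ [(1 − q_obs)(e/2) / (q_obs(1 − e))], where q is the leave-one-out
posterior and e the assumed miscall rate (default 0.01, a typical
genotyping-by-sequencing error rate). Calls above threshold 5 are set
to missing. Two properties worth knowing: an isolated marker can never
be cleaned (the posterior is the prior), and a double-recombinant
artifact needs at least two concordant flanking markers per side before
its error LOD clears 5 — with single flanks the model rationally
prefers "one flank is a miscall" over "two crossovers in 2 cM". On
sparse maps the cleaning is therefore conservative; the error-LOD
*ranking* still separates planted errors from correct calls with AUC
≈ 0.999 on a 1-cM map at 2% error.

**Drop-one-marker evaluation.** A marker is dropped when (a) the model
prefers the map without it — compared as the multipoint HMM
log-likelihood of all markers under the map versus the remaining
markers under the re-fitted map plus the candidate's data as an
unlinked 1:2:1 marker — or (b) it is non-terminal and removing it
shortens the group by more than 10 cM without physical-distance
support, where "support" means flanking markers on one scaffold at
least 1 Mb apart (both knobs configurable; flanks on different
scaffolds count as unsupported since their physical separation is
unknown). One marker is removed per iteration to a fixpoint (max 10
iterations).

## QTL scan

Genotype probabilities come from a forward-backward pass over states
(AA, AB, BB) with stationary prior (¼, ½, ¼), transitions from two
independent meioses each recombining with the Haldane fraction of the
inter-position distance, emissions 1 − e / e/2 / e/2 (uniform for
missing), and pseudo-markers every 1 cM by default. Haley-Knott
regression uses design [1, P(BB) − P(AA), P(AB)]; the per-position
projection is computed once from an SVD basis (rank-tolerant), so
permutation scans reuse it and reduce to matrix products. LOD values
for numerically perfect fits are capped at 999. Proportions are scanned
untransformed — a deliberate fidelity-over-purism choice, since the
phenotype is a proportion in [0,1] and the Gaussian working model is
adequate away from the boundaries; a logit transform can be applied to
the phenotype upstream if preferred.

Permutation thresholds shuffle the phenotype against the intact
genotype structure and take the empirical (1 − α) quantile of the
genome-wide maximum LOD with linear (type-7) interpolation — fixed and
documented for bit-reproducibility. Under the null the fraction of
replicates exceeding their own 5% threshold measures 0.05–0.06 at 200
permutations. Support intervals take the contiguous span within
`drop` (default 2) LOD of the peak, expanded one evaluated position
beyond the boundary on each side; peak ties break leftward and are
flagged. PVE = 1 − 10^(−2·LOD/n) on the fraction scale.

## Allele-frequency differentiation

The exact formula behind the published tool this statistic emulates is
not printed anywhere accessible; the construction here is a documented
interpretation and should be cited as this package's statistic. Per
sample, phred PLs are converted to relative likelihoods and weighted by
Hardy-Weinberg genotype frequencies at allele frequency p; group
log-likelihoods are maximized over p (bounded search, endpoint-checked)
separately per group and pooled; the statistic is
2(lnL_case + lnL_bg − lnL_pooled) with a χ²(1) p-value. With certain
genotypes it reduces exactly to the binomial allele-count LRT. Null
calibration on simulated shared-frequency panels gives type-I ≈ 0.055
at α = 0.05 — the mild liberality expected from boundary effects at
small group sizes.

The candidate-SNP rule requires every non-missing case call to be
homozygous-alt with case call rate ≥ 0.8 (the guard is this package's
choice; the missing-data rule of the original analysis is unstated) and
no background sample homozygous-alt at any call rate. Haplotype groups
are average-linkage clusters on Jaccard distance between samples'
homozygous-alt site sets, cut at similarity 0.5, keeping clusters with
≥ 5 defining SNPs (sites homozygous-alt in all members). The original
groups were at least partly curated by eye; this clustering is a
reproducible stand-in and can split or merge relative to manual
curation on borderline panels.

## Conserved noncoding elements and binding sites

Identity is evaluated per species in 100-bp reference-anchored windows
at step 1, gaps counting as mismatches; a base qualifies when any
covering window exceeds 70% identity. Because a wide window overhangs
an identity transition by up to half its width, boundaries are then
refined: trim each run end inward until the boundary base matches and
the boundary-anchored 20-bp window clears the 70% cutoff (random ~40%
background virtually never sustains that), then further until the
10-bp window clears 85% local identity (so a few adjacent lucky
matches cannot extend the element). Refined runs ≥ 100 bp are the
species' conserved regions. Boundary resolution is limited by the
10-bp fine window: measured error on planted elements is ≤ 3 bp, and a
99-bp element flanked by chance matches can be measured at 100 bp.
Exon masking happens before the length test, so a fragment left after
masking must itself reach 100 bp. CNEs are maximal runs ≥ 100 bp where
at least 10 avian or 3 tetrapod species' regions overlap; the two
clades are computed independently.

PWM scanning uses the Match-style information-weighted similarity:
position weights I = Σ_b f ln(4f), score (current − min)/(max − min)
over the whole matrix and over the 5 consecutive highest-information
positions (the core), both strands, with default cutoffs core 0.75 /
matrix 0.80 (the profile used originally is unpublished; these are
conventional mid-stringency values, configurable per motif).
Gain/loss compares hits keyed by (motif, offset, strand) between the
two alleles. Coordinates are 0-based half-open throughout; VCF
positions are 1-based internally and converted at the BED boundary.

## Duplication and copy-specific expression

Windowed depth (non-overlapping 5-kb tiling — the natural reading of
windowed genome coverage from standard tooling) is normalized as
2 × depth / median(depth), the median being robust to the duplication
itself. Calls are maximal runs of ≥ 3 windows with normalized value
≥ 2.5; the segment mean assigns het (< 3.5) or hom (≥ 3.5) — cutpoints
at the midpoints between expected integer copy-number bands, half-open
so no value falls in two bins. The original call was made by visual
inspection plus PCR; these thresholds are this package's explicit,
configurable equivalent. Soft-clip records near both call edges whose
clipped sequence remaps to the partner edge in tandem orientation
refine breakpoints to the modal clip positions (±1 bp); tied modes
leave the call unrefined with a warning, and absent evidence leaves a
depth-only flag. Depth is always the primary caller; insert-size
discordance only corroborates.

Copy-specific SNP classification pools counts within tissue: white
minor-allele fraction ≤ 0.05 and pigmented ≥ 0.20, with at least one
sample at depth ≥ 10 per tissue (else uninformative). The thresholds
are stated defaults (no numeric rule exists in the source analysis);
at depth ≥ 50 binomial tails make misclassification negligible.
Normalized expression is reads-in-gene / total-reads × 10⁶.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each stage assumes:
1:2:1 segregation with Haldane recombination and symmetric
miscall/missingness noise (defaults 0.5% error, 5% missing — typical
GBS-scale rates); proportion phenotypes with additive/dominance QTL
effects, Gaussian residuals, a 0.5 baseline so the [0,1] clamp is rarely
active (clamp events are counted), and a planted PVE set through
a²/2 = σ²·PVE/(1 − PVE); Hardy-Weinberg panels with group-shared
frequencies and planted case-fixed haplotypes, with PLs generated from
the same symmetric miscall channel the test assumes; alignments with
exact per-base identity levels (mismatch mass split between gaps and
substitutions); Poisson or negative-binomial depth scaled by local copy
number with junction-consistent soft-clips; and binomial allele counts.

It does not emulate: linkage disequilibrium or demography beyond the
planted haplotypes, crossover interference, read-level artifacts
(mapping bias, GC waves, duplicated-region mismapping), indel/gap
structure in conserved elements, population stratification, or
overdispersed RNA-seq counts. Passing tests therefore demonstrate
correctness of the algorithms under their stated models, not robustness
to those real-data pathologies; the statistic most sensitive to this
gap is the differentiation LRT, whose real-data calibration depends on
stratification that is deliberately absent here.

Problem sizes in the validation experiments (5 chromosomes × 50
markers at n = 150, 200-permutation thresholds over 100 null
replicates, 5000-site panels, 50-kb alignments, 1-Mb coverage tracks)
were chosen as the smallest scales at which the planted effects are
statistically unambiguous; all are package defaults in the analysis
scripts and can be raised freely.

## Determinism

Every generator and every stochastic procedure takes an explicit
integer seed; a single global seed expands into independent per-stage
streams (`simdata.stage_rng`), so identical seed + spec reproduces
byte-identical outputs and each stage is reproducible on its own.
Quantile interpolation, optimizer tolerances (1e-10 bounded searches
with endpoint checks), tie-breaking rules (leftmost peak, lowest
scaffold/bp duplicate representative, larger soft-clip mode), and the
LOD cap at 999 are all fixed and documented above so results are
bit-reproducible across runs.
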
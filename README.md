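# piedmap

Genetic dissection of piebald plumage patterning in the domestic pigeon
(*Columba livia*), rebuilt as a tested, simulation-backed analysis
pipeline. Piebalding — patches of white (depigmented) and pigmented
feathers — is quantified per body region, mapped in F2 intercrosses,
localized by population allele-frequency differentiation, and dissected
into candidate coding, regulatory (conserved noncoding element), and
structural (tandem duplication with copy-specific expression) variation.
Every stage runs on synthetic data with planted ground truth, so the
whole workflow is testable on a laptop with no sequence downloads.

Intended users: quantitative/population geneticists who want the
analysis steps of this kind of study as reusable, oracle-tested library
code rather than a one-off script collection.

## What the pipeline computes

**Phenotype.** Proportion of white plumage per body region from pixel
counts: `white = (whole − pigmented) / whole`, over 15 canonical body
regions.

**Linkage map** (`piedmap.linkmap`). From F2 genotypes coded AA/AB/BB:
chi-square 1:2:1 segregation-distortion filter at p < α/M (Bonferroni,
autosomes only), duplicate-marker collapse, 50%/66% genotyping-rate
filters, maximum-likelihood pairwise recombination fractions r̂ from the
phase-known F2 two-locus likelihood, linkage groups as connected
components at (r̂ ≤ 0.15, LOD ≥ 6), greedy scaffold chaining, Haldane
spacing d = −50 ln(1 − 2r), error-LOD genotype cleaning (> 5 erased),
and drop-one-marker evaluation (likelihood gain, or > 10 cM shrink
without physical support).

**QTL scan** (`piedmap.qtlscan`). Haley-Knott regression of the
phenotype on expected additive dosage P(BB) − P(AA) and dominance P(AB)
from a 3-state genotype HMM (stationary prior ¼, ½, ¼; Haldane
transitions; symmetric genotyping-error emissions), on markers plus a
pseudo-marker grid. LOD = (n/2) log₁₀(RSS₀/RSS₁); genome-wide 5%
thresholds from phenotype permutations; 2-LOD support intervals; PVE =
1 − 10^(−2·LOD/n).

**Population differentiation** (`piedmap.popdiff`). A probabilistic
FST-style site test: per-sample genotype likelihoods weighted by
Hardy-Weinberg frequencies at a fitted allele frequency, a
likelihood-ratio statistic 2(lnL_case + lnL_background − lnL_pooled)
against χ²(1), Bonferroni threshold α / n_sites, the candidate-SNP
fixation filter (alt allele homozygous in every case, never homozygous
in background), and haplotype-group delineation by clustering shared
homozygous-alt site sets.

**Conserved noncoding elements** (`piedmap.cneseek`). Reference
intervals ≥ 100 bp conserved at > 70% identity in ≥ 10 avian species or
≥ 3 non-avian tetrapods, exons masked, from 100-bp sliding-window
identity with match-anchored boundary refinement; plus Match-style PWM
scanning to report transcription-factor binding sites gained or lost
between reference and alternate alleles.

**Structural variant & expression** (`piedmap.svdup`). Read depth in
5-kb windows normalized to copy number 2 (median reference), duplication
calls from runs of elevated windows with half-open het/hom cutpoints at
2.5/3.5, base-pair breakpoint refinement from soft-clip junction
evidence, cohort genotype screening, normalized expression
(reads-in-gene per million), and copy-specific SNP classification
(mono-allelic in white tissue, bi-allelic in pigmented).

**Simulators** (`piedmap.simdata`) generate each input class with
planted truth: F2 crosses under Haldane recombination, proportion
phenotypes from planted QTLs, case/background panels with planted fixed
haplotypes and phred-scaled PLs, alignments with planted conserved
elements, coverage tracks with a planted 37-kb tandem duplication, and
allele-count tables with planted copy-specific SNPs.

## Worked example

The analysis is a numbered sequence of scripts; each consumes the
previous one's outputs under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_build_map.py
python analysis/03_qtl_scan.py --seed 1 --n-perm 200
python analysis/04_popdiff.py
python analysis/05_cne_tfbs.py
python analysis/06_dup_expression.py
```

Output from a run with `--seed 1` (abridged):

```
F2 cross: 250 markers x 150 birds; planted QTL chr3@50cM, realized PVE 0.593
Input markers: 250; retained on map: 250 in 5 groups (0 genotypes erased, ...)
  LG3: 50 markers, 118.0 cM (true 100.0 cM)
dorsal body: max LOD 29.5, 5% threshold 3.23 (200 permutations)
  QTL on LG3: peak 59.0 cM (marker pseudo), LOD 29.5, PVE 59.6%,
  2-LOD interval [57.0, 61.0] cM
2000 sites tested; Bonferroni threshold 2.5e-05; 5 genome-wide significant
5 candidate SNPs (fixed in cases, never hom-alt in background), spanning 101000-101400
Haplotype group 1: 20 samples, 5 defining SNPs at scf507:101000-101400
avian CNE 12000-12180 (180 bp, >= 11 species, mean identity 0.95)
Allele swap at CNE position 12164: 0 motifs gained, 1 lost
Duplication scf507:500000-537000 (37 kb), het, mean CN 3.00, breakpoints +/-1 bp
6 of 40 SNPs classified copy-specific
```

Reading the numbers: the scan recovers the planted chromosome-3 QTL
(LOD 29.5 far above the permutation threshold 3.23; the estimated PVE,
59.6%, matches the realized planted PVE 0.593); the five planted fixed
SNPs are exactly the candidate set and define one haplotype group; both
planted conserved elements are found with ~bp-accurate boundaries and a
core-destroying allele swap loses one binding motif; the planted 37-kb
heterozygous duplication is called with exact soft-clip-refined
breakpoints, and exactly the six planted copy-specific SNPs are
recovered.

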
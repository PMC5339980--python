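# Methods

`seqselect` is a desk-scale reconstruction of the workflow used to decide
which whole-genome sequence variants are worth adding to routine genomic
prediction in a large pedigreed dairy population: simulate sequence
genotypes through the pedigree, edit the variant list, impute everything
to sequence density, rank variants by association or estimated effect,
refit marker effects on each candidate panel, and score the resulting
predictions against truth. This note records the models, the defaults and
why they were chosen, and what the synthetic data can and cannot say
about real cattle data.

## Population and genotype simulation

**Founder haplotypes.** Each chromosome has a small ancestral pool
(default `pool_size = 4`) of haplotypes whose alleles are Bernoulli draws
at the catalog frequencies (frequencies themselves uniform on
[0.01, 0.99]). A founder haplotype copies one pool member and switches to
a random pool member with probability `1 - ld_param` at each variant.
Adjacent-variant LD therefore rises monotonically with `ld_param`, and
marginal allele frequencies match the catalog in expectation (with
pool-sampling noise of order `sqrt(p(1-p)/pool_size)` per variant).

**LD calibration.** `ld_param` is a per-variant switch probability, so
its value must depend on variant density. The desk default
`ld_param = 0.9933` at 30,000 variants per 100-Mb chromosome was
calibrated against the published summary of real sequence data — the
mean over variants of the maximum |r| with the 350 variants on either
side is about 0.96 — and coincides with the per-base-pair translation of
the value 0.9998 used at full sequence density (~1M variants per
chromosome). At desk density the untranslated value produces ancestral
blocks spanning ~20% of a chromosome, which makes any array a perfect
tag of every QTL and removes the phenomenon the pipeline studies.

**Gene drop.** Non-founders receive one gamete per parent; crossover
counts are Poisson with mean `chrom_length_morgans` (default 1 Morgan
per 100-Mb chromosome, no interference), positions uniform in base
pairs. An animal with one unknown parent receives that gamete from a
randomly chosen founder. Mendelian consistency holds exactly at every
cell by construction and is asserted in the tests.

**Pedigree.** Discrete generations with heavy sire usage (default 25
sires per 300 offspring) mimic dairy-style half-sib family structure.
The default scale is 300 founders + 9 generations x 300 = 3,000 animals,
3 chromosomes x 30,000 variants, nested array analogues of
18,000 / 6,000 / 1,200 variants, 500 QTL and 5 traits. The array
analogues are deliberately denser, relative to the sequence, than the
real 600k/60k/12k chips: the desk genome is ~1/300 of the real one and
scaling the arrays by the same factor would leave too few markers per
Morgan for genomic prediction to function at all.

**Trait architecture.** QTL positions are drawn uniformly without
replacement and shared across traits; per-trait effects are
`alpha = q * base^(|q| - 2)` with `q ~ N(0,1)` and `base = 2.7`. The
per-locus variance `2p(1-p)alpha^2` then concentrates as published for
this transform: across 10,000 QTL the largest locus contributes roughly
3-13% of the additive variance, the top 10 about 20-34%, the top 100
about 57-63% and the top 1,000 about 90-93%; the acceptance script
recomputes these shares from scratch. The transform is read
multiplicatively (`q` times `base^(|q|-2)`), since raising a negative
normal deviate to a real power is undefined; the printed concentration
ranges validate the reading.

**Phenotypes.** `y = TBV + e` with `var(e) = sigma_g^2 (1 - R)/R`, so
`var(TBV)/var(y) = R`, the reliability of a deregressed evaluation.
Reference animals default to R = 0.9 (high-reliability progeny-tested
bulls); the per-animal values are configurable. A zero-variance trait
returns `y = TBV` with a logged warning rather than erroring, so
degenerate configurations stay debuggable.

## Editing

Edits follow routine practice, each with its published threshold: MAF
below 0.01 removed ("lower than" is strict, so MAF exactly 0.01 stays);
LD pruning removes a variant correlated at |r| > 0.95 with an
already-kept variant among the previous 350 kept variants on the same
chromosome, or with a protected variant within the next 350 positions —
protected markers always win over unprotected duplicates regardless of
scan order (otherwise the ascending-position scan keeps the earlier
variant; a raw-count window mode is available because the published
description does not say which was used); genotype-probability masking (call set
missing when no class probability exceeds 0.98, alternate 0.95);
missingness limits of 5% for MAF < 0.10 and MAF/2 otherwise; excess
heterozygosity above 1.5 x 2p(1-p); chip-vs-sequence orientation by
dosage correlation (|r| >= 0.95 keeps, <= -0.95 flips, otherwise drop);
and opposite-homozygote Mendelian conflicts set missing (offspring side
by default; both sides by flag — the published account does not say
which call is blanked). Variants within 2,500 bp of a QTL and all
array-tier variants are protected from removal, because previously
genotyped markers must survive for imputation. Filters are idempotent
and the MAF -> LD order with per-stage counts mirrors the published edit
table.

## Imputation

The imputer is a from-scratch greedy minimum-mismatch matcher in the
spirit of haplotype-library imputation programs; it is not a port of any
of them. Reference animals with phased sequence genotypes define, per
chromosome window, the list of distinct haplotypes with population
counts. For each target animal and window, the best haplotype pair is
found by alternating conditional search over the `top_candidates = 30`
haplotypes with the fewest homozygote incompatibilities (fix one member,
exactly optimise the other, repeat); ties prefer the higher population
count, then listing order. Missing dosages are filled from the chosen
pair; observed dosages are never altered.

Window levels default to (500, 250, 125, 62) variants: a window match is
accepted when its mismatches are at most 2 per 100 observed dosages,
otherwise the next (shorter) level retries, which localises
recombination breakpoints. At the final level the best available pair is
accepted unconditionally (a finite reference never contains every
population haplotype); setting `best_effort_final_level=False` restores
strict behaviour, leaving unresolved cells missing.

When a pedigree is supplied, animals are matched in pedigree order and
each animal's candidate set also contains the window haplotypes just
assigned to its parents — a gamete is a recombinant of one parent's
pair, so these are the strongest candidates and accuracy propagates down
the pedigree the way pedigree-aware imputation programs exploit. Two
further refinements matter: parental and continuation candidates win
mismatch ties over merely-common haplotypes (the pedigree prior is far
stronger than population frequency exactly where the observed markers
are ambiguous), and windows are processed left-to-right per chromosome
so each animal also receives the haplotypes that extend its
previous-window choice through the reference gametes (inheritance
switches only at crossovers, about once per Morgan). Only animals with
missing cells, plus their ancestor closure, are matched in a window.

Residual missing cells are replaced by twice the allele frequency before
prediction, which is also the exact centering point, so unimputed cells
contribute zero information rather than bias.

The mask-and-restore harness mirrors the published evaluation: hold
out test animals (default split mirrors a 404-reference / 40-test
design), reduce them to an array subset, impute back to sequence, and
report the percentage of masked dosages restored exactly (allele-level
scoring by flag; the published text does not say which unit it counts).
Unresolved cells count as incorrect. The floor for comparison is the
closed-form Hardy-Weinberg random-fill concordance `sum_g f_g^2`
averaged over masked variants.

## Variant selection

Three statistics: (1) GWA — per-variant fixed effect in the mixed model
`y = mu + x beta + u + e`, `var(u) = A sigma_a^2` on the pedigree
relationship matrix, solved exactly by GLS rotation through the Cholesky
factor of `V = h2 A + (1 - h2) I`; with `h2 = 0` this is identically the
ordinary single-marker t-test. Per-trait p-values combine by Fisher's
`-2 sum log p` (the published account does not name its combination
rule; Fisher is the documented stand-in). (2) Largest absolute estimated
effect `|alpha|` from whole-genome regression. (3) Largest estimated
locus variance `2p(1-p)alpha^2`. Top-k lists per trait are merged with
duplicates removed (k x traits is the upper bound); an
average-across-traits mode mimics index selection. A greedy base-pair
window pruner (accept best, suppress lower-scoring variants within the
window) reproduces the array-design thinning step. An optional
conditional re-scan refits each candidate with already-selected
neighbours within 1 Mb as covariates; it is off by default because the
exact conditioning scheme of the original GWA runs is not published.

## Marker-effect estimation

Single-trait coordinate descent (Gauss-Seidel with residual update) on
the mixed-model equations. With reliabilities supplied, the residual
weight is `R/(1-R)` (deregression weighting; capped at 1e6 as R -> 1)
and the base residual variance equals `sigma_g^2`, which makes the
marker ridge `lambda = m/(1 - polygenic_fraction)` free of any variance
estimate. Unweighted fits use `sigma_g^2 = heritability x var(y)`
(default heritability 0.30). The polygenic term uses Henderson's sparse
A-inverse (inbreeding ignored — exact for non-inbred pedigrees, the
standard approximation otherwise) with one Gauss-Seidel pass per round.

Nonlinear ("heavy-tailed") mode rescales each marker's prior variance
every round by `curve^(min(|alpha_j|/sd(alpha), cap) - 2)`, with
`curve = 1.12` and `cap = 5` by default; `curve = 1` reproduces linear
SNP-BLUP exactly (asserted in tests). The QTL-only ceiling scenario uses
`curve = 2.7` (the true simulation parameter), no cap and no polygenic
fraction. The published source for this estimator does not print its
curve parameter; 1.12 is this package's default and both values are
configurable. Convergence is declared when the largest absolute effect
change in a round falls below `tol` (library default 1e-6, experiment
default 1e-4 at the desk problem sizes); hitting `max_iter` flags
non-convergence on the result rather than raising.

## Validation

Simulation-style reliability is `100 cor(GEBV, TBV)^2` on validation
animals excluded from training by construction. Real-data-style
reliability divides `100 cor(pred, dereg)^2` by the mean reliability of
the deregressed evaluations (scalar division; per-animal rescaling is a
switchable alternative, as the published wording admits both) and adds
the observed-minus-expected parent-average reliability, capping at 100
with a warning. The expected PA reliability convention, when not
supplied, is `mean((rel_sire + rel_dam)/4)`. Bias is the least-squares
slope of validation data on predictions (expectation 1). The economic
arithmetic is `sqrt(rel_new/rel_old)` for the accuracy ratio and
`progress x (ratio - 1) x replacements` for annual value.

## The experiment driver

`run_experiment` composes the stages under one master seed (per-stage
child generators are derived deterministically, so every report is
byte-identical given config + seed). Animals are genotyped by tier —
oldest 10% at sequence, next 5% at the 600k analogue, a 2% scatter at
the 12k analogue, the rest at the 60k analogue — mirroring the real
genotyping census, where the most-used ancestors are sequenced and only
a small minority of bulls carry the low-density chip. The
working variant set is the edited union of the dense array tier, the
genic (near-QTL) sequence variants and the QTL; all animals are imputed
to it. The last 20% of animals (in pedigree order) are validation; their
phenotypes never enter effect estimation or selection. Four scenarios
are scored per trait: parent average of phenotype-based evaluations, the
60k-analogue array, the array plus variants selected from the working
pool by the configured statistic, and the true QTL alone.

## What the generator does and does not emulate

Emulated: multi-generation pedigree structure with intense sire
selection, adjacent-marker LD of realistic summary magnitude, nested
array tiers, a heavy-tailed architecture matching the published
variance-concentration ranges, reliability-calibrated pseudo-phenotypes,
and mixed genotyping densities that force imputation.

Not emulated: mutation and coalescent history (founder diversity is a
4-haplotype pool, so rare haplotypes are systematically undersampled and
imputation is easier than on real data at low MAF); sequencing and
variant-calling error (real call-probability edits matter more than
here); sex chromosomes; InDels beyond a type label; genotyping platform
error; multi-breed structure; and map errors. Passing tests therefore
demonstrate internal correctness of the algorithms and the direction and
ordering of information gains, not the magnitudes attainable on real
data — full-scale reliabilities cannot be reproduced at 3,000 animals
and 90,000 variants, and the tests assert orderings and gaps, never the
published magnitudes.

## Numerical choices

Dosages are int8 with -1 as missing; correlation in LD pruning is
computed over animals called for both variants, with zero-variance pairs
treated as uncorrelated; monomorphic variants in GWA get p = 1 with a
logged skip, while a zero-residual (perfect) fit gets p = 0; Fisher
combination clamps p = 0 to the smallest positive double with a warning;
selection rankings use stable sorts so ties resolve by variant order;
the LD-prune scan compares against kept neighbours nearest-first and
stops at the first conflict. Desk problem sizes (3 chromosomes, 3,000
animals, ~20,000 working variants, 150 solver rounds) were chosen so a
replicate of the full experiment completes in a few minutes on one core.
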
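# Methods

## Site and genotype model

A cohort is a list of `SiteRecord`s (chromosome, 1-based position, REF, up
to three ALTs, per-sample diploid genotypes as allele-index pairs) plus a
`CohortPanel` (sample → population → continent). Only records whose FILTER
is PASS or "." enter analyses by default (`pass_only=False` keeps all);
missing allele calls are preserved and excluded from every allele-count
denominator. SNP identity is keyed on (chrom, pos, alt) so tri-allelic
sites contribute one key per ALT and never collapse; a positional
(chrom, pos) mode exists for novelty catalogs that lack alleles, since
whether catalog matching should be allele-aware is a genuine judgement
call — both modes are exposed and allele-aware is the default.

BED inputs (0-based half-open) are converted to the internal 1-based
inclusive convention on read and back on write.

## Pairwise SNP-sharing distance

D = 1 − |S₁∩S₂| / min(|S₁|, |S₂|). The min() denominator scales D into
[0, 1] and makes D = 0 exactly when one repertoire nests in the other, which
matches the interpretation that low D means SNPs of one sample are likely
present in the other. Membership is presence-only: heterozygous and
homozygous carriers contribute identically. Per-population summaries report
min/q1/median/q3/max over all n(n−1)/2 within-population pairs using the
median-unbiased quantile convention (`numpy.quantile(...,
method="median_unbiased")`), chosen so the boxplot statistics are exactly
reproducible. `subsample_normalize` reduces every population to the same
size (default 36) with a seeded draw, dropping (with a warning) populations
below that size, to remove sample-size confounding when comparing
distributions across populations.

## Het/Hom, Ts/Tv, CpG and frequency classes

Het/Hom is per-sample heterozygous over homozygous-ALTERNATIVE genotype
counts. The non-reference denominator is the convention under which human
whole-genome values land in the observed 1.4–2.0 band (hom-ref denominators
give ratios far below 1); a sample with zero hom-alt genotypes raises rather
than reporting an infinite ratio. Multi-allelic genotypes are included by
default (1/2 is heterozygous, 2/2 homozygous-alt); `biallelic_only=True`
restricts to bi-allelic sites. Population-level Het/Hom is the arithmetic
mean over samples plus boxplot quartiles.

Ts/Tv counts transitions (A↔G, C↔T) against transversions over bi-allelic
SNPs. Zero transitions with nonzero transversions is a valid ratio of 0;
zero transversions is an error. CpG context is evaluated on the forward
reference strand only (site base with next base, or previous base with site
base, reading "CG"), with no reverse-strand complementing; the choice is
recorded here because genome-wide CpG fractions differ slightly between the
two conventions. The allele-frequency split is low (AAF < 0.05) vs common
(AAF ≥ 0.05), boundary inclusive on the common side.

## Sharing matrices

A population is present at a key iff ≥ 1 of its samples carries ≥ 1 ALT
copy — no frequency threshold, because the statistic counts SNP presence.
The matrix stores exactly-two counts symmetrically; the conservation
identity used in tests counts unique cells (diagonal + upper triangle) plus
the separately-reported count of keys in ≥ 3 populations, which together
equal the number of segregating keys. Continental aggregation bins each
exactly-two event under the partner population's continent.

## ABBA/BABA D-statistic

Informative sites require: all four alleles called, exactly two distinct
alleles among the four, a transversion between them, archaic ≠ outgroup, and
(implied by the pattern definitions) G1 ≠ G2. The outgroup allele defines
state A. D = (N_BABA − N_ABBA)/(N_BABA + N_ABBA), reported ×100 as %D.

Diploid inputs are collapsed to one allele per genome by a policy:
`random_draw` (default, seeded — the common practice for archaic-admixture
counting), `homozygous_only`, or `major_allele` (deterministic alphabetical
tie-break). The policy and seed are recorded in run manifests.

Blocks are fixed windows anchored at position 1 on each chromosome
(default 5 Mb, no centromere masking); empty blocks are dropped. The default
jackknife is the equal-weight delete-one estimator over the M informative
blocks:

    SE² = (M−1)/M · Σⱼ (D₍₋ⱼ₎ − mean D₍₋ⱼ₎)²,   Z = D / SE

A count-weighted (Busing-style) variant is available via `weighted=True`;
for roughly balanced blocks the two agree closely. When every block yields
the same delete-one estimate the SE is 0 and the result carries a
`degenerate_variance` flag with Z = NaN instead of an infinite Z. Z is
defined as D/SE throughout; no attempt is made to replicate external sign
conventions for Z that disagree with the sign of D.

## Structural-deletion consensus

Order of operations: size filter (50 bp ≤ length ≤ 10 Mb, inclusive) on
caller-level calls, then within-sample, within-chromosome transitive
chaining of calls that overlap by ≥ 1 bp (abutting calls do not merge) into
union-boundary consensuses. Because unions can exceed the size window, a
post-merge re-check is available but off by default. Novelty is one-sided:
the fraction of the *query* span covered by the union of catalog intervals
(no double counting across overlapping or split catalog entries), novel iff
strictly < 0.5. A reciprocal mode (some single catalog interval covering
≥ 50% of both query and itself) is provided behind a flag. Novelty is
assessed on the cross-sample union of consensuses by default; per-sample
assessment is a matter of passing per-sample call sets.

## Synthetic generators

All generators are pure functions of their configs; the same seed gives
byte-identical output files.

**Cohort.** Balding–Nichols: per site an ancestral frequency p ~
U(0.05, 0.95); per population q ~ Beta with mean p and variance F·p(1−p)
(shape a = p(1−F)/F, b = (1−p)(1−F)/F); genotypes Binomial(2, q). Expected
within-population heterozygosity is 2p(1−p)(1−F), giving closed-form
monotonicity targets for tests. Defaults — three populations of 36 samples
(the size-normalized cohort size) with F = 0.01/0.05/0.15 — emulate the
African > European > East-Asian diversity ordering at continent scale.
Sites are unlinked at fixed 100 bp spacing on one contig: linkage
disequilibrium is irrelevant to every statistic in scope except jackknife SE
realism, which the block simulator models directly at the block level.

**Four-genome sites.** Each site is independently BABA with p_baba, ABBA
with p_abba, otherwise uninformative (archaic = outgroup); emitted
substitutions are always transversions with the outgroup carrying state A.
Sites are assigned uniformly to contiguous 5 Mb blocks. Two layers share
the same pattern stream per seed: `simulate_dstat_patterns` returns the
block/pattern arrays for large-scale calibration, and
`simulate_dstat_sites` renders the identical draws as a concrete allele
table; a unit test verifies site-by-site classification of the rendered
table reproduces the pattern layer exactly, so calibration results on the
array layer are results about the full classifier pipeline. Expected
D = (p_baba − p_abba)/(p_baba + p_abba).

**Deletions.** Truth intervals with log-uniform lengths (default
100 bp – 10 kb) placed without overlap by rejection; four callers each
detect a truth with probability 0.8, boundaries shifted by rounded
N(0, 10 bp) jitter, plus 5 uniformly placed false positives per caller.
P(≥ 1 caller detects) = 1 − (1−p)⁴ is the closed-form check.

What the generators do not emulate: linkage disequilibrium and haplotype
structure, sequencing/genotyping error, ancient-DNA damage beyond the
transversion restriction, realistic transition/transversion bias (substitution
types are uniform), site-frequency-spectrum shape beyond Balding–Nichols,
and caller-specific error modes. Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated models, not
robustness to artefacts of real sequencing data.

## Problem sizes and numerical choices

The jackknife null calibration runs 1,000 replicates of 10⁶ sites in 200
blocks at p_BABA = p_ABBA = 0.0025 and checks that |Z| > 1.96 in 3–7% of
replicates; the signal run uses 100 replicates at p_BABA = 0.003,
p_ABBA = 0.002 against the analytic SE of the conditional binomial ratio
(Var(D) = 4q(1−q)/E[S], q = p_b/(p_b+p_a)). The diversity-ordering check
uses three populations of 36 samples at 4,000 sites; sharing conservation
runs 50 random small configs. Degenerate inputs: empty SNP sets, all-missing
sites, zero hom-alt samples, zero transversions, < 2 jackknife blocks and
both-zero pattern counts all raise with specific messages rather than
returning sentinel values; zero transitions and degenerate jackknife
variance are flagged valid outputs.

## Known limitations

Novelty percentages, genome-wide Ts/Tv, Het/Hom levels and the jackknife
SE/Z of real comparisons depend on the underlying genomes and catalogs and
cannot be reproduced from synthetic data; the suite checks their mechanisms
(boundaries, conservation, calibration) instead. Indel normalization,
genotype likelihoods, phasing, annotation, F_ST/PCA/ADMIXTURE-style
structure inference and non-deletion SV classes are out of scope.
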
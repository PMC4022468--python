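"""Per-sample and per-population QC on a simulated cohort.

Het/Hom is the count of heterozygous genotypes over homozygous-alternative
genotypes per sample; under Hardy–Weinberg at alt frequency q it tends to
2(1−q)/q, and diverse populations sit higher.  Ts/Tv is the transition /
transversion count ratio over bi-allelic SNPs; the low/common split counts
ALT alleles below vs at-or-above 5% frequency.
"""

import tempfile
from pathlib import Path

from popdiv import cohort_metrics, simulate, variant_io

workdir = Path(tempfile.mkdtemp())
cfg = simulate.PopGenConfig(n_populations=2, samples_per_pop=10, n_sites=3000,
                            fst_per_pop=(0.02, 0.2), seed=7)
simulate.simulate_cohort(cfg, workdir / "cohort.vcf", workdir / "popmap.tsv")
sites, panel = variant_io.read_cohort(workdir / "cohort.vcf", workdir / "popmap.tsv")

metrics = cohort_metrics.sample_metrics(sites, panel)
print(cohort_metrics.population_het_hom(metrics, panel)
      [["population", "n_samples", "mean", "median"]].to_string(index=False))

tstv = cohort_metrics.ts_tv_ratio(sites)
print(f"\nTs/Tv over bi-allelic SNPs: {tstv.ratio:.2f} "
      f"({tstv.n_transitions} transitions / {tstv.n_transversions} transversions)")
print("(the generator draws substitutions uniformly, so Ts/Tv is near 0.5;")
print(" real genomes sit near 2 genome-wide because transitions dominate)")

n_low = n_common = 0
for s in sites:
    for aaf in variant_io.alt_allele_frequency(s):
        if variant_io.frequency_class(aaf) == "low":
            n_low += 1
        else:
            n_common += 1
print(f"\nAAF classes at the 5% split: {n_low} low-frequency, {n_common} common")
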
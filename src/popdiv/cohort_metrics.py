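"""Per-sample and per-population QC metrics: Het/Hom, Ts/Tv, CpG context.

Het/Hom uses homozygous-ALTERNATIVE genotypes in the denominator (the
non-reference convention): with hom-ref in the denominator the ratio on
whole-genome data would sit far below 1, whereas the non-ref convention
gives the familiar 1.4–2.0 range across human populations.  Multi-allelic
genotypes count: 1/2 is heterozygous, 2/2 is homozygous-alt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .variant_io import CohortPanel, SiteRecord, is_transversion


@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    n_het: int
    n_hom_alt: int
    n_hom_ref: int
    n_missing: int
    n_snps: int

    @property
    def het_hom(self) -> float:
        if self.n_hom_alt == 0:
            raise ZeroDivisionError(
                f"{self.sample_id}: no homozygous-alt genotypes; Het/Hom undefined"
            )
        return self.n_het / self.n_hom_alt


@dataclass(frozen=True)
class TsTvSummary:
    n_transitions: int
    n_transversions: int

    @property
    def ratio(self) -> float:
        if self.n_transversions == 0:
            raise ZeroDivisionError("no transversions; Ts/Tv undefined")
        return self.n_transitions / self.n_transversions


def het_hom_ratio(n_het: int, n_hom_alt: int) -> float:
    """Heterozygous / homozygous-alternative genotype count ratio."""
    if n_hom_alt == 0:
        raise ZeroDivisionError("no homozygous-alt genotypes; Het/Hom undefined")
    return n_het / n_hom_alt


def _classify_gt(gt: tuple[Optional[int], Optional[int]]) -> str:
    a, b = gt
    if a is None or b is None:
        return "missing"
    if a == b:
        return "hom_ref" if a == 0 else "hom_alt"
    return "het"


def sample_metrics(
    sites: Iterable[SiteRecord],
    panel: CohortPanel,
    biallelic_only: bool = False,
) -> list[SampleMetrics]:
    """Genotype-class counts per sample over SNP sites.

    Per sample the four classes partition the SNP sites:
    n_het + n_hom_alt + n_hom_ref + n_missing = number of SNP sites.
    """
    counts = {s: {"het": 0, "hom_alt": 0, "hom_ref": 0, "missing": 0} for s in panel.samples}
    snp_keys: dict[str, set] = {s: set() for s in panel.samples}
    for site in sites:
        if not site.is_snp():
            continue
        if biallelic_only and len(site.alts) != 1:
            continue
        for sample, gt in zip(panel.samples, site.genotypes):
            counts[sample][_classify_gt(gt)] += 1
            for idx in gt:
                if idx is not None and idx >= 1:
                    snp_keys[sample].add((site.chrom, site.pos, site.alts[idx - 1]))
    return [
        SampleMetrics(
            sample_id=s,
            n_het=counts[s]["het"],
            n_hom_alt=counts[s]["hom_alt"],
            n_hom_ref=counts[s]["hom_ref"],
            n_missing=counts[s]["missing"],
            n_snps=len(snp_keys[s]),
        )
        for s in panel.samples
    ]


def metrics_frame(metrics: Sequence[SampleMetrics], panel: CohortPanel) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "sample_id": m.sample_id,
                "population": panel.population_of[m.sample_id],
                "continent": panel.continent_of[panel.population_of[m.sample_id]],
                "n_het": m.n_het,
                "n_hom_alt": m.n_hom_alt,
                "n_hom_ref": m.n_hom_ref,
                "n_missing": m.n_missing,
                "n_snps": m.n_snps,
                "het_hom": m.het_hom,
            }
        )
    return pd.DataFrame(rows)


def population_het_hom(metrics: Sequence[SampleMetrics], panel: CohortPanel) -> pd.DataFrame:
    """Per-population mean Het/Hom plus boxplot statistics.

    Returns one row per population with mean, min, q1, median, q3, max and
    n_samples.  Raises on a population with no samples carrying a metric.
    """
    df = metrics_frame(metrics, panel)
    out = []
    for pop in panel.populations:
        vals = df.loc[df["population"] == pop, "het_hom"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"population {pop!r} has no samples with metrics")
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="median_unbiased")
        out.append(
            {
                "population": pop,
                "continent": panel.continent_of[pop],
                "n_samples": int(vals.size),
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(out)


def ts_tv_ratio(sites: Iterable[SiteRecord]) -> TsTvSummary:
    """Transition/transversion counts over bi-allelic SNP sites.

    Non-SNP and multi-allelic records are ignored so callers can pass the
    full site list.
    """
    n_ts = n_tv = 0
    for site in sites:
        if not site.is_biallelic_snp():
            continue
        if is_transversion(site.ref, site.alts[0]):
            n_tv += 1
        else:
            n_ts += 1
    return TsTvSummary(n_ts, n_tv)


def cpg_fraction(
    sites: Sequence[SiteRecord],
    reference_fasta: str,
) -> float:
    """Fraction of sites whose reference context is a CpG dinucleotide.

    A site is in CpG context if its reference base together with the next
    base reads "CG", or the previous base together with the site base reads
    "CG" — forward strand only.
    """
    ref = Fasta(reference_fasta)
    n_cpg = 0
    n = 0
    for site in sites:
        if site.chrom not in ref:
            raise ValueError(f"contig {site.chrom!r} absent from {reference_fasta}")
        contig = ref[site.chrom]
        if site.pos > len(contig):
            raise ValueError(
                f"{site.chrom}:{site.pos} beyond contig length {len(contig)}"
            )
        n += 1
        base = contig[site.pos - 1].seq.upper()
        nxt = contig[site.pos].seq.upper() if site.pos < len(contig) else ""
        prv = contig[site.pos - 2].seq.upper() if site.pos >= 2 else ""
        if (base == "C" and nxt == "G") or (prv == "C" and base == "G"):
            n_cpg += 1
    if n == 0:
        raise ValueError("no sites supplied")
    return n_cpg / n
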
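"""Multi-sample VCF input, site classification, and tabular output.

The in-memory model is deliberately small: a :class:`SiteRecord` per VCF
record (chromosome, position, alleles, per-sample genotype allele-index
pairs) and a :class:`CohortPanel` mapping samples to populations and
populations to continents.  All downstream statistics — per-sample SNP
sets, sharing matrices, Het/Hom — are derived from these two objects.

Coordinates are 1-based inclusive throughout (the VCF convention).
Missing genotype calls are preserved as ``None`` allele indices and are
excluded from allele-count denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pysam

Genotype = tuple[Optional[int], Optional[int]]
SiteKey = tuple[str, int, str]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SiteRecord:
    """One variant site with per-sample diploid genotypes.

    ``genotypes[i]`` is an ordered pair of allele indices for the i-th
    sample of the cohort (0 = REF, 1.. = ALTs); ``None`` marks a missing
    allele call.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[Genotype, ...]
    filter_pass: bool = True

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def is_biallelic_snp(self) -> bool:
        return self.is_snp() and len(self.alts) == 1


@dataclass(frozen=True)
class CohortPanel:
    """Sample ordering plus sample→population and population→continent maps."""

    samples: tuple[str, ...]
    population_of: dict[str, str]
    continent_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.population_of]
        if missing:
            raise ValueError(f"samples without a population: {missing}")
        for pop in set(self.population_of.values()):
            if pop not in self.continent_of:
                raise ValueError(f"population {pop!r} has no continent assignment")

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of[s], None)
        return tuple(seen)

    def samples_in(self, population: str) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.population_of[s] == population)

    def restrict(self, samples: Sequence[str]) -> "CohortPanel":
        keep = set(samples)
        return CohortPanel(
            samples=tuple(s for s in self.samples if s in keep),
            population_of={s: p for s, p in self.population_of.items() if s in keep},
            continent_of=dict(self.continent_of),
        )


@dataclass
class SampleSnpSet:
    """The (chrom, pos, alt) keys at which one sample carries ≥1 alt copy."""

    sample_id: str
    keys: set[SiteKey] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.keys)


def read_popmap(path: str | Path) -> CohortPanel:
    """Read a 3-column TSV (sample_id, population, continent), header optional."""
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    cont_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":  # header
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            sample, pop, cont = parts[0], parts[1], parts[2]
            if sample in pop_of:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if pop in cont_of and cont_of[pop] != cont:
                raise ValueError(
                    f"{path}:{lineno}: population {pop!r} mapped to two continents"
                )
            samples.append(sample)
            pop_of[sample] = pop
            cont_of[pop] = cont
    return CohortPanel(tuple(samples), pop_of, cont_of)


def read_cohort(
    vcf_path: str | Path,
    popmap_path: str | Path,
    pass_only: bool = True,
) -> tuple[list[SiteRecord], CohortPanel]:
    """Load a multi-sample VCF and its population map.

    Sites are returned ordered by (chrom, pos); samples keep the VCF
    header order.  Records whose FILTER is neither PASS nor "." are
    dropped unless ``pass_only=False``.

    Raises ``ValueError`` if a VCF sample is absent from the population
    map or a genotype cannot be parsed.
    """
    panel_full = read_popmap(popmap_path)
    vcf = pysam.VariantFile(str(vcf_path))
    vcf_samples = tuple(vcf.header.samples)
    absent = [s for s in vcf_samples if s not in panel_full.population_of]
    if absent:
        raise ValueError(
            f"VCF sample(s) missing from population map {popmap_path}: {absent}"
        )
    panel = CohortPanel(
        samples=vcf_samples,
        population_of={s: panel_full.population_of[s] for s in vcf_samples},
        continent_of=dict(panel_full.continent_of),
    )

    sites: list[SiteRecord] = []
    for rec in vcf:
        filters = list(rec.filter.keys())
        filter_pass = filters in ([], ["PASS"])
        if pass_only and not filter_pass:
            continue
        alts = tuple(rec.alts or ())
        gts: list[Genotype] = []
        for s in vcf_samples:
            try:
                gt = rec.samples[s].get("GT", (None, None))
            except Exception as exc:  # pragma: no cover - htslib-level failure
                raise ValueError(
                    f"{vcf_path}: malformed GT at {rec.chrom}:{rec.pos} sample {s}: {exc}"
                ) from exc
            if gt is None:
                gt = (None, None)
            if len(gt) == 1:
                gt = (gt[0], None)
            if len(gt) != 2:
                raise ValueError(
                    f"{vcf_path}: non-diploid GT at {rec.chrom}:{rec.pos} sample {s}"
                )
            for idx in gt:
                if idx is not None and idx > len(alts):
                    raise ValueError(
                        f"{vcf_path}: allele index {idx} out of range at {rec.chrom}:{rec.pos}"
                    )
            gts.append((gt[0], gt[1]))
        sites.append(
            SiteRecord(rec.chrom, rec.pos, rec.ref, alts, tuple(gts), filter_pass)
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites, panel


def allelicity(site: SiteRecord) -> str:
    """Classify a SNP as biallelic / triallelic / quadallelic by ALT count."""
    if not site.is_snp():
        raise ValueError(f"{site.chrom}:{site.pos} is not a SNP")
    n = len(site.alts)
    try:
        return {1: "biallelic", 2: "triallelic", 3: "quadallelic"}[n]
    except KeyError:
        raise ValueError(
            f"{site.chrom}:{site.pos}: {n} ALT alleles exceed the quad-allelic class"
        ) from None


def alt_allele_frequency(site: SiteRecord) -> tuple[float, ...]:
    """Per-ALT allele frequency: alt copies / non-missing allele calls."""
    counts = [0] * len(site.alts)
    n_called = 0
    for gt in site.genotypes:
        for idx in gt:
            if idx is None:
                continue
            n_called += 1
            if idx >= 1:
                counts[idx - 1] += 1
    if n_called == 0:
        raise ValueError(f"{site.chrom}:{site.pos}: all genotypes missing")
    return tuple(c / n_called for c in counts)


def frequency_class(aaf: float, threshold: float = 0.05) -> str:
    """Split into 'low' (AAF < threshold) and 'common' (AAF ≥ threshold)."""
    if not 0.0 <= aaf <= 1.0:
        raise ValueError(f"AAF {aaf} outside [0, 1]")
    return "common" if aaf >= threshold else "low"


def load_catalog(
    path: str | Path,
    match_mode: Literal["allele", "position"] = "allele",
) -> set[tuple]:
    """Load a known-variant catalog as a set of site keys.

    Accepts a VCF (one key per ALT) or a TSV with columns chrom, pos[, alt].
    ``match_mode='allele'`` keys on (chrom, pos, alt); ``'position'`` keys on
    (chrom, pos).
    """
    path = Path(path)
    keys: set[tuple] = set()
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        for rec in pysam.VariantFile(str(path)):
            for alt in rec.alts or ():
                keys.add(
                    (rec.chrom, rec.pos, alt)
                    if match_mode == "allele"
                    else (rec.chrom, rec.pos)
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("chrom\t"):
                    continue
                parts = line.split("\t")
                if match_mode == "allele":
                    if len(parts) < 3:
                        raise ValueError(
                            f"{path}:{lineno}: allele-aware catalog needs chrom, pos, alt"
                        )
                    keys.add((parts[0], int(parts[1]), parts[2]))
                else:
                    keys.add((parts[0], int(parts[1])))
    return keys


def classify_novelty(
    site_key: SiteKey,
    catalogs: Iterable[set[tuple]],
    match_mode: Literal["allele", "position"] = "allele",
) -> str:
    """'novel' iff the key is absent from every catalog, else 'known'."""
    probe = site_key if match_mode == "allele" else site_key[:2]
    for cat in catalogs:
        if probe in cat:
            return "known"
    return "novel"


def is_transversion(ref_base: str, alt_base: str) -> bool:
    """True for purine↔pyrimidine changes; False for A↔G and C↔T transitions."""
    for b in (ref_base, alt_base):
        if b not in _BASES:
            raise ValueError(f"not an ACGT base: {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt are identical; not a substitution")
    return (ref_base, alt_base) not in TRANSITIONS


def sample_snp_sets(sites: Iterable[SiteRecord], panel: CohortPanel) -> dict[str, SampleSnpSet]:
    """Build per-sample SNP sets over (chrom, pos, alt) keys.

    A sample contributes a key wherever it carries ≥1 copy of that ALT;
    missing genotype calls contribute nothing.
    """
    sets = {s: SampleSnpSet(s) for s in panel.samples}
    for site in sites:
        if not site.is_snp():
            continue
        for sample, gt in zip(panel.samples, site.genotypes):
            for idx in gt:
                if idx is not None and idx >= 1:
                    sets[sample].keys.add((site.chrom, site.pos, site.alts[idx - 1]))
    return sets


# ---------------------------------------------------------------------------
# tabular output

_GT_SEP = "/"


def _format_gt(gt: Genotype) -> str:
    return _GT_SEP.join("." if a is None else str(a) for a in gt)


def _parse_gt(text: str) -> Genotype:
    a, b = text.split(_GT_SEP)
    return (None if a == "." else int(a), None if b == "." else int(b))


def write_site_table(sites: Sequence[SiteRecord], panel: CohortPanel, path: str | Path) -> None:
    """Write sites as a TSV with one genotype column per sample."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talts\tfilter_pass\t" + "\t".join(panel.samples) + "\n")
        for s in sites:
            gts = "\t".join(_format_gt(g) for g in s.genotypes)
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\t"
                f"{int(s.filter_pass)}\t{gts}\n"
            )


def read_site_table(path: str | Path) -> tuple[list[SiteRecord], tuple[str, ...]]:
    """Read back a site table written by :func:`write_site_table`."""
    sites: list[SiteRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = tuple(header[5:])
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sites.append(
                SiteRecord(
                    chrom=parts[0],
                    pos=int(parts[1]),
                    ref=parts[2],
                    alts=tuple(parts[3].split(",")) if parts[3] else (),
                    genotypes=tuple(_parse_gt(g) for g in parts[5:]),
                    filter_pass=bool(int(parts[4])),
                )
            )
    return sites, samples


def write_json_summary(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
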
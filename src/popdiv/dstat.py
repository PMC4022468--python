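"""ABBA/BABA D-statistic with a 5 Mb block jackknife.

Four genomes per comparison: two modern genomes G1 and G2, an archaic
genome, and an outgroup (chimpanzee) whose allele defines the ancestral
state A; the derived state is B.  Counting is restricted to bi-allelic
transversion substitutions because post-mortem cytosine deamination in
ancient DNA inflates apparent transitions.

    D = (N_BABA - N_ABBA) / (N_BABA + N_ABBA)

BABA sites (G1 = archaic = B, G2 = outgroup = A) mark excess allele sharing
between G1 and the archaic lineage; ABBA sites the reverse.  The standard
error comes from a delete-one jackknife over non-overlapping genomic blocks
(default 5 Mb), which preserves local LD structure; Z = D / SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pysam

from .variant_io import is_transversion

DEFAULT_BLOCK_SIZE = 5_000_000

AllelePolicy = Literal["random_draw", "homozygous_only", "major_allele"]


@dataclass(frozen=True)
class FourGenomeSite:
    chrom: str
    pos: int
    g1: Optional[str]
    g2: Optional[str]
    archaic: Optional[str]
    outgroup: Optional[str]


@dataclass
class PatternCounts:
    block_id: tuple[str, int]
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_baba: int = 0
    n_abba: int = 0


@dataclass(frozen=True)
class DStatResult:
    g1_id: str
    g2_id: str
    archaic_id: str
    n_baba: int
    n_abba: int
    dstat: float  # signed fraction in [-1, 1]
    se: float
    z: float  # NaN when se == 0
    m_blocks: int
    degenerate_variance: bool = False

    @property
    def pct_dstat(self) -> float:
        return 100.0 * self.dstat

    @property
    def pct_se(self) -> float:
        return 100.0 * self.se


def resolve_allele(
    genotype: tuple[Optional[str], Optional[str]],
    policy: AllelePolicy = "random_draw",
    rng: Optional[np.random.Generator] = None,
) -> Optional[str]:
    """Collapse a diploid genotype (pair of bases) to one base, or None.

    random_draw picks one of the two alleles uniformly (requires ``rng``);
    homozygous_only returns None at heterozygous sites; major_allele breaks
    ties to the alphabetically first base.
    """
    a, b = genotype
    if a is None or b is None:
        return None
    if a == b:
        return a
    if policy == "random_draw":
        if rng is None:
            raise ValueError("random_draw policy requires an rng")
        return a if rng.integers(2) == 0 else b
    if policy == "homozygous_only":
        return None
    if policy == "major_allele":
        return min(a, b)
    raise ValueError(f"unknown allele-resolution policy {policy!r}")


def classify_pattern(site: FourGenomeSite) -> str:
    """Classify one four-genome site as 'BABA', 'ABBA' or 'other'.

    Informative sites must have all four alleles called, exactly two
    distinct alleles, a transversion substitution between them, and the
    archaic allele different from the outgroup allele.
    """
    alleles = (site.g1, site.g2, site.archaic, site.outgroup)
    if any(a is None for a in alleles):
        return "other"
    distinct = set(alleles)
    if len(distinct) != 2:
        return "other"
    x, y = distinct
    if not is_transversion(x, y):
        return "other"
    if site.archaic == site.outgroup:
        return "other"
    # state A is the outgroup allele; B the other one
    a_state = site.outgroup
    if site.g1 != a_state and site.g2 == a_state:  # G1=archaic=B, G2=outgroup=A
        return "BABA"
    if site.g2 != a_state and site.g1 == a_state:  # G2=archaic=B, G1=outgroup=A
        return "ABBA"
    return "other"


def dstatistic(n_baba: int, n_abba: int) -> float:
    """Point estimate (N_BABA − N_ABBA) / (N_BABA + N_ABBA), a fraction in [−1, 1]."""
    if n_baba < 0 or n_abba < 0:
        raise ValueError("pattern counts must be non-negative")
    total = n_baba + n_abba
    if total == 0:
        raise ZeroDivisionError("no informative (BABA/ABBA) sites; D undefined")
    return (n_baba - n_abba) / total


def block_partition(
    sites: Sequence[tuple[str, int, str]],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[PatternCounts]:
    """Tally classified sites into non-overlapping fixed windows.

    ``sites`` is a (chrom, pos, pattern) sequence sorted by (chrom, pos);
    pattern is 'BABA', 'ABBA' or 'other'.  Windows are anchored at
    position 1 on every chromosome; empty blocks are dropped.
    """
    if block_size < 1:
        raise ValueError("block_size must be positive")
    order = [(c, p) for c, p, _ in sites]
    if order != sorted(order):
        raise ValueError("sites must be sorted by (chrom, pos)")
    blocks: dict[tuple[str, int], PatternCounts] = {}
    for chrom, pos, pattern in sites:
        if pattern not in ("BABA", "ABBA"):
            continue
        idx = (pos - 1) // block_size
        key = (chrom, idx)
        blk = blocks.get(key)
        if blk is None:
            blk = PatternCounts(
                block_id=key,
                chrom=chrom,
                start=idx * block_size + 1,
                end=(idx + 1) * block_size,
            )
            blocks[key] = blk
        if pattern == "BABA":
            blk.n_baba += 1
        else:
            blk.n_abba += 1
    return [blocks[k] for k in sorted(blocks)]


def jackknife(
    blocks: Sequence[PatternCounts],
    g1_id: str = "G1",
    g2_id: str = "G2",
    archaic_id: str = "archaic",
    weighted: bool = False,
) -> DStatResult:
    """Delete-one block jackknife for the D-statistic.

    The default is the equal-weight delete-one estimator

        SE^2 = (M-1)/M * sum_j (D_(-j) - mean_j D_(-j))^2

    over the M blocks with at least one informative site.  With
    ``weighted=True`` the Busing-style weighted block jackknife is used
    instead, weighting each block by its informative-site count.
    """
    baba = np.array([b.n_baba for b in blocks], dtype=float)
    abba = np.array([b.n_abba for b in blocks], dtype=float)
    informative = (baba + abba) > 0
    baba, abba = baba[informative], abba[informative]
    m = baba.size
    if m < 2:
        raise ValueError(f"need ≥2 non-empty blocks for the jackknife, got {m}")
    tb, ta = baba.sum(), abba.sum()
    d = dstatistic(int(tb), int(ta))

    # delete-one estimates
    loo_b = tb - baba
    loo_a = ta - abba
    if np.any(loo_b + loo_a == 0):
        raise ValueError("a delete-one replicate has no informative sites")
    d_loo = (loo_b - loo_a) / (loo_b + loo_a)

    if not weighted:
        var = (m - 1) / m * float(np.sum((d_loo - d_loo.mean()) ** 2))
    else:
        n = tb + ta
        mj = baba + abba
        hj = n / mj
        d_j = m * d - float(np.sum((1 - mj / n) * d_loo))
        tau = hj * d - (hj - 1) * d_loo
        var = float(np.sum((tau - d_j) ** 2 / (hj - 1))) / m

    se = math.sqrt(var)
    degenerate = se == 0.0
    z = d / se if se > 0 else float("nan")
    return DStatResult(
        g1_id=g1_id,
        g2_id=g2_id,
        archaic_id=archaic_id,
        n_baba=int(tb),
        n_abba=int(ta),
        dstat=d,
        se=se,
        z=z,
        m_blocks=m,
        degenerate_variance=degenerate,
    )


def dstat_from_sites(
    sites: Iterable[FourGenomeSite],
    block_size: int = DEFAULT_BLOCK_SIZE,
    g1_id: str = "G1",
    g2_id: str = "G2",
    archaic_id: str = "archaic",
    weighted: bool = False,
) -> DStatResult:
    """Classify, block-partition and jackknife a four-genome site stream."""
    classified = sorted(
        ((s.chrom, s.pos, classify_pattern(s)) for s in sites),
        key=lambda t: (t[0], t[1]),
    )
    blocks = block_partition(classified, block_size=block_size)
    return jackknife(blocks, g1_id, g2_id, archaic_id, weighted=weighted)


def jackknife_from_arrays(
    block_ids: np.ndarray,
    patterns: np.ndarray,
    n_blocks: int,
    **kwargs,
) -> DStatResult:
    """Jackknife from integer block ids and pattern codes (1=BABA, 2=ABBA, 0=other).

    Vectorized tally for large simulated site sets; equivalent to
    block_partition + jackknife on the rendered site table.
    """
    baba = np.bincount(block_ids[patterns == 1], minlength=n_blocks)
    abba = np.bincount(block_ids[patterns == 2], minlength=n_blocks)
    blocks = [
        PatternCounts(("sim", i), "sim", i * DEFAULT_BLOCK_SIZE + 1,
                      (i + 1) * DEFAULT_BLOCK_SIZE, int(b), int(a))
        for i, (b, a) in enumerate(zip(baba, abba))
    ]
    return jackknife(blocks, **kwargs)


# ---------------------------------------------------------------------------
# input routes

def read_site_table(path: str | Path) -> list[FourGenomeSite]:
    """Read a pre-joined four-genome table: chrom, pos, g1, g2, archaic, outgroup.

    '.' or empty fields are missing alleles.
    """
    out: list[FourGenomeSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, g1, g2, arch, outg = line.split("\t")[:6]
            clean = lambda x: None if x in (".", "") else x
            out.append(
                FourGenomeSite(chrom, int(pos), clean(g1), clean(g2), clean(arch), clean(outg))
            )
    return out


def load_allele_track(
    vcf_path: str | Path,
    policy: AllelePolicy = "random_draw",
    seed: int = 0,
    pass_only: bool = True,
) -> dict[tuple[str, int], str]:
    """Resolve a single-sample VCF into a (chrom, pos) → base allele track.

    Only bi-allelic SNP records are used.  Positions absent from the VCF are
    taken to be homozygous reference by the caller's join logic, so the
    track stores only positions where the genotype was observed; REF calls
    at emitted records resolve normally.
    """
    rng = np.random.default_rng(seed)
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    if len(samples) != 1:
        raise ValueError(f"{vcf_path}: expected a single-sample VCF, got {len(samples)}")
    track: dict[tuple[str, int], str] = {}
    for rec in vcf:
        if pass_only and list(rec.filter.keys()) not in ([], ["PASS"]):
            continue
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        gt = rec.samples[samples[0]].get("GT", (None, None))
        if gt is None or any(i is None for i in gt):
            continue
        alleles = (rec.alleles[gt[0]], rec.alleles[gt[1]])
        base = resolve_allele(alleles, policy=policy, rng=rng)
        if base is not None:
            track[(rec.chrom, rec.pos)] = base
    return track


def read_outgroup_track(path: str | Path) -> dict[tuple[str, int], str]:
    """Read an outgroup allele TSV: chrom, pos, base."""
    track: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, base = line.split("\t")[:3]
            track[(chrom, int(pos))] = base
    return track


def join_tracks(
    g1: dict[tuple[str, int], str],
    g2: dict[tuple[str, int], str],
    archaic: dict[tuple[str, int], str],
    outgroup: dict[tuple[str, int], str],
) -> list[FourGenomeSite]:
    """Intersect four allele tracks into a sorted four-genome site list."""
    common = sorted(set(g1) & set(g2) & set(archaic) & set(outgroup))
    return [
        FourGenomeSite(c, p, g1[(c, p)], g2[(c, p)], archaic[(c, p)], outgroup[(c, p)])
        for c, p in common
    ]
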
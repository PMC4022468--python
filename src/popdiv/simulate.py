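"""Seeded generators for every input the pipeline consumes.

Three generators, all pure functions of their config (seed included):

* ``simulate_cohort`` — a multi-population diploid genotype cohort under the
  Balding–Nichols model: per site an ancestral frequency p is drawn
  uniformly, each population's frequency q comes from a Beta distribution
  with mean p and variance F·p(1−p), and genotypes are Binomial(2, q) under
  Hardy–Weinberg.  F is the per-population differentiation parameter;
  expected within-population heterozygosity is 2p(1−p)(1−F), so larger F
  means a more drifted, less diverse population.  Defaults emulate a
  three-continent contrast (African-like F=0.01, European-like F=0.05,
  East-Asian-like F=0.15) with 36 samples per population, the cohort size
  used for size-normalized comparisons.

* ``simulate_dstat_patterns`` / ``simulate_dstat_sites`` — four-genome sites
  that are BABA with probability p_baba, ABBA with p_abba, otherwise
  non-informative, assigned uniformly to contiguous 5 Mb blocks; every
  emitted substitution is a transversion.  Expected
  D = (p_baba − p_abba)/(p_baba + p_abba).

* ``simulate_sv_calls`` — non-overlapping true deletions plus per-caller
  call sets with boundary jitter, per-caller detection probability and
  uniformly placed false positives, with the truth table returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dstat import DEFAULT_BLOCK_SIZE, FourGenomeSite
from .sv import DeletionCall

_BASES = np.array(["A", "C", "G", "T"])
# unordered transversion pairs (either member can be the ancestral state)
_TRANSVERSION_PAIRS = [
    ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T"),
]


# ---------------------------------------------------------------------------
# population cohort

@dataclass(frozen=True)
class PopGenConfig:
    n_populations: int = 3
    samples_per_pop: int = 36
    n_sites: int = 5000
    fst_per_pop: tuple[float, ...] = (0.01, 0.05, 0.15)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    pop_labels: tuple[str, ...] | None = None
    continents: tuple[str, ...] | None = None
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fst_per_pop) != self.n_populations:
            raise ValueError("fst_per_pop length must equal n_populations")
        for f in self.fst_per_pop:
            if not 0.0 < f < 1.0:
                raise ValueError(f"Balding–Nichols F must be in (0,1), got {f}")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must sit inside (0,1)")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.pop_labels is not None:
            return self.pop_labels
        return tuple(f"POP{i + 1}" for i in range(self.n_populations))

    @property
    def continent_labels(self) -> tuple[str, ...]:
        if self.continents is not None:
            return self.continents
        return tuple(f"CONT{i + 1}" for i in range(self.n_populations))


def simulate_genotype_matrix(
    config: PopGenConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the cohort in memory.

    Returns (genotypes, pop_freqs, positions, refs, alts): genotypes is an
    (n_samples, n_sites) int array of alt-allele dosages 0/1/2 with samples
    blocked by population; pop_freqs is (n_populations, n_sites).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=config.n_sites)

    freqs = np.empty((config.n_populations, config.n_sites))
    for k, f in enumerate(config.fst_per_pop):
        shape = (1.0 - f) / f
        freqs[k] = rng.beta(p * shape, (1.0 - p) * shape)

    n_samples = config.n_populations * config.samples_per_pop
    geno = np.empty((n_samples, config.n_sites), dtype=np.int8)
    for k in range(config.n_populations):
        rows = slice(k * config.samples_per_pop, (k + 1) * config.samples_per_pop)
        geno[rows] = rng.binomial(2, freqs[k], size=(config.samples_per_pop, config.n_sites))

    positions = 100 * (np.arange(config.n_sites) + 1)
    ref_idx = rng.integers(4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    return geno, freqs, positions, _BASES[ref_idx], _BASES[alt_idx]


_GT_STRINGS = ("0/0", "0/1", "1/1")


def simulate_cohort(
    config: PopGenConfig,
    vcf_path: str | Path,
    popmap_path: str | Path,
) -> None:
    """Write the simulated cohort as a multi-sample VCF and a population map.

    Output is byte-identical for identical configs (seed included).
    """
    geno, _, positions, refs, alts = simulate_genotype_matrix(config)
    sample_ids = [
        f"{label}_{i + 1:03d}"
        for label in config.labels
        for i in range(config.samples_per_pop)
    ]
    contig_len = int(positions[-1]) + 100 if len(positions) else 1000

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.chrom},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(config.n_sites):
            gts = "\t".join(_GT_STRINGS[geno[i, j]] for i in range(len(sample_ids)))
            fh.write(
                f"{config.chrom}\t{positions[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    with open(popmap_path, "w") as fh:
        fh.write("sample_id\tpopulation\tcontinent\n")
        for label, cont in zip(config.labels, config.continent_labels):
            for i in range(config.samples_per_pop):
                fh.write(f"{label}_{i + 1:03d}\t{label}\t{cont}\n")


# ---------------------------------------------------------------------------
# four-genome D-statistic sites

@dataclass(frozen=True)
class DstatSimConfig:
    n_sites: int = 1_000_000
    n_blocks: int = 200
    p_baba: float = 0.0025
    p_abba: float = 0.0025
    block_size: int = DEFAULT_BLOCK_SIZE
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_baba < 0 or self.p_abba < 0:
            raise ValueError("pattern probabilities must be non-negative")
        if self.p_baba + self.p_abba >= 1:
            raise ValueError("p_baba + p_abba must be < 1")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")

    @property
    def expected_d(self) -> float:
        tot = self.p_baba + self.p_abba
        return (self.p_baba - self.p_abba) / tot if tot > 0 else float("nan")


def simulate_dstat_patterns(config: DstatSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pattern layer: (block_ids, patterns) with 1=BABA, 2=ABBA, 0=other.

    Sites are assigned uniformly to blocks; this is the layer the jackknife
    calibration runs on.  ``simulate_dstat_sites`` renders the same draws as
    a concrete allele table.
    """
    rng = np.random.default_rng(config.seed)
    u = rng.random(config.n_sites)
    patterns = np.zeros(config.n_sites, dtype=np.int8)
    patterns[u < config.p_baba] = 1
    patterns[(u >= config.p_baba) & (u < config.p_baba + config.p_abba)] = 2
    block_ids = rng.integers(config.n_blocks, size=config.n_sites)
    return block_ids, patterns


def simulate_dstat_sites(config: DstatSimConfig) -> list[FourGenomeSite]:
    """Render the pattern draws as a sorted four-genome allele table.

    Every informative site is a transversion with the outgroup carrying the
    ancestral state A; non-informative sites have archaic == outgroup so the
    classifier discards them.
    """
    rng = np.random.default_rng(config.seed)
    u = rng.random(config.n_sites)
    patterns = np.zeros(config.n_sites, dtype=np.int8)
    patterns[u < config.p_baba] = 1
    patterns[(u >= config.p_baba) & (u < config.p_baba + config.p_abba)] = 2
    block_ids = rng.integers(config.n_blocks, size=config.n_sites)
    # independent stream for allele rendering keeps the pattern stream
    # identical to simulate_dstat_patterns for the same seed
    rng2 = np.random.default_rng((config.seed, 1))
    offsets = rng2.integers(1, config.block_size + 1, size=config.n_sites)
    pair_idx = rng2.integers(len(_TRANSVERSION_PAIRS), size=config.n_sites)
    flip = rng2.integers(2, size=config.n_sites)

    sites: list[FourGenomeSite] = []
    for i in range(config.n_sites):
        pos = int(block_ids[i]) * config.block_size + int(offsets[i])
        x, y = _TRANSVERSION_PAIRS[pair_idx[i]]
        a_state, b_state = (x, y) if flip[i] == 0 else (y, x)
        if patterns[i] == 1:  # BABA
            g1, g2, arch, outg = b_state, a_state, b_state, a_state
        elif patterns[i] == 2:  # ABBA
            g1, g2, arch, outg = a_state, b_state, b_state, a_state
        else:  # uninformative: archaic matches outgroup
            g1, g2, arch, outg = a_state, a_state, a_state, a_state
        sites.append(FourGenomeSite(config.chrom, pos, g1, g2, arch, outg))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_dstat_site_table(sites: Sequence[FourGenomeSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tg1\tg2\tarchaic\toutgroup\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.g1}\t{s.g2}\t{s.archaic}\t{s.outgroup}\n")


# ---------------------------------------------------------------------------
# multi-caller deletion calls

@dataclass(frozen=True)
class SvSimConfig:
    n_true_deletions: int = 50
    genome_length: int = 10_000_000
    chrom: str = "1"
    min_len: int = 100
    max_len: int = 10_000
    callers: tuple[str, ...] = ("caller1", "caller2", "caller3", "caller4")
    detection_prob: float = 0.8
    boundary_jitter_sd: float = 10.0
    fp_per_caller: int = 5
    fp_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sd < 0:
            raise ValueError("jitter sd must be ≥ 0")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection probability must be in [0,1]")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid deletion length bounds")


def simulate_sv_calls(
    config: SvSimConfig,
) -> tuple[list[DeletionCall], list[tuple[str, int, int]]]:
    """Simulate per-caller deletion call sets plus the ground-truth intervals.

    True deletions are placed without overlap (log-uniform lengths); each
    caller reports each truth independently with ``detection_prob``, its
    boundaries perturbed by rounded zero-mean Gaussian jitter, and adds
    ``fp_per_caller`` uniformly placed false positives.
    """
    rng = np.random.default_rng(config.seed)
    lengths = np.exp(
        rng.uniform(np.log(config.min_len), np.log(config.max_len), config.n_true_deletions)
    ).astype(int)
    lengths = np.clip(lengths, config.min_len, config.max_len)
    if lengths.sum() * 3 > config.genome_length:
        raise ValueError("genome too small to place the requested deletions without overlap")

    truth: list[tuple[str, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for L in lengths:
        for _ in range(1000):
            start = int(rng.integers(1, config.genome_length - L + 1))
            end = start + int(L) - 1
            if all(end < s or start > e for s, e in occupied):
                occupied.append((start, end))
                truth.append((config.chrom, start, end))
                break
        else:
            raise ValueError("could not place a deletion without overlap")
    truth.sort(key=lambda t: t[1])

    calls: list[DeletionCall] = []
    for caller in config.callers:
        for chrom, start, end in truth:
            if rng.random() >= config.detection_prob:
                continue
            if config.boundary_jitter_sd > 0:
                js = int(round(rng.normal(0, config.boundary_jitter_sd)))
                je = int(round(rng.normal(0, config.boundary_jitter_sd)))
            else:
                js = je = 0
            s, e = max(1, start + js), max(1, end + je)
            if s > e:
                s, e = e, s
            calls.append(DeletionCall(chrom, s, e, caller))
        for _ in range(config.fp_per_caller):
            s = int(rng.integers(1, config.genome_length - config.fp_len))
            calls.append(DeletionCall(config.chrom, s, s + config.fp_len - 1, caller))
    return calls, truth


def write_truth_bed(truth: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in truth:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def write_calls_tsv(calls: Sequence[DeletionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcaller\tsample_id\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.caller}\t{c.sample_id}\n")
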
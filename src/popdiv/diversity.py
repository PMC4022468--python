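"""Intra-population diversity via pairwise SNP-set distances.

For two samples with SNP key sets S1 and S2 the distance is

    D = 1 - |S1 ∩ S2| / min(|S1|, |S2|)

scaled to [0, 1].  D = 0 whenever one set is nested in the other; a low D
means the smaller SNP repertoire is largely contained in the other sample's,
i.e. high SNP sharing and genetic homogeneity.  Membership is presence-only
over (chrom, pos, alt) keys; genotype dosage is ignored.

Quartiles for the per-population summaries use the median-unbiased quantile
convention so boxplots are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .variant_io import CohortPanel, SampleSnpSet


@dataclass(frozen=True)
class PairwiseDistance:
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    n_shared: int
    d: float


@dataclass(frozen=True)
class PopulationDistanceSummary:
    population: str
    n_samples: int
    n_pairs: int
    min: float
    q1: float
    median: float
    q3: float
    max: float


def pairwise_d(s1: SampleSnpSet, s2: SampleSnpSet) -> PairwiseDistance:
    """Distance D = 1 − |S1∩S2| / min(|S1|, |S2|) between two SNP sets."""
    n1, n2 = len(s1.keys), len(s2.keys)
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"empty SNP set for {s1.sample_id if n1 == 0 else s2.sample_id}; D undefined"
        )
    shared = len(s1.keys & s2.keys)
    return PairwiseDistance(
        sample_a=s1.sample_id,
        sample_b=s2.sample_id,
        n_a=n1,
        n_b=n2,
        n_shared=shared,
        d=1.0 - shared / min(n1, n2),
    )


def population_pairs(
    panel: CohortPanel,
    snp_sets: Mapping[str, SampleSnpSet],
    population: str,
) -> list[PairwiseDistance]:
    """All unordered within-population pairwise distances."""
    members = panel.samples_in(population)
    if len(members) < 2:
        raise ValueError(f"population {population!r} has {len(members)} sample(s); need ≥2")
    return [pairwise_d(snp_sets[a], snp_sets[b]) for a, b in combinations(members, 2)]


def population_distance_distribution(
    panel: CohortPanel,
    snp_sets: Mapping[str, SampleSnpSet],
    population: str,
) -> PopulationDistanceSummary:
    """Five-number summary of within-population pairwise D (boxplot stats)."""
    pairs = population_pairs(panel, snp_sets, population)
    d = np.array([p.d for p in pairs])
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75], method="median_unbiased")
    n = len(panel.samples_in(population))
    return PopulationDistanceSummary(
        population=population,
        n_samples=n,
        n_pairs=len(pairs),
        min=float(d.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(d.max()),
    )


def pairs_frame(pairs: list[PairwiseDistance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": p.sample_a,
                "sample_b": p.sample_b,
                "n_a": p.n_a,
                "n_b": p.n_b,
                "n_shared": p.n_shared,
                "d": p.d,
            }
            for p in pairs
        ]
    )


def subsample_normalize(panel: CohortPanel, n: int = 36, seed: int = 0) -> CohortPanel:
    """Reduce every population to exactly ``n`` randomly chosen samples.

    Populations with fewer than ``n`` samples are dropped with a warning,
    so size-confounded comparisons across populations are avoided.  The
    selection is deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError(f"subsample size {n} < 2")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for pop in panel.populations:
        members = panel.samples_in(pop)
        if len(members) < n:
            warnings.warn(
                f"population {pop!r} has {len(members)} samples (< {n}); dropped",
                stacklevel=2,
            )
            continue
        chosen = rng.choice(len(members), size=n, replace=False)
        keep.extend(members[i] for i in sorted(chosen))
    return panel.restrict(keep)
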
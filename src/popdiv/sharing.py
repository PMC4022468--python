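"""Inter-population SNP sharing: private, uniquely-shared and continental counts.

A population is "present" at a SNP key iff at least one of its samples
carries at least one copy of that ALT — presence, not frequency.  The
sharing matrix counts keys private to one population (diagonal) and keys
present in exactly two populations (off-diagonal); keys segregating in
three or more populations are tallied separately, so

    sum(matrix) + n_multi == number of segregating SNP keys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .variant_io import CohortPanel, SiteKey, SiteRecord


@dataclass(frozen=True)
class PresenceProfile:
    site_key: SiteKey
    populations_present: frozenset[str]


def presence_profiles(
    sites: Iterable[SiteRecord], panel: CohortPanel
) -> list[PresenceProfile]:
    """Population presence set for every segregating SNP key.

    Monomorphic-reference keys (no carrier anywhere) yield no profile.
    """
    profiles: list[PresenceProfile] = []
    for site in sites:
        if not site.is_snp():
            continue
        present: dict[str, set[str]] = {}
        for sample, gt in zip(panel.samples, site.genotypes):
            pop = panel.population_of[sample]
            for idx in gt:
                if idx is not None and idx >= 1:
                    present.setdefault(site.alts[idx - 1], set()).add(pop)
        for alt, pops in present.items():
            profiles.append(
                PresenceProfile((site.chrom, site.pos, alt), frozenset(pops))
            )
    return profiles


@dataclass(frozen=True)
class SharingMatrix:
    populations: tuple[str, ...]
    counts: pd.DataFrame  # square, index == columns == populations
    n_multi: int  # keys present in ≥3 populations

    @property
    def total_segregating(self) -> int:
        """Unique keys accounted for: diagonal + upper triangle + multi-population.

        Off-diagonal cells are stored symmetrically, so each exactly-two
        key appears in two cells; the unique count halves that.
        """
        arr = self.counts.to_numpy()
        diag = int(arr.trace())
        off = int(arr.sum()) - diag
        assert off % 2 == 0
        return diag + off // 2 + self.n_multi


def unique_sharing_matrix(
    profiles: Iterable[PresenceProfile], panel: CohortPanel
) -> SharingMatrix:
    """Counts of private (diagonal) and exactly-two-population keys."""
    pops = panel.populations
    counts = pd.DataFrame(0, index=list(pops), columns=list(pops), dtype=int)
    n_multi = 0
    for prof in profiles:
        pp = prof.populations_present
        if len(pp) == 1:
            (p,) = pp
            counts.loc[p, p] += 1
        elif len(pp) == 2:
            a, b = sorted(pp)
            counts.loc[a, b] += 1
            counts.loc[b, a] += 1
        else:
            n_multi += 1
    return SharingMatrix(pops, counts, n_multi)


def continental_sharing(
    profiles: Iterable[PresenceProfile], panel: CohortPanel
) -> pd.DataFrame:
    """Exactly-two-population sharing binned by the partner's continent.

    Row = reference population, column = continent of the single partner
    population; entry (p, c) counts keys shared exactly between p and one
    population on continent c.  Row sums equal the off-diagonal row sums
    of the sharing matrix.
    """
    pops = panel.populations
    continents = sorted(set(panel.continent_of.values()))
    table = pd.DataFrame(0, index=list(pops), columns=continents, dtype=int)
    for prof in profiles:
        pp = prof.populations_present
        if len(pp) != 2:
            continue
        a, b = pp
        table.loc[a, panel.continent_of[b]] += 1
        table.loc[b, panel.continent_of[a]] += 1
    return table
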
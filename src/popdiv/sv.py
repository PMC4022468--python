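"""Structural-deletion consolidation across callers and novelty classification.

Deletion calls from multiple callers are consolidated per sample and
chromosome: calls overlapping by at least one base are chained transitively
into a single consensus whose span is the union (min start, max end) and
whose evidence is the set of supporting callers.  A size window of
50 bp – 10 Mb (inclusive) is applied to calls before merging.  A consensus
is novel iff strictly less than half of its length is covered by the union
of catalogued deletions; the denominator is the query length (one-sided),
with a reciprocal mode available.

Intervals are 1-based inclusive internally; BED input (0-based half-open)
is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    caller: str
    sample_id: str = "cohort"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConsensusDeletion:
    chrom: str
    start: int
    end: int
    supporting_callers: set[str] = field(default_factory=set)
    sample_id: str = "cohort"
    n_calls: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_callers(self) -> int:
        return len(self.supporting_callers)


def size_filter(
    calls: Iterable[DeletionCall],
    min_len: int = 50,
    max_len: int = 10_000_000,
) -> list[DeletionCall]:
    """Keep calls with min_len ≤ length ≤ max_len (both bounds inclusive)."""
    return [c for c in calls if min_len <= c.length <= max_len]


def merge_union(calls: Iterable[DeletionCall]) -> list[ConsensusDeletion]:
    """Chain overlapping calls (per sample and chromosome) into union spans.

    Overlap of ≥1 bp chains transitively: A–B overlapping and B–C
    overlapping puts A, B, C in one consensus even if A and C are disjoint.
    Abutting-but-disjoint calls (end + 1 == next start) are NOT merged.
    """
    by_group: dict[tuple[str, str], list[DeletionCall]] = {}
    for c in calls:
        by_group.setdefault((c.sample_id, c.chrom), []).append(c)

    out: list[ConsensusDeletion] = []
    for (sample, chrom), group in sorted(by_group.items()):
        group.sort(key=lambda c: (c.start, c.end))
        current: ConsensusDeletion | None = None
        for c in group:
            if current is not None and c.start <= current.end:
                current.end = max(current.end, c.end)
                current.supporting_callers.add(c.caller)
                current.n_calls += 1
            else:
                if current is not None:
                    out.append(current)
                current = ConsensusDeletion(
                    chrom=chrom,
                    start=c.start,
                    end=c.end,
                    supporting_callers={c.caller},
                    sample_id=sample,
                    n_calls=1,
                )
        if current is not None:
            out.append(current)
    return out


def _union_coverage(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as disjoint sorted intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_fraction(
    query: tuple[str, int, int],
    catalog: Iterable[tuple[str, int, int]],
) -> float:
    """Fraction of the query interval covered by the union of catalog intervals.

    Splitting a catalog interval into abutting pieces does not change the
    result: coverage is computed on the union, never double-counted.
    """
    chrom, qs, qe = query
    if qs > qe:
        raise ValueError(f"invalid query interval {chrom}:{qs}-{qe}")
    same_chrom = [(s, e) for c, s, e in catalog if c == chrom]
    covered = 0
    for s, e in _union_coverage(same_chrom):
        lo, hi = max(s, qs), min(e, qe)
        if lo <= hi:
            covered += hi - lo + 1
    return covered / (qe - qs + 1)


def classify_sv_novelty(
    consensus: ConsensusDeletion,
    catalog: Iterable[tuple[str, int, int]],
    threshold: float = 0.5,
    reciprocal: bool = False,
) -> str:
    """'novel' iff overlap with known deletions is strictly below threshold.

    Default is one-sided (query-length denominator).  With
    ``reciprocal=True`` a consensus is known only if some single catalog
    interval covers ≥ threshold of BOTH the query and itself.
    """
    query = (consensus.chrom, consensus.start, consensus.end)
    if not reciprocal:
        frac = overlap_fraction(query, catalog)
        return "novel" if frac < threshold else "known"
    qlen = consensus.length
    for c, s, e in catalog:
        if c != consensus.chrom:
            continue
        lo, hi = max(s, consensus.start), min(e, consensus.end)
        if lo > hi:
            continue
        ov = hi - lo + 1
        if ov / qlen >= threshold and ov / (e - s + 1) >= threshold:
            return "known"
    return "novel"


# ---------------------------------------------------------------------------
# I/O

def read_calls_bed(path: str | Path, caller: str, sample_id: str = "cohort") -> list[DeletionCall]:
    """Read deletion calls from BED (0-based half-open → 1-based inclusive)."""
    calls: list[DeletionCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            calls.append(DeletionCall(parts[0], int(parts[1]) + 1, int(parts[2]), caller, sample_id))
    return calls


def read_calls_tsv(path: str | Path) -> list[DeletionCall]:
    """Read calls from TSV with header: chrom, start, end, caller[, sample_id] (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "caller"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    has_sample = "sample_id" in df.columns
    return [
        DeletionCall(
            str(r.chrom), int(r.start), int(r.end), str(r.caller),
            str(r.sample_id) if has_sample else "cohort",
        )
        for r in df.itertuples()
    ]


def read_catalog_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def consensus_frame(
    consensuses: Sequence[ConsensusDeletion],
    novelty: Sequence[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(consensuses):
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "sample_id": c.sample_id,
                "n_callers": c.n_callers,
                "callers": ",".join(sorted(c.supporting_callers)),
                **({"novelty": novelty[i]} if novelty is not None else {}),
            }
        )
    return pd.DataFrame(rows)


def write_consensus_bed(consensuses: Sequence[ConsensusDeletion], path: str | Path) -> None:
    """Write consensus deletions as BED (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for c in consensuses:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{','.join(sorted(c.supporting_callers))}\n")
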
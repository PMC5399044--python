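"""Genomic interval algebra for targeted bisulfite sequencing.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  The 1-based Bismark coverage dialect is translated at the
file boundary (see :mod:`dmrcall.io`), never here.

Capture probes define the observable portion of the genome.  Following
the study design of targeted enrichment, probe intervals are extended a
fixed number of bases on either side and nearby extended regions are
merged into *clusters*; differentially methylated regions are searched
only within clusters, so runs of CpGs never bridge a capture gap.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


class IntervalError(ValueError):
    """Raised for invalid genomic intervals or interval parameters."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(
                f"interval start must be >= 0, got {self.start}"
            )
        if self.start >= self.end:
            raise IntervalError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def contains(self, pos: int) -> bool:
        """Membership of a single base under the half-open convention."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Cluster:
    """A merged, extended capture-probe region bounding DMR search.

    Clusters on one chromosome are pairwise disjoint and sorted;
    ``cluster_id`` is stable across runs (assigned in (chrom, start)
    order) and ``source_probe_count`` records how many probes merged
    into this cluster.
    """

    interval: GenomicInterval
    cluster_id: int
    source_probe_count: int

    def __post_init__(self) -> None:
        if self.source_probe_count < 1:
            raise IntervalError("a cluster must derive from at least one probe")


@dataclass(frozen=True)
class GeneModel:
    """One gene, reduced to its transcription start site and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise IntervalError(f"TSS must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise IntervalError(
                f"strand must be '+' or '-', got {self.strand!r}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _merge_triples(
    triples: list[tuple[str, int, int, int]], merge_gap_lt: int
) -> list[tuple[str, int, int, int]]:
    """Merge sorted (chrom, start, end, n_probes) when gap < merge_gap_lt."""
    merged: list[tuple[str, int, int, int]] = []
    for chrom, start, end, n in triples:
        if merged and chrom == merged[-1][0] and start - merged[-1][2] < merge_gap_lt:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] + n)
        else:
            merged.append((chrom, start, end, n))
    return merged


def extend_and_merge(
    probes: Iterable[GenomicInterval],
    extend_bp: int = 100,
    merge_gap_lt: int = 300,
    merge_before_extension: bool = False,
) -> list[Cluster]:
    """Build CpG clusters from capture-probe intervals.

    Each probe is extended ``extend_bp`` bases on either side (clipped
    at coordinate 0), then regions separated by a gap strictly smaller
    than ``merge_gap_lt`` bases are merged into single clusters.  The
    gap between consecutive half-open intervals is ``next.start -
    prev.end``; overlapping or adjacent extended probes (gap <= 0)
    always merge.

    With ``merge_before_extension=True`` the gap criterion is applied to
    the raw probe coordinates instead; the merged regions are then
    extended, and regions the extension causes to overlap are unioned.

    Returns clusters sorted by (chrom, start), pairwise disjoint per
    chromosome, with stable sequential ids.
    """
    if extend_bp < 0:
        raise IntervalError(f"extend_bp must be >= 0, got {extend_bp}")
    if merge_gap_lt < 0:
        raise IntervalError(f"merge_gap_lt must be >= 0, got {merge_gap_lt}")

    if merge_before_extension:
        raw = sorted((p.chrom, p.start, p.end, 1) for p in probes)
        merged = _merge_triples(raw, merge_gap_lt)
        extended = [
            (c, max(0, s - extend_bp), e + extend_bp, n) for c, s, e, n in merged
        ]
        merged = _merge_triples(extended, 1)  # union overlaps/adjacency only
    else:
        extended = sorted(
            (p.chrom, max(0, p.start - extend_bp), p.end + extend_bp, 1)
            for p in probes
        )
        merged = _merge_triples(extended, merge_gap_lt)
    return [
        Cluster(GenomicInterval(c, s, e), i, n)
        for i, (c, s, e, n) in enumerate(merged)
    ]


def promoter_window(
    gene: GeneModel, upstream_bp: int = 1500, downstream_bp: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around a gene's TSS.

    "Upstream" and "downstream" are taken in the direction of
    transcription: on the plus strand the window is
    ``[tss - upstream_bp, tss + downstream_bp)``; on the minus strand it
    is reflected about the TSS.  The window is clipped at coordinate 0.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise IntervalError("window extents must be >= 0")
    if upstream_bp + downstream_bp == 0:
        raise IntervalError("promoter window must have positive width")
    if gene.strand == "+":
        start, end = gene.tss - upstream_bp, gene.tss + downstream_bp
    else:
        start, end = gene.tss - downstream_bp, gene.tss + upstream_bp
    return GenomicInterval(gene.chrom, max(0, start), end)


def assign_to_clusters(
    positions: Mapping[str, Sequence[int]], clusters: Sequence[Cluster]
) -> dict[tuple[str, int], int | None]:
    """Map each CpG position to the id of the cluster containing it.

    ``positions`` maps chromosome -> sorted positions.  Positions
    outside every cluster map to ``None`` (they are excluded from DMR
    search but still count toward genome-wide summaries).  A position
    equal to a cluster's ``end`` is outside it (half-open).
    """
    by_chrom: dict[str, list[Cluster]] = {}
    for cl in clusters:
        by_chrom.setdefault(cl.interval.chrom, []).append(cl)
    starts: dict[str, list[int]] = {}
    for chrom, cls in by_chrom.items():
        cls.sort(key=lambda c: c.interval.start)
        starts[chrom] = [c.interval.start for c in cls]

    out: dict[tuple[str, int], int | None] = {}
    for chrom, pos_list in positions.items():
        if any(b < a for a, b in zip(pos_list, pos_list[1:])):
            raise IntervalError(f"positions on {chrom} are not sorted")
        chrom_clusters = by_chrom.get(chrom, [])
        chrom_starts = starts.get(chrom, [])
        for pos in pos_list:
            i = bisect_right(chrom_starts, pos) - 1
            if i >= 0 and chrom_clusters[i].interval.contains(pos):
                out[(chrom, pos)] = chrom_clusters[i].cluster_id
            else:
                out[(chrom, pos)] = None
    return out
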
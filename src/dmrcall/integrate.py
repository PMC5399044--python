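"""Promoter-DMR / differential-expression integration.

Differentially expressed genes (DEGs) are classified by the sign of
their log2 fold change at an FDR threshold (q < 0.05, strict; no
magnitude cutoff beyond sign — significance plus direction is the
operative rule).  Significant DEGs are then intersected with DMRs
falling in the gene's strand-aware promoter window (1,500 bp upstream
to 500 bp downstream of the TSS), yielding one record per (gene, DMR)
pair with the 2x2 direction pattern (up/down x hyper/hypo), plus a
deduplicated gene-level overlap count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .dmr import DMR
from .intervals import GeneModel, promoter_window, overlaps, GenomicInterval
from .io import DEGRecord


class IntegrationError(ValueError):
    pass


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    status: str  # "up", "down", "not_significant"
    log2fc: float
    q: float


@dataclass(frozen=True)
class OverlapRecord:
    """A significant DEG whose promoter window overlaps a DMR."""

    gene_id: str
    deg_status: str
    dmr_direction: str
    pattern: str  # e.g. "down/hyper"
    dmr: DMR
    log2fc: float
    q: float


def classify_degs(
    records: Sequence[DEGRecord], q_threshold: float = 0.05
) -> list[DegCall]:
    """Classify expression records as up / down / not significant.

    Significance requires q strictly below the threshold; direction is
    the sign of log2fc.  A significant record with log2fc exactly 0 has
    no direction and stays not_significant.
    """
    calls = []
    for r in records:
        if r.q < q_threshold and r.log2fc > 0:
            status = "up"
        elif r.q < q_threshold and r.log2fc < 0:
            status = "down"
        else:
            status = "not_significant"
        calls.append(DegCall(r.gene_id, status, r.log2fc, r.q))
    return calls


def deg_fraction_summary(n_input: int, n_up: int, n_down: int) -> dict:
    """Up/down/total DEG percentages of the input gene count, 1 decimal."""
    if n_input <= 0:
        raise IntegrationError("n_input must be positive")
    if n_up + n_down > n_input:
        raise IntegrationError("more DEGs than input genes")
    return {
        "pct_up": round(100.0 * n_up / n_input, 1),
        "pct_down": round(100.0 * n_down / n_input, 1),
        "pct_total": round(100.0 * (n_up + n_down) / n_input, 1),
    }


def percentage(part: int, whole: int) -> float:
    """100 * part / whole at one decimal (e.g. the low-expression fraction)."""
    if whole <= 0:
        raise IntegrationError("whole must be positive")
    return round(100.0 * part / whole, 1)


def promoter_dmr_deg_overlap(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    deg_calls: Sequence[DegCall],
    upstream_bp: int = 1500,
    downstream_bp: int = 500,
    require_midpoint: bool = False,
) -> tuple[list[OverlapRecord], int]:
    """Intersect significant DEGs with DMRs in their promoter windows.

    A DMR is "in" a promoter when its span overlaps the window by at
    least one base; with ``require_midpoint=True`` its midpoint must lie
    inside the window instead.  Genes with both a hyper and a hypo
    promoter DMR yield multiple records.  Returns the (gene, DMR) pair
    records sorted by (gene_id, DMR start) plus the gene-level count
    (each gene counted once).
    """
    by_gene: Mapping[str, DegCall] = {c.gene_id: c for c in deg_calls}
    records: list[OverlapRecord] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        call = by_gene.get(gene.gene_id)
        if call is None or call.status not in ("up", "down"):
            continue
        window = promoter_window(gene, upstream_bp, downstream_bp)
        for dmr in sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start)):
            if require_midpoint:
                mid = (dmr.interval.start + dmr.interval.end) // 2
                hit = dmr.interval.chrom == window.chrom and window.contains(mid)
            else:
                hit = overlaps(dmr.interval, window)
            if hit:
                records.append(
                    OverlapRecord(
                        gene_id=gene.gene_id,
                        deg_status=call.status,
                        dmr_direction=dmr.direction,
                        pattern=f"{call.status}/{dmr.direction}",
                        dmr=dmr,
                        log2fc=call.log2fc,
                        q=call.q,
                    )
                )
    n_genes = len({r.gene_id for r in records})
    return records, n_genes


def write_overlap_table(records: Sequence[OverlapRecord], path) -> None:
    """Overlap TSV: one row per (gene, DMR) pair."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#gene_id\tdeg_status\tlog2fc\tq\tdmr_chrom\tdmr_start\tdmr_end"
            "\tdmr_direction\tpattern\n"
        )
        for r in records:
            iv = r.dmr.interval
            fh.write(
                f"{r.gene_id}\t{r.deg_status}\t{r.log2fc:g}\t{r.q:g}\t"
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.dmr_direction}\t{r.pattern}\n"
            )
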
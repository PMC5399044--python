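"""Readers and writers for the pipeline's on-disk formats.

All formats are plain tab-separated UTF-8 text; lines starting with
``#`` are treated as headers/comments everywhere.

* Bismark-style coverage tables — one per sequencing library, columns
  ``chrom, start(1-based), end(=start), methylation %, count_methylated,
  count_unmethylated``.  This dialect is adopted as the on-disk CpG
  format because upstream methylation calls come from Bismark; positions
  are converted to 0-based on read and the methylation-percent column is
  recomputed from counts (never trusted).
* BED — capture probes, CpG islands, DMR output (0-based half-open,
  first three columns required).
* Gene TSV — ``gene_id, chrom, tss, strand`` (TSS 0-based).
* DEG TSV — ``gene_id, log2fc, q`` from a differential-expression run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from .intervals import GeneModel, GenomicInterval

if TYPE_CHECKING:  # pragma: no cover
    from .dmr import DMR


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


@dataclass(frozen=True)
class CpGRecord:
    """One CpG site in one library: 0-based position plus read counts."""

    chrom: str
    pos: int
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 0 or self.meth < 0 or self.unmeth < 0:
            raise ParseError(f"negative position or count in {self!r}")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


@dataclass(frozen=True)
class DEGRecord:
    """A differential-expression call: log2 fold change and q value."""

    gene_id: str
    log2fc: float
    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ParseError(f"q value must lie in [0, 1], got {self.q}")


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_coverage(path: str | Path, library_id: str | None = None) -> list[CpGRecord]:
    """Read a Bismark-style coverage table into sorted CpG records.

    The file's 1-based ``start`` becomes the 0-based ``pos``; the
    methylation-percent column is ignored (recomputed from counts on
    write).  ``library_id`` is accepted for caller bookkeeping only.
    """
    records: list[CpGRecord] = []
    seen: set[tuple[str, int]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
            )
        chrom, start_s, end_s, _pct, meth_s, unmeth_s = fields
        try:
            start, end = int(start_s), int(end_s)
            meth, unmeth = int(meth_s), int(unmeth_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
        if start != end:
            raise ParseError(
                f"{path}:{lineno}: coverage rows must have start == end, "
                f"got {start} != {end}"
            )
        if start < 1:
            raise ParseError(f"{path}:{lineno}: 1-based position must be >= 1")
        if meth < 0 or unmeth < 0:
            raise ParseError(f"{path}:{lineno}: negative count")
        key = (chrom, start - 1)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate CpG at {chrom}:{start}")
        seen.add(key)
        records.append(CpGRecord(chrom, start - 1, meth, unmeth))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_coverage(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write CpG records in the Bismark coverage dialect (1-based).

    Rows with zero coverage are skipped — the methylation percentage is
    undefined there, and absent rows round-trip to coverage 0 on merge.
    """
    rows = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            if r.coverage == 0:
                continue
            pct = 100.0 * r.meth / r.coverage
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{pct:.1f}\t{r.meth}\t{r.unmeth}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read the first three columns of a BED file (0-based half-open)."""
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    out.sort()
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the 4-column gene TSV: gene_id, chrom, tss, strand."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        gene_id, chrom, tss_s, strand = fields
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(GeneModel(gene_id, chrom, int(tss_s), strand))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read the 3-column DEG TSV: gene_id, log2fc, q."""
    records: list[DEGRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        gene_id, fc_s, q_s = fields
        if gene_id == "gene_id":  # un-commented header line
            continue
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            records.append(DEGRecord(gene_id, float(fc_s), float(q_s)))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tlog2fc\tq\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:g}\t{r.q:g}\n")


_DMR_COLUMNS = (
    "chrom",
    "start",
    "end",
    "n_cpgs",
    "direction",
    "mean_delta",
    "area",
    "cluster_id",
)


def write_dmr_table(dmrs: Sequence["DMR"], path: str | Path) -> None:
    """Write DMRs as a BED-like TSV, sorted by (chrom, start).

    ``mean_delta`` is in percentage points with one decimal; coordinates
    are 0-based half-open.  An empty DMR list yields a header-only file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_DMR_COLUMNS) + "\n")
        for d in sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start)):
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.n_cpgs}\t{d.direction}\t{d.mean_delta:.1f}\t"
                f"{d.area:.1f}\t{d.cluster_id}\n"
            )


def read_dmr_table(path: str | Path) -> list["DMR"]:
    """Read a DMR TSV written by :func:`write_dmr_table`.

    Per-CpG positions and deltas are not stored in the table; the
    reconstructed DMRs carry the span, counts and summary statistics
    only, which is what downstream promoter integration needs.
    """
    from .dmr import DMR

    dmrs: list[DMR] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != len(_DMR_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(_DMR_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        chrom, start_s, end_s, n_s, direction, mean_s, area_s, cid_s = fields
        if direction not in ("hyper", "hypo"):
            raise ParseError(f"{path}:{lineno}: bad direction {direction!r}")
        try:
            dmrs.append(
                DMR(
                    interval=GenomicInterval(chrom, int(start_s), int(end_s)),
                    cluster_id=int(cid_s),
                    cpg_positions=(),
                    per_cpg_delta=(),
                    direction=direction,
                    mean_delta=float(mean_s),
                    area=float(area_s),
                    n_cpgs=int(n_s),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return dmrs
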
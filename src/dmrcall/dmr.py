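"""Methylome inference for a pooled two-group targeted-bisulfite design.

The model is deliberately threshold-based rather than test-based.  Each
exposure group is a single pooled DNA library sequenced in two technical
replicates, so there is no within-group biological variance to estimate;
instead, per-CpG methylation levels (beta values) are compared between
groups directly and regions are called where the difference is sustained.

Pipeline order:

1. ``coverage_filter`` — keep CpGs with >= ``min_coverage`` reads in
   *every* library (default 10x, all four libraries).
2. ``compute_delta`` — per CpG, ΔMeth = 100 x (mean beta of the
   high-exposure replicates - mean beta of the low-exposure replicates),
   in percentage points.
3. ``find_dmrs`` — within each capture cluster, maximal runs of
   consecutive retained CpGs whose ΔMeth exceeds the cutoff (default 10
   points, strict) with a single sign; runs with at least ``min_cpgs``
   CpGs (default 4) are emitted as DMRs.  Runs never cross cluster
   boundaries.
4. Genome-wide summaries: hyper/hypo partition, per-library
   full-methylation fraction (beta strictly above 0.80), cumulative
   methylation distributions for replicate concordance, and per-element
   stratification (CpG island / shore / shelf / promoter / gene body).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    Cluster,
    GeneModel,
    GenomicInterval,
    assign_to_clusters,
    promoter_window,
)
from .io import CpGRecord


class MethylomeError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: id, exposure group, replicate index."""

    library_id: str
    group: str  # "high" or "low"
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in ("high", "low"):
            raise MethylomeError(f"group must be 'high' or 'low', got {self.group!r}")


@dataclass(frozen=True)
class DmrConfig:
    """Thresholds of the methylome analysis.

    cutoff: ΔMeth cutoff in percentage points (strict ``>``), default 10.
    min_cpgs: minimum consecutive CpGs per DMR, default 4.
    min_coverage: per-library read-depth floor, default 10.
    full_meth_threshold: beta above which a CpG counts as fully
        methylated (strict ``>``), default 0.80.
    pool_counts: if True, group betas come from summed counts across
        replicates instead of the replicate-averaged betas.
    """

    cutoff: float = 10.0
    min_cpgs: int = 4
    min_coverage: int = 10
    full_meth_threshold: float = 0.80
    pool_counts: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise MethylomeError("cutoff must be > 0")
        if self.min_cpgs < 1:
            raise MethylomeError("min_cpgs must be >= 1")
        if self.min_coverage < 1:
            raise MethylomeError("min_coverage must be >= 1")
        if not 0.0 < self.full_meth_threshold < 1.0:
            raise MethylomeError("full_meth_threshold must lie in (0, 1)")


@dataclass
class MethylationMatrix:
    """Per-CpG methylated/unmethylated counts across libraries.

    Sites are sorted by (chrom, pos).  ``meth`` and ``unmeth`` are
    (n_sites, n_libraries) integer arrays aligned with ``libraries``;
    a site missing from one library's file carries coverage 0 there.
    """

    chrom: np.ndarray
    pos: np.ndarray
    libraries: list[LibraryInfo]
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        n, k = self.meth.shape
        if self.unmeth.shape != (n, k) or len(self.pos) != n or len(self.chrom) != n:
            raise MethylomeError("matrix arrays have inconsistent shapes")
        if k != len(self.libraries):
            raise MethylomeError("library list does not match count columns")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise MethylomeError("sites must be sorted by (chrom, pos)")

    @classmethod
    def from_records(
        cls,
        records_by_library: Mapping[str, Sequence[CpGRecord]],
        groups: Mapping[str, str],
    ) -> "MethylationMatrix":
        """Merge per-library CpG records on the union of sites.

        ``groups`` maps library_id -> "high"/"low".  Replicate indices
        are assigned per group in library-id order.
        """
        lib_ids = list(records_by_library)
        sites = sorted(
            {(r.chrom, r.pos) for recs in records_by_library.values() for r in recs}
        )
        index = {site: i for i, site in enumerate(sites)}
        n, k = len(sites), len(lib_ids)
        meth = np.zeros((n, k), dtype=np.int64)
        unmeth = np.zeros((n, k), dtype=np.int64)
        for j, lib in enumerate(lib_ids):
            for r in records_by_library[lib]:
                i = index[(r.chrom, r.pos)]
                meth[i, j] = r.meth
                unmeth[i, j] = r.unmeth
        rep_counter: dict[str, int] = {"high": 0, "low": 0}
        libraries = []
        for lib in lib_ids:
            group = groups[lib]
            rep_counter[group] += 1
            libraries.append(LibraryInfo(lib, group, rep_counter[group]))
        chrom = np.array([c for c, _ in sites], dtype=object)
        pos = np.array([p for _, p in sites], dtype=np.int64)
        return cls(chrom, pos, libraries, meth, unmeth)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def library_index(self, library_id: str) -> int:
        for j, lib in enumerate(self.libraries):
            if lib.library_id == library_id:
                return j
        raise MethylomeError(f"unknown library {library_id!r}")

    def beta(self) -> np.ndarray:
        """Per-site, per-library methylation fraction; NaN at coverage 0."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)
        return b

    def group_columns(self, group: str) -> list[int]:
        return [j for j, lib in enumerate(self.libraries) if lib.group == group]

    def positions_by_chrom(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c, p in zip(self.chrom, self.pos):
            out.setdefault(str(c), []).append(int(p))
        return out


@dataclass
class DeltaTrack:
    """Per retained CpG: ΔMeth in percentage points (high - low)."""

    chrom: np.ndarray
    pos: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.delta) > 100 + 1e-9):
            raise MethylomeError("|ΔMeth| cannot exceed 100 percentage points")


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region.

    A maximal run of >= ``min_cpgs`` consecutive retained CpGs, all with
    |ΔMeth| strictly above the cutoff and one sign, inside one capture
    cluster.  ``area`` is the sum of |ΔMeth| over the run's CpGs; the
    interval spans the first to last CpG, half-open (end = last + 1).
    """

    interval: GenomicInterval
    cluster_id: int
    cpg_positions: tuple[int, ...]
    per_cpg_delta: tuple[float, ...]
    direction: str  # "hyper" or "hypo"
    mean_delta: float
    area: float
    n_cpgs: int

    def validate(self, config: DmrConfig) -> None:
        """Check every type invariant; raises MethylomeError on violation."""
        if self.direction not in ("hyper", "hypo"):
            raise MethylomeError(f"bad direction {self.direction!r}")
        if self.n_cpgs < config.min_cpgs:
            raise MethylomeError("DMR shorter than min_cpgs")
        if self.cpg_positions:
            if len(self.cpg_positions) != self.n_cpgs:
                raise MethylomeError("n_cpgs does not match positions")
            sign = 1.0 if self.direction == "hyper" else -1.0
            for d in self.per_cpg_delta:
                if sign * d <= config.cutoff:
                    raise MethylomeError("per-CpG ΔMeth does not exceed cutoff")
            span = GenomicInterval(
                self.interval.chrom, self.cpg_positions[0], self.cpg_positions[-1] + 1
            )
            if span != self.interval:
                raise MethylomeError("interval does not span first..last CpG")


def compute_beta(meth: int, unmeth: int) -> float:
    """Methylation level meth / (meth + unmeth); undefined at coverage 0."""
    cov = meth + unmeth
    if cov <= 0:
        raise MethylomeError("beta undefined at zero coverage")
    return meth / cov


def coverage_filter(
    matrix: MethylationMatrix, min_coverage: int = 10
) -> MethylationMatrix:
    """Retain CpGs with >= ``min_coverage`` reads in all libraries."""
    keep = (matrix.coverage >= min_coverage).all(axis=1)
    return MethylationMatrix(
        matrix.chrom[keep],
        matrix.pos[keep],
        list(matrix.libraries),
        matrix.meth[keep],
        matrix.unmeth[keep],
    )


def compute_delta(matrix: MethylationMatrix, pool_counts: bool = False) -> DeltaTrack:
    """ΔMeth per CpG: 100 x (high-group mean beta - low-group mean beta).

    With ``pool_counts=False`` (default) each replicate's beta gets equal
    weight; with True, counts are summed within a group first.  Requires
    a coverage-filtered matrix (every library covered at every site).
    """
    hi = matrix.group_columns("high")
    lo = matrix.group_columns("low")
    if not hi or not lo:
        raise MethylomeError("both exposure groups need at least one library")
    cov = matrix.coverage
    if np.any(cov[:, hi + lo] == 0):
        raise MethylomeError("apply coverage_filter before computing ΔMeth")
    if pool_counts:
        beta_hi = matrix.meth[:, hi].sum(axis=1) / cov[:, hi].sum(axis=1)
        beta_lo = matrix.meth[:, lo].sum(axis=1) / cov[:, lo].sum(axis=1)
    else:
        b = matrix.meth / cov
        beta_hi = b[:, hi].mean(axis=1)
        beta_lo = b[:, lo].mean(axis=1)
    return DeltaTrack(matrix.chrom, matrix.pos, 100.0 * (beta_hi - beta_lo))


def find_dmrs(
    delta: DeltaTrack,
    clusters: Sequence[Cluster],
    config: DmrConfig = DmrConfig(),
) -> list[DMR]:
    """Call DMRs as maximal sign-consistent exceedance runs per cluster.

    Within each cluster, every maximal run of consecutive retained CpGs
    with ΔMeth > cutoff is a hyper candidate and every maximal run with
    ΔMeth < -cutoff a hypo candidate; candidates with at least
    ``min_cpgs`` CpGs are returned, sorted by (chrom, start).
    """
    positions = {}
    for c, p in zip(delta.chrom, delta.pos):
        positions.setdefault(str(c), []).append(int(p))
    cluster_map = assign_to_clusters(positions, clusters)

    # group retained sites per cluster, preserving genomic order
    per_cluster: dict[int, list[tuple[str, int, float]]] = {}
    for c, p, d in zip(delta.chrom, delta.pos, delta.delta):
        cid = cluster_map[(str(c), int(p))]
        if cid is not None:
            per_cluster.setdefault(cid, []).append((str(c), int(p), float(d)))

    dmrs: list[DMR] = []
    for cid in sorted(per_cluster):
        sites = per_cluster[cid]
        i = 0
        n = len(sites)
        while i < n:
            d = sites[i][2]
            if d > config.cutoff:
                sign = 1
            elif d < -config.cutoff:
                sign = -1
            else:
                i += 1
                continue
            j = i
            while j < n and sign * sites[j][2] > config.cutoff:
                j += 1
            if j - i >= config.min_cpgs:
                run = sites[i:j]
                deltas = tuple(d for _, _, d in run)
                positions_run = tuple(p for _, p, _ in run)
                dmrs.append(
                    DMR(
                        interval=GenomicInterval(
                            run[0][0], positions_run[0], positions_run[-1] + 1
                        ),
                        cluster_id=cid,
                        cpg_positions=positions_run,
                        per_cpg_delta=deltas,
                        direction="hyper" if sign > 0 else "hypo",
                        mean_delta=float(np.mean(deltas)),
                        area=float(np.sum(np.abs(deltas))),
                        n_cpgs=len(run),
                    )
                )
            i = j
    dmrs.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return dmrs


def summarize_direction_counts(n_hyper: int, n_hypo: int) -> dict:
    """Hyper/hypo partition with percentages at one decimal."""
    total = n_hyper + n_hypo
    if total == 0:
        return {
            "n_total": 0,
            "n_hyper": 0,
            "n_hypo": 0,
            "pct_hyper": None,
            "pct_hypo": None,
        }
    return {
        "n_total": total,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": round(100.0 * n_hyper / total, 1),
        "pct_hypo": round(100.0 * n_hypo / total, 1),
    }


def summarize_dmrs(dmrs: Sequence[DMR]) -> dict:
    """Count DMRs by direction and report the percentage split."""
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
    return summarize_direction_counts(n_hyper, n_hypo)


def full_methylation_contrast(
    high_pcts: Sequence[float], low_pcts: Sequence[float]
) -> float:
    """Group difference in full-methylation percentage, in points.

    Takes the per-replicate full-methylation percentages of each group
    and returns mean(high) - mean(low), rounded to the nearest point.
    """
    if not high_pcts or not low_pcts:
        raise MethylomeError("both groups need at least one replicate value")
    return round(float(np.mean(high_pcts)) - float(np.mean(low_pcts)))


def full_methylation_fraction(
    matrix: MethylationMatrix, library_id: str, threshold: float = 0.80
) -> float:
    """Percentage of retained CpGs with beta strictly above ``threshold``.

    "Full methylation" is beta > 0.80 by default; a site at exactly the
    threshold does not count.
    """
    if matrix.n_sites == 0:
        raise MethylomeError("no retained sites")
    j = matrix.library_index(library_id)
    cov = matrix.coverage[:, j]
    if np.any(cov == 0):
        raise MethylomeError("library has uncovered sites; filter first")
    beta = matrix.meth[:, j] / cov
    return 100.0 * float(np.count_nonzero(beta > threshold)) / matrix.n_sites


def cumulative_distribution(
    matrix: MethylationMatrix, library_id: str, grid: Sequence[float]
) -> np.ndarray:
    """Proportion of sites with beta <= level, for each grid level.

    Used to compare technical replicates: two replicates of the same
    pooled library should produce near-identical curves.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise MethylomeError("grid must be non-empty")
    if matrix.n_sites == 0:
        raise MethylomeError("no retained sites")
    j = matrix.library_index(library_id)
    beta = matrix.meth[:, j] / matrix.coverage[:, j]
    return np.array(
        [np.count_nonzero(beta <= g) / matrix.n_sites for g in grid_arr]
    )


# -- functional-element stratification ---------------------------------------

ELEMENT_CATEGORIES = ("island", "shore", "shelf", "promoter", "gene_body")


def _element_labels(
    chrom: str,
    pos: int,
    islands: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoters: Mapping[str, GenomicInterval],
    gene_spans: Mapping[str, GenomicInterval],
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> set[str]:
    labels: set[str] = set()
    for isl in islands:
        if isl.chrom != chrom:
            continue
        if isl.contains(pos):
            labels.add("island")
            continue
        dist = isl.start - pos - 1 if pos < isl.start else pos - isl.end
        # dist = bases between the CpG and the island edge, 0 = adjacent
        if dist < shore_bp:
            labels.add("shore")
        elif dist < shelf_bp:
            labels.add("shelf")
    for g in genes:
        if g.chrom != chrom:
            continue
        prom = promoters[g.gene_id]
        if prom.contains(pos):
            labels.add("promoter")
        span = gene_spans.get(g.gene_id)
        if span is not None and span.contains(pos) and not prom.contains(pos):
            labels.add("gene_body")
    return labels


def stratify_by_element(
    matrix: MethylationMatrix,
    islands: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    gene_spans: Mapping[str, GenomicInterval] | None = None,
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> dict[str, dict[str, float]]:
    """Per-element, per-group mean methylation.

    Each CpG is labeled with every category it belongs to (categories
    overlap): CpG island; shore (within ``shore_bp`` of an island edge);
    shelf (``shore_bp``-``shelf_bp`` away); promoter (strand-aware
    -1500/+500 window); gene body (gene span minus its promoter, when
    ``gene_spans`` is given).  Returns
    ``{category: {"high": mean_beta, "low": mean_beta, "n_cpgs": n}}``.
    """
    if not islands and not genes:
        raise MethylomeError("no annotation supplied")
    promoters = {g.gene_id: promoter_window(g) for g in genes}
    gene_spans = gene_spans or {}
    hi = matrix.group_columns("high")
    lo = matrix.group_columns("low")
    cov = matrix.coverage
    with np.errstate(invalid="ignore"):
        b = matrix.meth / cov
    beta_hi = b[:, hi].mean(axis=1)
    beta_lo = b[:, lo].mean(axis=1)

    sums: dict[str, list] = {c: [0.0, 0.0, 0] for c in ELEMENT_CATEGORIES}
    for i in range(matrix.n_sites):
        labels = _element_labels(
            str(matrix.chrom[i]),
            int(matrix.pos[i]),
            islands,
            genes,
            promoters,
            gene_spans,
            shore_bp,
            shelf_bp,
        )
        for lab in labels:
            sums[lab][0] += beta_hi[i]
            sums[lab][1] += beta_lo[i]
            sums[lab][2] += 1
    out: dict[str, dict[str, float]] = {}
    for cat, (s_hi, s_lo, n) in sums.items():
        if n:
            out[cat] = {"high": s_hi / n, "low": s_lo / n, "n_cpgs": n}
    return out
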
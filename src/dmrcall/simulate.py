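"""Synthetic targeted-bisulfite datasets with planted effects.

The generator emulates the statistical structure the analysis assumes:

* a capture design — probes laid along each chromosome, extended and
  merged into clusters exactly as the pipeline does, with CpGs placed
  only inside clusters (targeted enrichment observes nothing else);
* a pooled two-group design — one latent pool methylation profile per
  exposure group; each group is sequenced as two *technical* replicates
  that share the pool exactly, so replicate differences are pure
  resampling noise (no biological replicate variance, mirroring a
  pooled-DNA design);
* bimodal per-CpG methylation — a two-mode Beta mixture; the default
  weights/shapes put the fraction of pool methylation above 0.80 at 40%;
* negative-binomial read depth and binomial methylated counts;
* planted DMRs — runs of consecutive CpGs whose high-group pool is
  shifted by ±effect_delta points and clipped to [0, 1].  Hypermethylated
  regions are planted on low-methylation baseline and hypomethylated
  regions on high-methylation baseline, so the stated effect size is
  realizable without truncation (regulatory-element DMRs flip state);
* planted promoter/expression overlaps — gene models whose promoter
  windows are placed over a chosen subset of truth DMRs, with a
  differential-expression table in which exactly those genes are
  significant.

Every draw flows from ``SimConfig.seed`` through independent
``numpy.random.Generator`` streams, so one seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import Cluster, GeneModel, GenomicInterval, extend_and_merge
from .io import CpGRecord, DEGRecord


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic methylome; defaults are the study-like regime."""

    seed: int = 0
    n_chroms: int = 2
    probes_per_chrom: int = 40
    probe_len_bp: int = 120
    probe_gap_range: tuple[int, int] = (150, 1500)
    cpg_spacing_bp: float = 20.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    high_mode_weight: float = 0.47
    beta_high_mode: tuple[float, float] = (10.0, 1.2)
    beta_low_mode: tuple[float, float] = (1.2, 10.0)
    n_hyper_dmrs: int = 5
    n_hypo_dmrs: int = 5
    dmr_len_cpgs: tuple[int, int] = (6, 10)
    effect_delta: float = 25.0
    n_genes: int = 40
    n_planted_overlap_genes: int = 4
    deg_effect: float = 2.0
    planted_deg_direction: str = "down"  # "down" | "up" | "alternate"
    island_fraction: float = 0.3
    extend_bp: int = 100
    merge_gap_lt: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_delta <= 100.0:
            raise SimulationError("effect_delta must lie in [0, 100]")
        for name in (
            "n_chroms",
            "probes_per_chrom",
            "n_hyper_dmrs",
            "n_hypo_dmrs",
            "n_genes",
            "n_planted_overlap_genes",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise SimulationError("coverage parameters must be positive")
        if not 0.0 <= self.high_mode_weight <= 1.0:
            raise SimulationError("high_mode_weight must lie in [0, 1]")
        if self.dmr_len_cpgs[0] < 1 or self.dmr_len_cpgs[0] > self.dmr_len_cpgs[1]:
            raise SimulationError("dmr_len_cpgs must be a valid (lo, hi) range")
        if self.planted_deg_direction not in ("down", "up", "alternate"):
            raise SimulationError("planted_deg_direction must be down/up/alternate")


LIBRARIES = ("high_rep1", "high_rep2", "low_rep1", "low_rep2")
GROUPS = {
    "high_rep1": "high",
    "high_rep2": "high",
    "low_rep1": "low",
    "low_rep2": "low",
}


@dataclass(frozen=True)
class PlantedDmr:
    interval: GenomicInterval
    direction: str
    delta: float
    cpg_positions: tuple[int, ...]
    cluster_id: int


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    deg_status: str
    dmr_direction: str
    dmr_index: int

    @property
    def pattern(self) -> str:
        return f"{self.deg_status}/{self.dmr_direction}"


@dataclass
class TruthTable:
    """Ledger of planted effects, used for recovery testing."""

    dmrs: list[PlantedDmr] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dmrs": [
                {
                    "chrom": d.interval.chrom,
                    "start": d.interval.start,
                    "end": d.interval.end,
                    "direction": d.direction,
                    "delta": d.delta,
                    "cpg_positions": list(d.cpg_positions),
                    "cluster_id": d.cluster_id,
                }
                for d in self.dmrs
            ],
            "genes": [dataclasses.asdict(g) for g in self.genes],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        dmrs = [
            PlantedDmr(
                GenomicInterval(d["chrom"], d["start"], d["end"]),
                d["direction"],
                d["delta"],
                tuple(d["cpg_positions"]),
                d["cluster_id"],
            )
            for d in payload["dmrs"]
        ]
        genes = [PlantedGene(**g) for g in payload["genes"]]
        return cls(dmrs, genes)


@dataclass
class SimulatedMethylome:
    probes: list[GenomicInterval]
    islands: list[GenomicInterval]
    clusters: list[Cluster]
    records: dict[str, list[CpGRecord]]
    groups: dict[str, str]
    truth: TruthTable
    pool_high: np.ndarray
    pool_low: np.ndarray
    cpg_chrom: np.ndarray
    cpg_pos: np.ndarray


def _draw_pool(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Bimodal Beta mixture of latent pool methylation levels."""
    is_high = rng.random(n) < cfg.high_mode_weight
    a_hi, b_hi = cfg.beta_high_mode
    a_lo, b_lo = cfg.beta_low_mode
    p = np.where(is_high, rng.beta(a_hi, b_hi, n), rng.beta(a_lo, b_lo, n))
    return p


def _nb_coverage(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Negative-binomial read depth with mean m and dispersion r (var = m + m^2/r)."""
    r = cfg.coverage_dispersion
    p = r / (r + cfg.coverage_mean)
    return rng.negative_binomial(r, p, n)


def nb_min_coverage_tail(cfg: SimConfig, min_coverage: int = 10) -> float:
    """P(coverage < min_coverage) for one library under the NB depth model."""
    from scipy import stats

    r = cfg.coverage_dispersion
    p = r / (r + cfg.coverage_mean)
    return float(stats.nbinom.cdf(min_coverage - 1, r, p))


def simulate_methylome(config: SimConfig) -> SimulatedMethylome:
    """Generate probes, four coverage tables, and the planted-DMR truth.

    With ``effect_delta == 0`` no effects are planted and the truth list
    is empty (the null model).
    """
    rng = np.random.default_rng([config.seed, 11])

    probes: list[GenomicInterval] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        pos = 1000
        for _ in range(config.probes_per_chrom):
            probes.append(GenomicInterval(chrom, pos, pos + config.probe_len_bp))
            pos += config.probe_len_bp + int(
                rng.integers(config.probe_gap_range[0], config.probe_gap_range[1] + 1)
            )
    clusters = extend_and_merge(probes, config.extend_bp, config.merge_gap_lt)

    # islands: a random subset of (pre-extension) probe footprints
    n_isl = int(round(config.island_fraction * len(probes)))
    isl_idx = sorted(rng.choice(len(probes), size=n_isl, replace=False).tolist())
    islands = [probes[i] for i in isl_idx]

    # CpGs placed inside clusters with geometric spacing
    chroms: list[str] = []
    positions: list[int] = []
    cluster_of: list[int] = []
    spacing_p = 1.0 / max(config.cpg_spacing_bp, 1.0)
    for cl in clusters:
        pos = cl.interval.start + int(rng.geometric(spacing_p))
        while pos < cl.interval.end:
            chroms.append(cl.interval.chrom)
            positions.append(pos)
            cluster_of.append(cl.cluster_id)
            pos += int(rng.geometric(spacing_p))
    cpg_chrom = np.array(chroms, dtype=object)
    cpg_pos = np.array(positions, dtype=np.int64)
    cluster_of_arr = np.array(cluster_of, dtype=np.int64)
    n_cpgs = len(cpg_pos)

    pool = _draw_pool(rng, config, n_cpgs)
    pool_high = pool.copy()
    pool_low = pool.copy()

    truth = TruthTable()
    n_planted = config.n_hyper_dmrs + config.n_hypo_dmrs
    if config.effect_delta > 0 and n_planted > 0:
        directions = ["hyper"] * config.n_hyper_dmrs + ["hypo"] * config.n_hypo_dmrs
        shift = config.effect_delta / 100.0
        cluster_ids = [cl.cluster_id for cl in clusters]
        rng.shuffle(cluster_ids)
        cluster_sites = {
            cid: np.flatnonzero(cluster_of_arr == cid) for cid in cluster_ids
        }
        taken = iter(cluster_ids)
        a_hi, b_hi = config.beta_high_mode
        a_lo, b_lo = config.beta_low_mode
        for direction in directions:
            length = int(
                rng.integers(config.dmr_len_cpgs[0], config.dmr_len_cpgs[1] + 1)
            )
            cid = None
            for cand in taken:
                if len(cluster_sites[cand]) >= length:
                    cid = cand
                    break
            if cid is None:
                raise SimulationError(
                    "not enough clusters with sufficient CpGs to plant all DMRs; "
                    "increase probes_per_chrom or probe_len_bp"
                )
            sites = cluster_sites[cid]
            start_i = int(rng.integers(0, len(sites) - length + 1))
            idx = sites[start_i : start_i + length]
            # baseline drawn from the mode the shift moves away from
            if direction == "hyper":
                base = rng.beta(a_lo, b_lo, length)
                pool_high[idx] = np.clip(base + shift, 0.0, 1.0)
            else:
                base = rng.beta(a_hi, b_hi, length)
                pool_high[idx] = np.clip(base - shift, 0.0, 1.0)
            pool_low[idx] = base
            pos_run = tuple(int(p) for p in cpg_pos[idx])
            truth.dmrs.append(
                PlantedDmr(
                    GenomicInterval(str(cpg_chrom[idx[0]]), pos_run[0], pos_run[-1] + 1),
                    direction,
                    config.effect_delta,
                    pos_run,
                    int(cid),
                )
            )
        truth.dmrs.sort(key=lambda d: (d.interval.chrom, d.interval.start))

    records: dict[str, list[CpGRecord]] = {}
    for lib in LIBRARIES:
        pool_lib = pool_high if GROUPS[lib] == "high" else pool_low
        cov = _nb_coverage(rng, config, n_cpgs)
        meth = rng.binomial(cov, pool_lib)
        records[lib] = [
            CpGRecord(str(cpg_chrom[i]), int(cpg_pos[i]), int(meth[i]), int(cov[i] - meth[i]))
            for i in range(n_cpgs)
        ]

    return SimulatedMethylome(
        probes=probes,
        islands=islands,
        clusters=clusters,
        records=records,
        groups=dict(GROUPS),
        truth=truth,
        pool_high=pool_high,
        pool_low=pool_low,
        cpg_chrom=cpg_chrom,
        cpg_pos=cpg_pos,
    )


def place_genes(config: SimConfig, truth: TruthTable) -> list[GeneModel]:
    """Gene models with promoters planted over a subset of truth DMRs.

    The first ``n_planted_overlap_genes`` truth DMRs each get one gene
    whose strand-aware promoter window (-1500/+500 of the TSS) fully
    contains the region; filler genes are placed far from all clusters
    so their promoters cannot touch any called DMR.  Updates
    ``truth.genes`` with the expected overlap patterns.
    """
    rng = np.random.default_rng([config.seed, 23])
    k = config.n_planted_overlap_genes
    if k > len(truth.dmrs):
        raise SimulationError(
            f"cannot plant {k} overlap genes with only {len(truth.dmrs)} truth DMRs"
        )
    genes: list[GeneModel] = []
    truth.genes = []
    for i in range(k):
        dmr = truth.dmrs[i]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = dmr.interval.end + 100
        else:
            tss = max(0, dmr.interval.start - 100)
        gene_id = f"PLANT{i + 1:03d}"
        genes.append(GeneModel(gene_id, dmr.interval.chrom, tss, strand))
        if config.planted_deg_direction == "alternate":
            status = "down" if i % 2 == 0 else "up"
        else:
            status = config.planted_deg_direction
        truth.genes.append(PlantedGene(gene_id, status, dmr.direction, i))

    chrom_max: dict[str, int] = {}
    for d in truth.dmrs:
        chrom_max[d.interval.chrom] = max(
            chrom_max.get(d.interval.chrom, 0), d.interval.end
        )
    n_filler = max(0, config.n_genes - k)
    chrom_names = [f"chr{c + 1}" for c in range(max(config.n_chroms, 1))]
    far = {c: chrom_max.get(c, 0) + 1_000_000 for c in chrom_names}
    for i in range(n_filler):
        chrom = chrom_names[i % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"FILL{i + 1:03d}", chrom, far[chrom], strand))
        far[chrom] += 5000
    return genes


def simulate_expression(
    config: SimConfig, truth: TruthTable, gene_models: list[GeneModel]
) -> list[DEGRecord]:
    """Differential-expression table with exactly the planted genes significant.

    Planted overlap genes get |log2fc| = ``deg_effect`` with q far below
    0.05; all other genes get log2fc near 0 with q >= 0.05.
    """
    rng = np.random.default_rng([config.seed, 37])
    known = {g.gene_id for g in gene_models}
    planted = {g.gene_id: g for g in truth.genes}
    for gid in planted:
        if gid not in known:
            raise SimulationError(f"planted gene {gid!r} absent from gene models")
    records: list[DEGRecord] = []
    for g in gene_models:
        if g.gene_id in planted:
            sign = 1.0 if planted[g.gene_id].deg_status == "up" else -1.0
            log2fc = sign * config.deg_effect
            q = float(10.0 ** -rng.uniform(6.0, 20.0))
        else:
            log2fc = float(rng.normal(0.0, 0.1))
            q = float(rng.uniform(0.05, 1.0))
        records.append(DEGRecord(g.gene_id, log2fc, q))
    return records


def write_manifest(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True) + "\n"
    )
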
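# Methods

## Design and model

The pipeline targets a pooled two-group targeted-bisulfite design: equal
quantities of DNA from every individual in an exposure group are pooled into
one library, and each pool is sequenced twice (technical replicates). The
observable methylome is restricted to capture-probe neighborhoods. Two
consequences shape the method:

* **No within-group variance is estimable.** Each group is one biological
  sample (the pool). DMRs are therefore defined by a sustained effect-size
  threshold — runs of CpGs whose group difference exceeds a cutoff — not by a
  per-region test statistic with a permutation or model-based null. No
  p-values are attached to DMRs, by design.
* **Technical replicates share the latent pool methylation exactly.**
  Replicate disagreement is pure resampling noise, which is why cumulative
  methylation distributions of the two replicates of a pool should coincide,
  and why the simulator draws both replicates from one latent profile.

## Coordinates and formats

Internally everything is 0-based half-open (BED convention). The single
exception is the Bismark coverage dialect at the file boundary (1-based,
start = end), converted on read and write. The methylation-percent column of
coverage files is never trusted; it is recomputed from the counts. A CpG
missing from one library's file is represented as coverage 0, which makes the
"≥ 10× in all samples" filter well defined on the union of sites.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 10 reads | per-library depth floor; a site is retained only if every library meets it |
| `extend_bp` | 100 bp | probe extension on each side before merging |
| `merge_gap_lt` | 300 bp | strict gap threshold for merging extended probes into clusters |
| `cutoff` | 10 points | per-CpG \|ΔMeth\| exceedance, strict `>` |
| `min_cpgs` | 4 | minimum consecutive exceeding CpGs per DMR |
| `full_meth_threshold` | 0.80 | beta above which a CpG is "fully methylated", strict `>` |
| promoter window | −1500/+500 bp | strand-aware, around the TSS |
| shore / shelf | 0–2 kb / 2–4 kb | flanks of CpG island edges (standard convention) |
| `q_threshold` | 0.05 | strict FDR cutoff for differential expression |

Strictness choices (`> 10`, `> 0.80`, `q < 0.05`) follow the definitions of
the quantities ("above 10%", "> 80%", "q < 0.05") rather than inclusive
variants.

## Design choices where the design was open

* **Extension before merging.** Probes are extended first; the < 300 bp merge
  gap is measured between extended regions (`next.start − prev.end` on
  half-open intervals). `merge_before_extension=True` applies the gap
  criterion to raw probe coordinates instead, then extends and unions any
  overlaps the extension creates.
* **Replicate-averaged ΔMeth.** Group betas are the unweighted mean of the
  replicates' betas, because replicates are technical resamplings of one
  pool and should count equally regardless of sequencing depth.
  `pool_counts=True` switches to summed-count pooling, which weights
  replicates by coverage.
* **Per-CpG exceedance only.** A run qualifies when every CpG exceeds the
  cutoff; no additional threshold on the region mean is applied (every-CpG
  exceedance already implies the mean exceeds it).
* **Promoter-aware strand.** "Upstream/downstream of the TSS" is taken in the
  direction of transcription; the minus-strand window is the mirror image of
  the plus-strand one.
* **Promoter overlap = any overlap.** A DMR is "in" a promoter if the spans
  share ≥ 1 bp; `require_midpoint=True` restricts to DMRs whose midpoint lies
  inside the window. The gene-level overlap count deduplicates genes with
  multiple promoter DMRs; a gene with both a hyper and a hypo promoter DMR
  contributes two pattern records but one gene.
* **Out-of-cluster CpGs** are excluded from DMR search (clusters bound region
  finding) but included in genome-wide summaries such as the full-methylation
  fraction.
* **No smoothing, no dispersion model.** BSmooth-style smoothing and
  beta-binomial dispersion modeling are deliberately out of scope; the method
  is the thresholded region finder.

## The synthetic-data generator

`simulate_methylome` emulates exactly the structure the analysis assumes:

* **Capture design**: `probes_per_chrom` probes of `probe_len_bp` with
  uniform gaps in `probe_gap_range`, clustered by the same
  `extend_and_merge` the pipeline uses; CpGs are placed only inside clusters
  with geometric spacing (mean `cpg_spacing_bp` = 20 bp, a CpG-dense regime
  typical of captured regulatory regions).
* **Methylation**: latent pool level per CpG from a bimodal Beta mixture,
  Beta(10, 1.2) (methylated mode) with weight 0.47 and Beta(1.2, 10)
  (unmethylated mode). The weight was calibrated analytically so the pool
  probability of β > 0.80 is 0.40, the genome-wide full-methylation regime
  the method is meant to summarize.
* **Depth**: negative binomial with mean 30 and dispersion 10
  (variance = m + m²/r), a realistic over-dispersion for capture
  sequencing; methylated counts are Binomial(coverage, pool level). Both
  replicates of a group use the same pool — technical replication is
  resampling only.
* **Planted DMRs**: runs of 6–10 consecutive CpGs in distinct clusters; the
  high-group pool is shifted by ±`effect_delta`/100 (default 25 points) and
  clipped to [0, 1]. Hypermethylated regions are planted on baselines drawn
  from the unmethylated mode and hypomethylated regions on the methylated
  mode, so the nominal effect size is realizable without truncation — the
  biological picture being that regulatory elements gaining or losing
  methylation flip between states.
* **Planted overlaps**: the first `n_planted_overlap_genes` truth DMRs each
  receive a gene whose strand-aware promoter fully contains the region;
  filler genes are placed ≥ 1 Mb from all clusters so their promoters cannot
  touch any called DMR. Planted genes get |log2FC| = 2 with q ≪ 0.05; all
  others get log2FC ~ N(0, 0.1²) with q ≥ 0.05.
* With `effect_delta = 0` the truth table is empty — the null model used for
  false-call-rate measurements.

What the simulator does **not** model: read-level errors and incomplete
bisulfite conversion (folded into the Beta modes), SNP-induced artifacts,
copy-number effects, biological replicate variance, and spatial correlation
of methylation beyond the planted regions. Passing recovery tests therefore
demonstrates correctness of the algorithms under the assumed design, not
robustness of threshold DMR calling to artifacts real capture data can carry.

A caveat on threshold monotonicity: raising `min_cpgs` can only remove DMRs,
but raising the ΔMeth `cutoff` can *split* one region into two (a borderline
CpG in the middle drops out), so the number of DMRs is not monotone in the
cutoff. The monotone quantity is the set of CpGs covered by DMRs, which can
only shrink as the cutoff rises; comparisons across cutoffs should be made on
covered CpGs or covered bases, not region counts.

## Numerical and degenerate-input choices

* Percentages in summaries are rounded to one decimal; the group contrast in
  full methylation is reported to the nearest point, matching the precision
  at which such contrasts are quoted.
* Beta values are undefined at zero coverage (an error for scalar queries,
  NaN in matrix form); the coverage filter guarantees defined betas
  downstream.
* Degenerate inputs fail loudly and early: empty promoter windows, unsorted
  position lists, malformed file lines (errors name the line number),
  negative interval parameters, q values outside [0, 1], duplicate CpGs or
  gene ids. Zero retained CpGs or zero DMRs are *valid empty results*, not
  errors — the CLI exits 0 with header-only tables.
* Determinism: every random draw derives from `SimConfig.seed` through named
  `numpy.random.Generator` streams, so one seed fixes every output byte.

## Problem sizes used in validation

The default simulated dataset (2 chromosomes × 40 probes, ~1,400 CpGs,
coverage 30×) is the scale at which planted recovery is measured; the
region-finder oracle check runs 1,000 random instances of up to 200 CpGs; the
null false-call rate aggregates 20 effect-free simulations at 100× coverage
(~40,000 CpGs total). These sizes give stable Monte-Carlo estimates for the
properties being checked while keeping the full validation suite fast enough
to run on every change.

## Known limitations

* Counts within a run are treated as exchangeable: there is no weighting of
  ΔMeth by per-CpG coverage, so a marginally covered CpG can break or extend
  a run as easily as a deep one.
* Exactly one TSS per gene record; transcript isoforms and alternative
  promoters are not represented.
* Cluster construction assumes probe coordinates and methylation calls are on
  the same genome build; there is no liftover.
* The DMR table stores run summaries, not per-CpG values; round-tripping
  through the TSV loses the per-CpG Δ vector (kept in memory when calling
  within one session).
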
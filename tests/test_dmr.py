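"""Coverage filtering, ΔMeth, region finding, and genome-wide summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix, matrix_from_betas
from dmrcall.dmr import (
    DmrConfig,
    MethylomeError,
    compute_beta,
    compute_delta,
    coverage_filter,
    cumulative_distribution,
    find_dmrs,
    full_methylation_fraction,
    stratify_by_element,
    summarize_direction_counts,
    summarize_dmrs,
)
from dmrcall.dmr import DeltaTrack
from dmrcall.intervals import GeneModel, GenomicInterval, extend_and_merge
from oracles import maximal_run_dmrs_oracle


def delta_track(deltas, chrom="chr1", start=1000, spacing=20):
    pos = np.arange(len(deltas)) * spacing + start
    return DeltaTrack(
        np.array([chrom] * len(deltas), dtype=object),
        pos.astype(np.int64),
        np.asarray(deltas, dtype=float),
    )


def one_cluster(start=0, end=10**6, chrom="chr1"):
    return extend_and_merge([GenomicInterval(chrom, start + 100, end - 100)])


class TestCoverageFilter:
    def test_retains_iff_all_libraries_at_threshold(self):
        m = make_matrix(
            ["chr1", "chr1"],
            [100, 200],
            [[6, 7, 5, 5], [6, 4, 15, 20]],
            [[6, 8, 5, 6], [6, 5, 15, 20]],
        )
        # coverages: site1 = (12, 15, 10, 11) -> keep; site2 = (12, 9, 30, 40) -> drop
        out = coverage_filter(m, 10)
        assert list(out.pos) == [100]

    def test_lowering_threshold_never_drops_sites(self, default_sim):
        from dmrcall.dmr import MethylationMatrix

        m = MethylationMatrix.from_records(default_sim.records, default_sim.groups)
        kept = [coverage_filter(m, c).n_sites for c in (30, 20, 10, 5, 1)]
        assert kept == sorted(kept)


class TestBetaAndDelta:
    def test_beta_arithmetic(self):
        assert compute_beta(8, 2) == pytest.approx(0.8)
        assert compute_beta(0, 10) == 0.0
        with pytest.raises(MethylomeError):
            compute_beta(0, 0)

    def test_delta_is_mean_of_replicate_betas(self):
        m = matrix_from_betas([(0.80, 0.82, 0.60, 0.58)])
        d = compute_delta(m)
        assert d.delta[0] == pytest.approx(22.0)

    def test_identical_groups_give_zero(self):
        m = matrix_from_betas([0.3, 0.9, 0.0])
        assert np.allclose(compute_delta(m).delta, 0.0)

    def test_group_swap_negates_delta(self):
        m = matrix_from_betas([(0.8, 0.7, 0.2, 0.3), (0.1, 0.2, 0.9, 0.8)])
        swapped = make_matrix(
            list(m.chrom),
            list(m.pos),
            m.meth[:, [2, 3, 0, 1]],
            m.unmeth[:, [2, 3, 0, 1]],
        )
        assert np.allclose(compute_delta(m).delta, -compute_delta(swapped).delta)

    def test_pooled_counts_weight_by_coverage(self):
        # rep1 has 10x the reads of rep2: pooling shifts the group beta
        m = make_matrix(
            ["chr1"], [100], [[100, 0, 50, 50]], [[0, 10, 50, 50]]
        )
        averaged = compute_delta(m).delta[0]
        pooled = compute_delta(m, pool_counts=True).delta[0]
        assert averaged == pytest.approx(100 * (0.5 - 0.5))
        assert pooled == pytest.approx(100 * (100 / 110 - 0.5))

    def test_requires_both_groups(self):
        m = make_matrix(["chr1"], [100], [[5, 5]], [[5, 5]], groups=("high", "high"))
        with pytest.raises(MethylomeError):
            compute_delta(m)


class TestFindDmrs:
    def test_run_broken_by_subthreshold_site(self):
        dmrs = find_dmrs(delta_track([12, 15, 11, 13, -2, 12]), one_cluster())
        assert len(dmrs) == 1
        (d,) = dmrs
        assert d.direction == "hyper" and d.n_cpgs == 4
        assert d.cpg_positions == (1000, 1020, 1040, 1060)
        assert d.interval == GenomicInterval("chr1", 1000, 1061)

    def test_all_zero_deltas_yield_nothing(self):
        assert find_dmrs(delta_track([0.0] * 20), one_cluster()) == []

    def test_hypo_run_statistics(self):
        (d,) = find_dmrs(delta_track([-11, -12, -13, -14]), one_cluster())
        assert d.direction == "hypo"
        assert d.n_cpgs == 4
        assert d.mean_delta == pytest.approx(-12.5)
        assert d.area == pytest.approx(50.0)

    def test_cutoff_is_strict(self):
        assert find_dmrs(delta_track([10.0, 10.0, 10.0, 10.0]), one_cluster()) == []

    def test_runs_do_not_cross_cluster_boundaries(self):
        clusters = extend_and_merge(
            [GenomicInterval("chr1", 1000, 1070), GenomicInterval("chr1", 2000, 2100)]
        )
        # clusters [900,1170) and [1900,2200): 4 exceeding CpGs split 2+2,
        # so no single cluster holds a qualifying run of 4
        track = DeltaTrack(
            np.array(["chr1"] * 4, dtype=object),
            np.array([1100, 1150, 1950, 2000], dtype=np.int64),
            np.array([15.0, 15.0, 15.0, 15.0]),
        )
        assert find_dmrs(track, clusters) == []
        # within one cluster the same deltas would qualify
        assert len(find_dmrs(track, one_cluster())) == 1

    def test_sites_outside_clusters_excluded(self):
        clusters = one_cluster(start=0, end=1500)
        track = delta_track([20, 20, 20, 20, 20], start=1400, spacing=50)
        # positions 1400..1600; cluster spans [100,1400) extended -> [0,1500)... only some inside
        dmrs = find_dmrs(track, clusters)
        for d in dmrs:
            assert all(p < 1500 for p in d.cpg_positions)

    @given(
        deltas=st.lists(
            st.floats(-40, 40, allow_nan=False, width=32), min_size=0, max_size=60
        ),
        min_cpgs=st.integers(1, 5),
        cutoff=st.floats(1, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, deltas, min_cpgs, cutoff):
        config = DmrConfig(cutoff=cutoff, min_cpgs=min_cpgs)
        track = delta_track(deltas)
        dmrs = find_dmrs(track, one_cluster(), config)
        got = sorted(
            (
                int(np.where(track.pos == d.cpg_positions[0])[0][0]),
                int(np.where(track.pos == d.cpg_positions[-1])[0][0]) + 1,
                d.direction,
            )
            for d in dmrs
        )
        want = maximal_run_dmrs_oracle(list(deltas), cutoff, min_cpgs)
        assert got == want
        # the two independent oracles agree with each other too
        from oracles import window_enumeration_oracle

        assert window_enumeration_oracle(list(deltas), cutoff, min_cpgs) == want
        for d in dmrs:
            d.validate(config)

    @given(
        deltas=st.lists(st.floats(-40, 40, allow_nan=False), min_size=4, max_size=60),
        c1=st.floats(5, 20),
        c2=st.floats(5, 20),
        m1=st.integers(1, 6),
        m2=st.integers(1, 6),
    )
    @settings(max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, deltas, c1, c2, m1, m2):
        # raising the cutoff can split one run into two, so DMR *counts*
        # are not monotone in the cutoff; the set of DMR-covered CpGs is.
        # min_cpgs only filters runs, so counts are monotone in it.
        lo_c, hi_c = sorted((c1, c2))
        lo_m, hi_m = sorted((m1, m2))
        track = delta_track(deltas)
        cl = one_cluster()

        def covered(cutoff, min_cpgs):
            return {
                p
                for d in find_dmrs(track, cl, DmrConfig(cutoff=cutoff, min_cpgs=min_cpgs))
                for p in d.cpg_positions
            }

        assert covered(hi_c, lo_m) <= covered(lo_c, lo_m)
        n_loose = len(find_dmrs(track, cl, DmrConfig(cutoff=lo_c, min_cpgs=lo_m)))
        n_tight_len = len(find_dmrs(track, cl, DmrConfig(cutoff=lo_c, min_cpgs=hi_m)))
        assert n_tight_len <= n_loose

    @given(
        deltas=st.lists(st.floats(-40, 40, allow_nan=False), min_size=0, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_negation_swaps_directions(self, deltas):
        track = delta_track(deltas)
        neg = delta_track([-d for d in deltas])
        cl = one_cluster()
        a = find_dmrs(track, cl)
        b = find_dmrs(neg, cl)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [(d.cpg_positions, flip[d.direction]) for d in a] == [
            (d.cpg_positions, d.direction) for d in b
        ]


class TestSummaries:
    def test_direction_partition_percentages(self):
        s = summarize_direction_counts(391, 777)
        assert s["n_total"] == 1168
        assert s["pct_hyper"] == 33.5
        assert s["pct_hypo"] == 66.5

    def test_empty_and_symmetric_partitions(self):
        empty = summarize_direction_counts(0, 0)
        assert empty["n_total"] == 0 and empty["pct_hyper"] is None
        even = summarize_direction_counts(1, 1)
        assert (even["pct_hyper"], even["pct_hypo"]) == (50.0, 50.0)

    def test_summarize_dmrs_counts_directions(self):
        (d,) = find_dmrs(delta_track([-11, -12, -13, -14]), one_cluster())
        s = summarize_dmrs([d])
        assert (s["n_hyper"], s["n_hypo"]) == (0, 1)


class TestFullMethylation:
    def test_counting_is_strict_at_threshold(self):
        m = matrix_from_betas([0.9, 0.85, 0.7, 0.81])
        assert full_methylation_fraction(m, "high_rep1", 0.8) == pytest.approx(75.0)
        m2 = matrix_from_betas([0.80, 0.9])
        assert full_methylation_fraction(m2, "high_rep1", 0.8) == pytest.approx(50.0)

    def test_all_unmethylated(self):
        m = matrix_from_betas([0.0, 0.0])
        assert full_methylation_fraction(m, "low_rep1") == 0.0

    def test_non_increasing_in_threshold(self):
        m = matrix_from_betas([i / 20 for i in range(21)])
        vals = [
            full_methylation_fraction(m, "high_rep1", t)
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert vals == sorted(vals, reverse=True)


class TestCumulativeDistribution:
    def test_direct_counting(self):
        m = matrix_from_betas([0.0, 0.5, 1.0], coverage=10)
        curve = cumulative_distribution(m, "high_rep1", [0.25, 0.75, 1.0])
        assert curve == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_point_mass_at_one(self):
        m = matrix_from_betas([1.0, 1.0], coverage=10)
        curve = cumulative_distribution(m, "high_rep1", [0.5, 0.99, 1.0])
        assert curve == pytest.approx([0.0, 0.0, 1.0])

    def test_replicates_of_same_pool_have_identical_curves(self):
        m = matrix_from_betas([0.2, 0.4, 0.9], coverage=50)
        grid = np.linspace(0, 1, 11)
        a = cumulative_distribution(m, "high_rep1", grid)
        b = cumulative_distribution(m, "high_rep2", grid)
        assert np.array_equal(a, b)

    def test_empty_grid_rejected(self):
        m = matrix_from_betas([0.5])
        with pytest.raises(MethylomeError):
            cumulative_distribution(m, "high_rep1", [])


class TestStratifyByElement:
    def setup_method(self):
        self.islands = [GenomicInterval("chr1", 10000, 11000)]
        self.genes = [GeneModel("G1", "chr1", 50000, "+")]

    def positions_matrix(self, positions, betas_high=0.6, betas_low=0.4):
        n = len(positions)
        cov = 100
        meth = [
            [
                round(betas_high * cov),
                round(betas_high * cov),
                round(betas_low * cov),
                round(betas_low * cov),
            ]
            for _ in range(n)
        ]
        unmeth = [[cov - x for x in row] for row in meth]
        return make_matrix(["chr1"] * n, list(positions), meth, unmeth)

    def test_island_shore_shelf_membership(self):
        m = self.positions_matrix([10500, 12000, 14000, 16000])
        # 10500 inside; 12000 is 1000 bp past the edge (shore);
        # 14000 is 3000 bp (shelf); 16000 is 5000 bp (no island category)
        out = stratify_by_element(m, self.islands, [])
        assert out["island"]["n_cpgs"] == 1
        assert out["shore"]["n_cpgs"] == 1
        assert out["shelf"]["n_cpgs"] == 1

    def test_promoter_and_gene_body_labels(self):
        spans = {"G1": GenomicInterval("chr1", 50000, 60000)}
        m = self.positions_matrix([49000, 55000])
        out = stratify_by_element(m, self.islands, self.genes, gene_spans=spans)
        assert out["promoter"]["n_cpgs"] == 1
        assert out["gene_body"]["n_cpgs"] == 1

    def test_equal_groups_give_equal_means(self):
        m = self.positions_matrix([10500, 12000], betas_high=0.5, betas_low=0.5)
        out = stratify_by_element(m, self.islands, [])
        for cat in out.values():
            assert cat["high"] == pytest.approx(cat["low"])

    def test_group_means_reflect_shift(self):
        m = self.positions_matrix([10500], betas_high=0.7, betas_low=0.3)
        out = stratify_by_element(m, self.islands, [])
        assert out["island"]["high"] == pytest.approx(0.7)
        assert out["island"]["low"] == pytest.approx(0.3)

    def test_no_annotation_rejected(self):
        m = self.positions_matrix([10500])
        with pytest.raises(MethylomeError):
            stratify_by_element(m, [], [])
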
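from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbpomics import binding
from rbpomics.binding import (
    DbpResult,
    aggregate_genes,
    annotate_regions,
    call_dbps,
    call_significant_peaks,
    coordination_stats,
    dbp_anova,
    dbp_effect,
    overlap_summary,
    region_distribution,
    rpm_normalize,
)
from rbpomics.iolib import (
    ClusterRecord,
    CountMatrix,
    GeneAnnotation,
    GeneFeature,
    GenomicInterval,
)

from conftest import cell_matrix, make_design


class TestRpm:
    def test_definition(self):
        design = make_design(n_replicates=2)
        cm = CountMatrix(
            ["c1"], [d.sample_id for d in design],
            np.array([[10, 0, 25, 3, 1, 2, 3, 4]]),
        )
        design[2] = type(design[2])(design[2].sample_id, "IP", "untreated", 1,
                                    5_000_000)
        rpm = rpm_normalize(cm, design)
        assert rpm.values[0, 0] == pytest.approx(10.0)
        assert rpm.values[0, 1] == 0.0
        assert rpm.values[0, 2] == pytest.approx(5.0)

    def test_linearity_in_counts(self, eclip_sim):
        rpm1 = rpm_normalize(eclip_sim.counts, eclip_sim.design)
        scaled = CountMatrix(
            list(eclip_sim.counts.row_ids),
            list(eclip_sim.counts.col_ids),
            eclip_sim.counts.values * 3,
        )
        rpm3 = rpm_normalize(scaled, eclip_sim.design)
        np.testing.assert_allclose(rpm3.values, 3 * rpm1.values)

    def test_missing_library_size(self, eclip_sim):
        with pytest.raises(ValueError, match="library size"):
            rpm_normalize(eclip_sim.counts, eclip_sim.design[:-1])


class TestPeakCalling:
    def _two_sample(self, ip, inp, lib=1_000_000):
        from rbpomics.iolib import SampleDesign

        design = [
            SampleDesign("ip1", "IP", "untreated", 1, lib),
            SampleDesign("in1", "input", "untreated", 1, lib),
        ]
        cm = CountMatrix(["c1"], ["ip1", "in1"], np.array([[ip, inp]]))
        return cm, design

    def test_enriched_peak_significant(self):
        # 80 IP vs 10 input reads in equal libraries: exactly 8-fold (log2=3)
        cm, design = self._two_sample(80, 10)
        (call,) = call_significant_peaks(cm, design, pseudocount=0)
        assert call.log2_enrichment == pytest.approx(3.0)
        # independent oracle: one-sided Fisher exact on the 2x2 table
        lib = 1_000_000
        _, p_fisher = stats.fisher_exact(
            [[80, lib - 80], [10, lib - 10]], alternative="greater"
        )
        assert call.p_value == pytest.approx(p_fisher, rel=1e-6)
        assert call.p_value < 0.001 and call.significant

    def test_same_enrichment_low_counts_not_significant(self):
        cm, design = self._two_sample(8, 1)
        (call,) = call_significant_peaks(cm, design, pseudocount=0)
        assert call.log2_enrichment == pytest.approx(3.0)
        _, p_fisher = stats.fisher_exact(
            [[8, 1_000_000 - 8], [1, 1_000_000 - 1]], alternative="greater"
        )
        assert call.p_value == pytest.approx(p_fisher, rel=1e-6)
        assert call.p_value > 0.001 and not call.significant

    def test_zero_input_with_pseudocount_is_finite(self):
        cm, design = self._two_sample(50, 0)
        (call,) = call_significant_peaks(cm, design, pseudocount=1)
        assert np.isfinite(call.log2_enrichment)

    def test_counts_exceeding_library_rejected(self):
        cm, design = self._two_sample(80, 10, lib=50)
        with pytest.raises(ValueError, match="exceed"):
            call_significant_peaks(cm, design)


def _gene(gene_id, chrom, feats):
    return GeneAnnotation(
        gene_id,
        [GeneFeature(GenomicInterval(chrom, a, b, "+"), r) for r, a, b in feats],
    )


class TestAnnotate:
    ann = [
        _gene("GA", "chr1", [("CDS", 0, 100), ("3UTR", 100, 200)]),
        _gene("GB", "chr1", [("CDS", 500, 700)]),
        _gene("GC", "chr2", [("5UTR", 0, 50)]),
    ]

    def _cluster(self, chrom, start, end, strand="+"):
        return ClusterRecord(GenomicInterval(chrom, start, end, strand), "c1")

    def test_fully_inside_feature(self):
        (rec,) = annotate_regions([self._cluster("chr1", 120, 160)], self.ann)
        assert (rec.gene_id, rec.region) == ("GA", "3UTR")

    def test_maximal_overlap_wins(self):
        # overlaps CDS by 10 bp and 3'UTR by 40 bp
        (rec,) = annotate_regions([self._cluster("chr1", 90, 140)], self.ann)
        assert rec.region == "3UTR"

    def test_no_gene_is_intergenic(self):
        (rec,) = annotate_regions([self._cluster("chr9", 0, 50)], self.ann)
        assert rec.region == "intergenic" and rec.gene_id == ""

    def test_opposite_strand_ignored(self):
        (rec,) = annotate_regions([self._cluster("chr1", 120, 160, "-")], self.ann)
        assert rec.region == "intergenic"

    def test_gene_tie_goes_to_lexicographically_smallest(self):
        ann = [
            _gene("GZ", "chr3", [("CDS", 0, 100)]),
            _gene("GA", "chr3", [("intron", 0, 100)]),
        ]
        (rec,) = annotate_regions([self._cluster("chr3", 20, 60)], ann)
        assert rec.gene_id == "GA"


class TestRegionDistribution:
    def _recs(self, regions):
        return [
            ClusterRecord(GenomicInterval("chr1", 10 * i, 10 * i + 5), f"c{i}",
                          gene_id="G", region=r)
            for i, r in enumerate(regions)
        ]

    def test_proportions(self):
        dist = region_distribution(self._recs(["3UTR"] * 7 + ["CDS"] * 3))
        assert dist["3UTR"] == pytest.approx(0.7)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            region_distribution([])


class TestAnova:
    def test_all_identical_gives_p_one(self):
        cm, design = cell_matrix({
            ("IP", "treated"): [5.0, 5.0], ("IP", "untreated"): [5.0, 5.0],
            ("input", "treated"): [5.0, 5.0], ("input", "untreated"): [5.0, 5.0],
        })
        assert dbp_anova(cm, design)[0] == 1.0

    def test_textbook_example_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = {
            ("IP", "treated"): [10.0, 12.0], ("IP", "untreated"): [4.0, 6.0],
            ("input", "treated"): [2.0, 3.0], ("input", "untreated"): [2.0, 3.0],
        }
        cm, design = cell_matrix(cells)
        p = dbp_anova(cm, design)[0]
        rows = [
            {"y": v, "assay": a, "treatment": t}
            for (a, t), vals in cells.items() for v in vals
        ]
        fit = ols("y ~ C(assay) * C(treatment)", pd.DataFrame(rows)).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        p_oracle = tab.loc["C(assay):C(treatment)", "PR(>F)"]
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_requires_two_replicates_per_cell(self):
        cm, design = cell_matrix({
            ("IP", "treated"): [1.0], ("IP", "untreated"): [2.0, 3.0],
            ("input", "treated"): [1.0, 2.0], ("input", "untreated"): [2.0, 3.0],
        })
        with pytest.raises(ValueError, match="replicates"):
            dbp_anova(cm, design)

    def test_missing_cell_is_error(self, eclip_sim):
        design = [d for d in eclip_sim.design if
                  not (d.assay == "IP" and d.treatment == "treated")]
        cm = eclip_sim.counts.subset_cols([d.sample_id for d in design])
        with pytest.raises(ValueError, match="cell"):
            dbp_anova(cm, design)


class TestEffect:
    def _delta(self, ip_t, in_t, ip_u, in_u):
        cm, design = cell_matrix({
            ("IP", "treated"): [ip_t, ip_t], ("input", "treated"): [in_t, in_t],
            ("IP", "untreated"): [ip_u, ip_u], ("input", "untreated"): [in_u, in_u],
        })
        return dbp_effect(cm, design, epsilon=0.0).iloc[0]

    def test_arithmetic(self):
        row = self._delta(8, 2, 4, 2)
        assert (row.lfc_treated, row.lfc_untreated, row.delta_lfc) == (2.0, 1.0, 1.0)

    def test_equal_means_give_zero(self):
        assert self._delta(3, 3, 3, 3).delta_lfc == 0.0

    def test_downregulation(self):
        assert self._delta(2, 2, 8, 2).delta_lfc == -2.0

    def test_all_zero_cluster_warns_and_is_zero(self):
        cm, design = cell_matrix({
            ("IP", "treated"): [0.0, 0.0], ("input", "treated"): [0.0, 0.0],
            ("IP", "untreated"): [0.0, 0.0], ("input", "untreated"): [0.0, 0.0],
        })
        with pytest.warns(RuntimeWarning, match="zero RPM"):
            eff = dbp_effect(cm, design, epsilon=0.1)
        assert eff["delta_lfc"].iloc[0] == 0.0


class TestCallDbps:
    def test_direction_rules(self):
        # strong interaction, delta > 0.5 -> up
        cm, design = cell_matrix({
            ("IP", "treated"): [40.0, 42.0], ("input", "treated"): [10.0, 11.0],
            ("IP", "untreated"): [10.0, 10.5], ("input", "untreated"): [10.0, 10.6],
        })
        (res,) = call_dbps(cm, design)
        assert res.direction == "up" and res.p_interaction < 0.05

    def test_small_delta_is_none_despite_significance(self):
        # perfect interaction but |delta| < 0.5
        cm, design = cell_matrix({
            ("IP", "treated"): [12.0, 12.0], ("input", "treated"): [10.0, 10.0],
            ("IP", "untreated"): [10.0, 10.0], ("input", "untreated"): [10.0, 10.0],
        })
        (res,) = call_dbps(cm, design, epsilon=0.0)
        assert res.p_interaction < 0.05
        assert abs(res.delta_lfc) < 0.5
        assert res.direction == "none"

    def test_column_order_invariance(self, eclip_sim):
        rpm = rpm_normalize(eclip_sim.counts, eclip_sim.design)
        res1 = call_dbps(rpm, eclip_sim.design)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(rpm.col_ids))
        shuffled = CountMatrix(
            list(rpm.row_ids),
            [rpm.col_ids[i] for i in perm],
            rpm.values[:, perm],
        )
        res2 = call_dbps(shuffled, eclip_sim.design)
        for a, b in zip(res1, res2):
            assert a.cluster_id == b.cluster_id
            assert a.p_interaction == pytest.approx(b.p_interaction, rel=1e-9)
            assert a.delta_lfc == pytest.approx(b.delta_lfc, rel=1e-9)
            assert a.direction == b.direction

    def test_null_call_rate_bounded(self):
        # pure null Gaussian RPM: calls require p < 0.05 AND |delta| > 0.5,
        # so the rate is below 0.05 and decreases as delta_min grows
        rng = np.random.default_rng(4)
        design = make_design()
        n = 4000
        vals = np.abs(rng.normal(50, 5, size=(n, 8)))
        cm = CountMatrix([f"c{i}" for i in range(n)],
                         [d.sample_id for d in design], vals)
        rate_05 = np.mean([r.direction != "none" for r in call_dbps(cm, design)])
        rate_10 = np.mean(
            [r.direction != "none"
             for r in call_dbps(cm, design, delta_min=1.0)]
        )
        assert rate_05 <= 0.05
        assert rate_10 <= rate_05


def _dbp(cid, delta, direction=None):
    if direction is None:
        direction = "up" if delta > 0 else "down"
    return DbpResult(cid, 0.01, delta, 0.0, delta, direction)


def _cluster_for(cid, gene):
    region = "3UTR" if gene else "intergenic"
    return ClusterRecord(GenomicInterval("chr1", 0, 50), cid, gene, region)


class TestAggregate:
    def test_coordinated_gene(self):
        dbps = [_dbp("c1", 1.2), _dbp("c2", 0.8)]
        clusters = [_cluster_for("c1", "G1"), _cluster_for("c2", "G1")]
        (s,) = aggregate_genes(dbps, clusters)
        assert (s.direction_class, s.n_dbps) == ("up", 2)
        assert s.mean_delta_lfc == pytest.approx(1.0)

    def test_mixed_gene(self):
        dbps = [_dbp("c1", 1.2), _dbp("c2", -0.7)]
        clusters = [_cluster_for("c1", "G1"), _cluster_for("c2", "G1")]
        (s,) = aggregate_genes(dbps, clusters)
        assert s.direction_class == "mixed"

    def test_none_calls_and_intergenic_excluded(self):
        dbps = [_dbp("c1", 1.2), DbpResult("c2", 0.5, 0, 0, 0.1, "none"),
                _dbp("c3", 2.0)]
        clusters = [_cluster_for("c1", "G1"), _cluster_for("c2", "G1"),
                    _cluster_for("c3", "")]
        (s,) = aggregate_genes(dbps, clusters)
        assert s.gene_id == "G1" and s.n_dbps == 1

    def test_direction_class_matches_brute_force_all_patterns(self):
        # every sign pattern up to 6 DBPs on one gene
        for k in range(1, 7):
            for signs in product([1, -1], repeat=k):
                dbps = [_dbp(f"c{i}", s * (1 + i)) for i, s in enumerate(signs)]
                clusters = [_cluster_for(f"c{i}", "G1") for i in range(k)]
                (summary,) = aggregate_genes(dbps, clusters)
                ups, downs = signs.count(1), signs.count(-1)
                expected = ("mixed" if ups and downs else "up" if ups else "down")
                assert summary.direction_class == expected
                assert summary.n_dbps == summary.n_up + summary.n_down == k


class TestOverlapAndCoordination:
    def test_set_arithmetic(self):
        ov = overlap_summary({"A", "B", "C"}, {"B", "C", "D"})
        assert (ov.n_shared, ov.n_lost, ov.n_new) == (2, 1, 1)

    def test_identical_sets(self):
        ov = overlap_summary({"A", "B"}, {"A", "B"})
        assert (ov.n_lost, ov.n_new) == (0, 0)
        assert ov.shared_fraction_of_untreated == pytest.approx(100.0)

    def test_empty_untreated_is_error(self):
        with pytest.raises(ValueError):
            overlap_summary(set(), {"A"})

    def test_coordination_counts(self):
        from rbpomics.binding import GeneBindingSummary

        summaries = [
            GeneBindingSummary("G1", 2, 2, 0, "up", 1.0),
            GeneBindingSummary("G2", 3, 0, 3, "down", -1.0),
            GeneBindingSummary("G3", 2, 1, 1, "mixed", 0.1),
            GeneBindingSummary("G4", 1, 1, 0, "up", 2.0),
        ]
        cs = coordination_stats(summaries)
        assert (cs.n_genes, cs.n_multi, cs.n_coordinated, cs.n_mixed) == (4, 3, 2, 1)
        assert cs.pct_coordinated_of_multi == pytest.approx(100 * 2 / 3)
        assert cs.pct_mixed_of_all == pytest.approx(25.0)
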
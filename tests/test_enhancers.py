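"""Peak analytics: thresholds, overlaps, windows, ratios, enrichment."""

import numpy as np
import pandas as pd
import pytest

from conftest import (brute_nearest_tss, brute_overlap_count, make_genes,
                      make_matrix, make_peaks, random_intervals)
from tcellsig import enhancers as enh
from tcellsig import synthetic_data as syn
from tcellsig.containers import CoverageTrack, PeakSet, TagProfile


class TestThresholdPeaks:
    @pytest.mark.parametrize("tags,kept", [(39.0, 0), (40.0, 1), (41.0, 1)])
    def test_inclusive_boundary(self, tags, kept):
        ps = make_peaks([("chr1", 0, 100, "p1", tags)], ["c"])
        assert len(enh.threshold_peaks(ps, "c")) == kept

    def test_empty_set_passes_through(self):
        ps = make_peaks([], ["c"])
        assert len(enh.threshold_peaks(ps, "c")) == 0

    def test_unknown_condition_is_error(self):
        ps = make_peaks([("chr1", 0, 100, "p1", 50.0)], ["c"])
        with pytest.raises(KeyError):
            enh.threshold_peaks(ps, "missing")


class TestOverlapTable:
    def test_diagonal_is_thresholded_count(self):
        ps = make_peaks([("chr1", 0, 100, "p1", 50.0),
                         ("chr1", 200, 300, "p2", 10.0)], ["c"])
        table = enh.overlap_table([ps])
        assert table.iloc[0, 0] == 1

    def test_hand_example(self):
        a = make_peaks([("chr1", 0, 100, "a1", 99.0),
                        ("chr1", 200, 300, "a2", 99.0)], ["c"])
        b = make_peaks([("chr1", 90, 110, "b1", 99.0)], ["c"])
        table = enh.overlap_table([a, b], labels=["A", "B"])
        assert table.loc["A", "B"] == 1
        assert table.loc["B", "A"] == 1

    def test_disjoint_chromosomes_no_overlap(self):
        a = make_peaks([("chr1", 0, 100, "a1", 99.0)], ["c"])
        b = make_peaks([("chr2", 0, 100, "b1", 99.0)], ["c"])
        table = enh.overlap_table([a, b], labels=["A", "B"])
        assert table.loc["A", "B"] == 0 and table.loc["B", "A"] == 0

    def test_matches_brute_force_on_random_intervals(self, rng):
        rows_a = random_intervals(rng, 300)
        rows_b = random_intervals(rng, 300)
        a = make_peaks([(c, s, e, f"a{i}", 99.0)
                        for i, (c, s, e) in enumerate(rows_a)], ["c"])
        b = make_peaks([(c, s, e, f"b{i}", 99.0)
                        for i, (c, s, e) in enumerate(rows_b)], ["c"])
        table = enh.overlap_table([a, b], labels=["A", "B"])
        assert table.loc["A", "B"] == brute_overlap_count(rows_a, rows_b)
        assert table.loc["B", "A"] == brute_overlap_count(rows_b, rows_a)

    def test_subset_counts_all_members(self, rng):
        rows = random_intervals(rng, 100)
        big = make_peaks([(c, s, e, f"p{i}", 99.0)
                          for i, (c, s, e) in enumerate(rows)], ["c"])
        sub_rows = rows[:30]
        sub = make_peaks([(c, s, e, f"q{i}", 99.0)
                          for i, (c, s, e) in enumerate(sub_rows)], ["c"])
        table = enh.overlap_table([sub, big], labels=["S", "ALL"])
        assert table.loc["S", "ALL"] == len(sub_rows)


class TestClassifyFoldChange:
    @pytest.mark.parametrize("a,b,pc,label", [
        (10.0, 25.0, 0.0, "up"),        # 2.5 > 2
        (10.0, 20.0, 0.0, "unchanged"),  # exactly 2-fold is not "more than"
        (0.0, 5.0, 1.0, "up"),          # pseudocount keeps the ratio finite
        (25.0, 10.0, 0.0, "down"),
    ])
    def test_rule(self, a, b, pc, label):
        ps = make_peaks([("chr1", 0, 100, "p1", a, b)], ["A", "B"])
        out = enh.classify_fold_change(ps, "A", "B", pseudocount=pc)
        assert out["p1"] == label

    def test_antisymmetric_under_condition_swap(self, rng):
        rows = [("chr1", i * 1000, i * 1000 + 100, f"p{i}",
                 float(rng.integers(0, 100)), float(rng.integers(0, 100)))
                for i in range(200)]
        ps = make_peaks(rows, ["A", "B"])
        fwd = enh.classify_fold_change(ps, "A", "B")
        rev = enh.classify_fold_change(ps, "B", "A")
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (rev == fwd.map(swap)).all()


class TestAggregateTags:
    def test_uniform_coverage_closed_form(self):
        sites = make_peaks([("chr1", 1000, 1200, "s1", 1.0),
                            ("chr1", 5000, 5100, "s2", 1.0),
                            ("chr1", 9000, 9500, "s3", 1.0)], ["x"])
        d = 2.0
        track = CoverageTrack({"chr1": np.full(20_000, d)})
        agg = enh.aggregate_tags_at_sites(sites, {"c": track}, window_bp=1000)
        assert agg["totals"]["c"] == pytest.approx(3 * 2 * 1000 * d)

    def test_matches_brute_force_summation(self, rng):
        cov = {"chr1": rng.uniform(0, 3, 50_000), "chr2": rng.uniform(0, 3, 50_000)}
        tracks = {"A": CoverageTrack({k: v.copy() for k, v in cov.items()}),
                  "B": CoverageTrack({k: v * 2 for k, v in cov.items()})}
        sites = make_peaks([("chr1", 100, 300, "s1", 1.0),
                            ("chr2", 40_000, 40_100, "s2", 1.0),
                            ("chr1", 49_900, 49_950, "s3", 1.0)], ["x"])
        agg = enh.aggregate_tags_at_sites(sites, tracks, window_bp=500)
        for cond, arr in (("A", 1.0), ("B", 2.0)):
            expected = 0.0
            for _, r in sites.df.iterrows():
                mid = (r["start"] + r["end"]) // 2
                a = cov[r["chrom"]]
                for pos in range(max(0, mid - 500), min(len(a), mid + 500)):
                    expected += a[pos] * arr
            assert agg["totals"][cond] == pytest.approx(expected)

    def test_planted_monotone_acetylation_ordering(self, rng):
        sites = make_peaks([("chr1", 2_000, 2_200, "s1", 1.0),
                            ("chr1", 8_000, 8_300, "s2", 1.0)], ["x"])
        tracks = {}
        for i, scale in enumerate((1.0, 2.0, 3.5)):
            base = rng.uniform(0.5, 1.0, 12_000)
            tracks[f"cond{i}"] = CoverageTrack({"chr1": base * scale})
        agg = enh.aggregate_tags_at_sites(sites, tracks)
        totals = [agg["totals"][f"cond{i}"] for i in range(3)]
        assert totals[0] < totals[1] < totals[2]

    def test_empty_sites_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            enh.aggregate_tags_at_sites(make_peaks([], ["x"]),
                                        {"c": CoverageTrack({"chr1": np.ones(10)})})


class TestSpreadingRatio:
    def test_uniform_coverage_is_exactly_one(self):
        prof = TagProfile(-5000, np.full(10_000, 3.0))
        assert enh.spreading_ratio(prof) == 1.0

    def test_focal_below_one_below_spread_body(self):
        focal = syn.generate_tag_profile("focal_tss", seed=1)
        body = syn.generate_tag_profile("spread_body", seed=1)
        r_focal = enh.spreading_ratio(focal)
        r_body = enh.spreading_ratio(body)
        assert r_focal < 1.0 < r_body

    def test_invariant_under_coverage_scaling(self):
        prof = syn.generate_tag_profile("focal_tss", seed=2)
        scaled = TagProfile(prof.offset_start, prof.coverage * 17.0)
        assert enh.spreading_ratio(scaled) == pytest.approx(
            enh.spreading_ratio(prof), rel=1e-12)

    def test_genomic_windows_are_strand_aware(self):
        # coverage high only upstream of position 10000 -> '+' body sees
        # nothing, '-' body sees everything
        cov = np.zeros(20_000)
        cov[6_000:9_000] = 5.0
        track = CoverageTrack({"chr1": cov})
        plus = pd.Series({"gene_id": "gp", "chrom": "chr1", "start": 10_000,
                          "end": 19_000, "strand": "+", "tss": 10_000})
        minus = pd.Series({"gene_id": "gm", "chrom": "chr1", "start": 1_000,
                           "end": 10_000, "strand": "-", "tss": 10_000})
        assert enh.spreading_ratio(track, plus) < enh.spreading_ratio(track, minus)

    def test_short_gene_truncates_with_warning(self, caplog):
        track = CoverageTrack({"chr1": np.full(12_000, 1.0)})
        short = pd.Series({"gene_id": "gs", "chrom": "chr1", "start": 5_000,
                           "end": 7_000, "strand": "+", "tss": 5_000})
        with caplog.at_level("WARNING"):
            ratio = enh.spreading_ratio(track, short)
        assert "truncated" in caplog.text
        assert ratio == pytest.approx(1.0)


class TestPromoterBindingFrequency:
    GENES = [("g1", "chr1", 10_000, 20_000, "+", 10_000),
             ("g2", "chr1", 40_000, 50_000, "+", 40_000),
             ("g3", "chr1", 70_000, 80_000, "-", 80_000),
             ("g4", "chr2", 10_000, 20_000, "+", 10_000)]

    def test_no_sites_gives_zero_everywhere(self):
        genes = make_genes(self.GENES)
        sites = {"AP1": make_peaks([("chr9", 0, 10, "s", 1.0)], ["x"])}
        out = enh.promoter_binding_frequency(sites, genes,
                                             {"all": [g[0] for g in self.GENES]})
        assert (out["value"] == 0.0).all()

    def test_half_of_group_bound(self):
        genes = make_genes(self.GENES)
        sites = {"AP1": make_peaks([("chr1", 9_500, 9_600, "s1", 1.0),
                                    ("chr1", 40_900, 41_000, "s2", 1.0)], ["x"])}
        out = enh.promoter_binding_frequency(sites, genes,
                                             {"grp": ["g1", "g2", "g3", "g4"]})
        assert out.loc[out["factor"] == "AP1", "value"].iloc[0] == 0.5

    def test_matches_brute_force_window_check(self, rng):
        genes = make_genes(self.GENES)
        rows = [("chr1", int(p), int(p) + 50, f"s{i}", 1.0)
                for i, p in enumerate(rng.integers(0, 100_000, 50))]
        sites = {"F": make_peaks(rows, ["x"])}
        out = enh.promoter_binding_frequency(sites, genes,
                                             {"grp": [g[0] for g in self.GENES]})
        expected = 0
        for gid, chrom, start, end, strand, tss in self.GENES:
            lo, hi = tss - 1000, tss + 1000
            if any(c == chrom and s < hi and lo < e for c, s, e, _, _ in rows):
                expected += 1
        assert out.loc[out["factor"] == "F", "value"].iloc[0] == expected / 4

    def test_planted_sites_enrich_subgroup(self):
        genes = make_genes(self.GENES)
        sites = {"F": make_peaks([("chr1", 9_800, 9_900, "s1", 1.0),
                                  ("chr1", 39_800, 39_900, "s2", 1.0)], ["x"])}
        out = enh.promoter_binding_frequency(
            sites, genes, {"all": ["g1", "g2", "g3", "g4"],
                           "planted": ["g1", "g2"]})
        f = out.set_index(["group", "factor"])["value"]
        assert f[("planted", "F")] > f[("all", "F")]

    def test_empty_group_is_error(self):
        genes = make_genes(self.GENES)
        with pytest.raises(ValueError, match="empty"):
            enh.promoter_binding_frequency(
                {"F": make_peaks([], ["x"])}, genes, {"none": []})


class TestStratifyByExpression:
    def _matrix(self):
        vals = np.array([[5.0], [50.0], [500.0]])
        return make_matrix(vals, [("s1", "A")], gene_ids=["lo", "mid", "hi"])

    def test_single_open_stratum_is_whole_group(self):
        out = enh.stratify_by_expression(["lo", "mid", "hi"], self._matrix(),
                                         (0, np.inf))
        assert list(out.values())[0] == ["lo", "mid", "hi"]

    def test_membership_by_arithmetic(self):
        out = enh.stratify_by_expression(["lo", "mid", "hi"], self._matrix(),
                                         (0, 10, 100, np.inf))
        assert out["[0, 10)"] == ["lo"]
        assert out["[10, 100)"] == ["mid"]
        assert out["[100, inf)"] == ["hi"]

    def test_missing_gene_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = enh.stratify_by_expression(["lo", "ghost"], self._matrix(),
                                             (0, np.inf))
        assert out["[0, inf)"] == ["lo"]
        assert "dropped" in caplog.text


class TestProximityEnrichment:
    def test_hand_table_chi_squared(self):
        chi2, p = enh.chi_squared_2x2([[30, 70], [10, 90]])
        assert chi2 == pytest.approx(12.5, abs=1e-9)

    def test_independent_table_is_null(self):
        chi2, p = enh.chi_squared_2x2([[20, 80], [10, 40]])
        assert chi2 == 0.0 and p == 1.0

    def test_small_expected_cell_is_error(self):
        with pytest.raises(ValueError, match="exact test"):
            enh.chi_squared_2x2([[1, 0], [0, 1]])

    def test_nearest_tss_matches_brute_force(self, rng):
        gene_rows = []
        for i in range(60):
            chrom = f"chr{1 + i % 3}"
            tss = int(rng.integers(0, 1_000_000))
            gene_rows.append((f"g{i:02d}", chrom, tss))
        genes = make_genes([(g, c, t, t + 1000, "+", t) for g, c, t in gene_rows])
        peak_rows = random_intervals(rng, 200)
        ps = make_peaks([(c, s, e, f"p{i}", 1.0)
                         for i, (c, s, e) in enumerate(peak_rows)], ["x"])
        got = enh.nearest_tss(ps, genes)
        expected = brute_nearest_tss(peak_rows, gene_rows)
        assert list(got) == expected

    def test_tie_goes_to_smaller_coordinate(self):
        genes = make_genes([("left", "chr1", 1_000, 2_000, "+", 1_000),
                            ("right", "chr1", 3_000, 4_000, "+", 3_000)])
        ps = make_peaks([("chr1", 1_990, 2_010, "mid", 1.0)], ["x"])  # mid 2000
        assert enh.nearest_tss(ps, genes)["mid"] == "left"

    def test_full_pipeline_on_planted_proximity(self, rng):
        # genes on a grid; subset peaks planted near the first 10 genes
        genes = make_genes([(f"g{i:02d}", "chr1", i * 100_000,
                             i * 100_000 + 5_000, "+", i * 100_000)
                            for i in range(40)])
        rows = []
        for i in range(10):  # subset: hug signature TSSs
            rows.append(("chr1", i * 100_000 + 200, i * 100_000 + 400,
                         f"sub{i}", 1.0))
        for i in range(90):  # background scattered
            pos = int(rng.integers(0, 4_000_000))
            rows.append(("chr1", pos, pos + 200, f"bg{i}", 1.0))
        allp = make_peaks(rows, ["x"])
        sub = make_peaks(rows[:10], ["x"])
        res = enh.proximity_enrichment(sub, allp, [f"g{i:02d}" for i in range(10)],
                                       genes)
        assert res["df"] == 1
        assert res["p"] < 0.01
        # chi2 consistent with the closed-form on its own table
        chi2, _ = enh.chi_squared_2x2(res["table"])
        assert res["chi2"] == pytest.approx(chi2, abs=1e-9)


class TestClassifyDigitalAnalog:
    def _matrix(self, rows, gene_ids):
        return make_matrix(np.array(rows, dtype=float),
                           [("r", "ref"), ("t1", "T1"), ("t2", "T2"),
                            ("t3", "T3"), ("t4", "T4")], gene_ids=gene_ids)

    def test_rule_examples(self):
        m = self._matrix([[20, 200, 200, 200, 200],
                          [20, 40, 60, 80, 120],
                          [20, 21, 20, 21, 20]], ["dig", "ana", "flat"])
        out = enh.classify_digital_analog(m, "ref")
        assert out.loc["dig", "label"] == "digital"
        assert out.loc["ana", "label"] == "analog"
        assert out.loc["flat", "label"] == "other"

    def test_zero_reference_uses_pseudocount(self):
        m = self._matrix([[0, 50, 50, 50, 50]], ["g"])
        out = enh.classify_digital_analog(m, "ref")
        assert out.loc["g", "label"] == "digital"

    def test_planted_digital_recovery(self):
        """Digital genes planted above the 4-fold induction threshold are
        recovered at >= 90%."""
        m, tr = syn.generate_expression(
            n_genes=1000,
            class_proportions={"digital": 0.10, "null": 0.90},
            effect_size_range=(5.0, 9.0), seed=13)
        out = enh.classify_digital_analog(m, "no_peptide")
        dig = tr.genes_of("digital")
        rec = (out.loc[dig, "label"] == "digital").mean()
        assert rec >= 0.90
        # null genes are essentially never called digital
        null = tr.genes_of("null")
        assert (out.loc[null, "label"] == "digital").mean() < 0.01
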
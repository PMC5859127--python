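"""Expression units, detection classes, depth arithmetic, intron rates."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from libprep.annotation import RawGeneRecord, build_gene_models, compute_overlap_flags
from libprep.counting import CountTable
from libprep.intervals import GenomicInterval
from libprep.metrics import (
    ExpressionMatrix,
    biotype_gene_fractions,
    biotype_read_fractions,
    compute_cpm,
    compute_rpkm,
    concordance_by_biotype,
    correlation_matrix,
    detection_classes,
    extra_depth_required,
    intron_rate_analysis,
    merge_replicates,
    usable_fraction,
)


class TestRpkmCpm:
    def test_rpkm_formula(self):
        counts = pd.Series({"G": 10})
        lengths = pd.Series({"G": 2000})
        assert compute_rpkm(counts, lengths, 1_000_000)["G"] == pytest.approx(5.0)

    def test_zero_count_zero_rpkm(self):
        assert compute_rpkm(pd.Series({"G": 0}), pd.Series({"G": 500}), 10_000)["G"] == 0

    def test_algebraic_inversion(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        counts = pd.Series(rng.integers(0, 10_000, 50), index=genes, dtype=float)
        lengths = pd.Series(rng.integers(100, 50_000, 50), index=genes)
        lib = 3_456_789.0
        rpkm = compute_rpkm(counts, lengths, lib)
        back = rpkm * (lengths / 1e3) * (lib / 1e6)
        assert np.allclose(back, counts)

    def test_cpm_magnitude_and_normalisation(self):
        counts = pd.Series({"G": 151})
        assert compute_cpm(counts, 1_000_000)["G"] == pytest.approx(151.0)
        rng = np.random.default_rng(2)
        col = pd.Series(rng.integers(1, 100, 20).astype(float))
        cpm = compute_cpm(col, col.sum())
        assert cpm.sum() == pytest.approx(1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            compute_cpm(pd.Series({"G": 1}), 0)


class TestMergeReplicates:
    def make_ct(self):
        genes = ["a", "b"]
        exonic = pd.DataFrame({"s1": [10, 0], "s2": [30, 4]}, index=genes)
        intronic = pd.DataFrame({"s1": [1, 1], "s2": [3, 1]}, index=genes)
        summary = pd.DataFrame(
            {"unique_fragments": [12, 38], "exonic": [10, 34],
             "intronic": [2, 4], "intergenic": [0, 0],
             "total_sequenced_reads": [20, 50]},
            index=["s1", "s2"],
        )
        return CountTable(exonic, intronic, summary)

    def test_singleton_identity(self):
        ct = self.make_ct()
        merged = merge_replicates(ct, {"g1": ["s1"], "g2": ["s2"]})
        assert merged.exonic["g1"].tolist() == ct.exonic["s1"].tolist()

    def test_sums(self):
        ct = self.make_ct()
        merged = merge_replicates(ct, {"g": ["s1", "s2"]})
        assert merged.exonic["g"].tolist() == [40, 4]
        assert merged.summary.loc["g", "total_sequenced_reads"] == 70

    def test_merged_rpkm_equals_pooled_recount(self):
        # RPKM on merged counts == RPKM computed from pooled fragments,
        # since both counts and library sizes add
        ct = self.make_ct()
        merged = merge_replicates(ct, {"g": ["s1", "s2"]})
        lengths = pd.Series({"a": 1000, "b": 2000})
        lib = merged.exonic["g"].sum()
        direct = compute_rpkm(ct.exonic["s1"] + ct.exonic["s2"], lengths, lib)
        via_merge = compute_rpkm(merged.exonic["g"], lengths, lib)
        assert np.allclose(direct, via_merge)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates(self.make_ct(), {"g": []})


class TestDetectionClasses:
    def test_threshold_cases(self):
        pa = pd.Series({"a": 0.2, "b": 0.2, "c": 0.05, "d": 0.05, "e": 0.1})
        rz = pd.Series({"a": 0.2, "b": 0.05, "c": 0.2, "d": 0.05, "e": 0.1})
        det = detection_classes(pa, rz)
        assert det.to_dict() == {"a": "Both", "b": "PolyA", "c": "RiboZ",
                                 "d": "None", "e": "None"}  # strict >

    def test_partition_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(500)]
        pa = pd.Series(rng.exponential(0.2, 500), index=genes)
        rz = pd.Series(rng.exponential(0.2, 500), index=genes)
        det = detection_classes(pa, rz)
        counts = det.value_counts()
        assert counts.sum() == 500
        loop = {"Both": 0, "PolyA": 0, "RiboZ": 0, "None": 0}
        for g in genes:
            if pa[g] > 0.1 and rz[g] > 0.1:
                loop["Both"] += 1
            elif pa[g] > 0.1:
                loop["PolyA"] += 1
            elif rz[g] > 0.1:
                loop["RiboZ"] += 1
            else:
                loop["None"] += 1
        assert counts.reindex(loop).fillna(0).astype(int).to_dict() == loop


class TestBiotypeBreakdowns:
    def test_all_protein_coding(self):
        det = pd.Series({"a": "Both", "b": "Both"})
        cats = pd.Series({"a": "protein-coding", "b": "protein-coding"})
        tab = biotype_gene_fractions(det, cats)
        assert tab.loc["Both", "protein-coding"] == pytest.approx(1.0)

    def test_hand_tally_ten_genes(self):
        genes = [f"g{i}" for i in range(10)]
        cats = pd.Series(
            ["protein-coding"] * 6 + ["lncRNA"] * 2 + ["pseudogene", "small RNA"],
            index=genes,
        )
        counts = pd.DataFrame({"s": [10, 10, 10, 10, 10, 10, 20, 0, 15, 5]},
                              index=genes)
        frac = biotype_read_fractions(counts, cats)
        assert frac.loc["s", "protein-coding"] == pytest.approx(60 / 100)
        assert frac.loc["s", "lncRNA"] == pytest.approx(20 / 100)
        assert frac.loc["s", "pseudogene"] == pytest.approx(15 / 100)
        assert frac.loc["s", "small RNA"] == pytest.approx(5 / 100)
        assert frac.loc["s"].sum() == pytest.approx(1.0)

    def test_gene_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(200)]
        det = pd.Series(rng.choice(["Both", "PolyA", "RiboZ", "None"], 200),
                        index=genes)
        cats = pd.Series(rng.choice(
            ["protein-coding", "lncRNA", "pseudogene", "small RNA", "TCR/BCR"],
            200), index=genes)
        tab = biotype_gene_fractions(det, cats)
        sums = tab.sum(axis=1).dropna()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestDepthArithmetic:
    def test_usable_fraction(self):
        assert usable_fraction(35_500_000, 50_000_000) == pytest.approx(0.71)
        assert usable_fraction(0, 50_000_000) == 0.0
        with pytest.raises(ValueError):
            usable_fraction(1, 0)

    def test_blood_headline(self):
        reported, raw = extra_depth_required(0.71, 0.22)
        assert reported == 220
        assert raw == pytest.approx(222.7, abs=0.05)

    def test_colon_headline(self):
        reported, raw = extra_depth_required(0.70, 0.46)
        assert reported == 50
        assert raw == pytest.approx(52.2, abs=0.05)

    def test_exact_double(self):
        assert extra_depth_required(0.5, 0.25)[1] == pytest.approx(100.0)

    def test_equal_fractions_zero_and_monotone(self):
        for x in (0.1, 0.5, 0.9):
            assert extra_depth_required(x, x)[1] == pytest.approx(0.0)
        raws = [extra_depth_required(0.7, fr)[1] for fr in (0.1, 0.3, 0.5, 0.7)]
        assert raws == sorted(raws, reverse=True)

    def test_zero_riboz_rejected(self):
        with pytest.raises(ValueError):
            extra_depth_required(0.7, 0.0)


def make_expression(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    lib = counts.sum(axis=0)
    return ExpressionMatrix(
        rpkm=compute_rpkm(counts, lengths, lib),
        cpm=compute_cpm(counts, lib),
        library_size=lib,
        library_size_mode="counted",
    )


class TestCorrelation:
    def test_duplicated_sample_r1(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"s1": rng.integers(1, 1000, 50)})
        counts["s2"] = counts["s1"]
        lengths = pd.Series(1000, index=counts.index)
        corr = correlation_matrix(make_expression(counts.astype(float), lengths))
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_scaled_counts_equal_library_r1(self):
        # doubling counts at double library size leaves CPM identical
        rng = np.random.default_rng(5)
        c1 = pd.Series(rng.integers(10, 1000, 40).astype(float))
        counts = pd.DataFrame({"s1": c1, "s2": 2 * c1})
        lengths = pd.Series(1000, index=counts.index)
        corr = correlation_matrix(make_expression(counts, lengths))
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.integers(0, 500, (5, 3)).astype(float),
                              columns=["a", "b", "c"])
        counts += 1  # avoid all-zero filter interactions
        lengths = pd.Series(1000, index=counts.index)
        expr = make_expression(counts, lengths)
        corr = correlation_matrix(expr, rpkm_filter=0.0)
        x = np.log2(expr.cpm["a"] + 1)
        y = np.log2(expr.cpm["b"] + 1)
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert corr.loc["a", "b"] == pytest.approx(manual)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_low_expression_filter_drops_only_everywhere_low(self):
        # gene low in one sample but high in the other must survive the
        # "RPKM < 0.5 across all samples" filter; gene low everywhere must not
        rpkm = pd.DataFrame({"s1": [10.0, 0.1, 0.1], "s2": [10.0, 0.1, 8.0]})
        cpm = pd.DataFrame({"s1": [100.0, 1.0, 1.0], "s2": [100.0, 1.0, 80.0]})
        expr = ExpressionMatrix(rpkm, cpm, cpm.sum(axis=0), "counted")
        corr = correlation_matrix(expr)
        # with gene 1 dropped, two genes remain: correlation defined
        assert corr.shape == (2, 2)
        keep = (expr.rpkm >= 0.5).any(axis=1)
        assert keep.tolist() == [True, False, True]


class TestConcordance:
    def test_identical_inputs(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        cpm = pd.Series(rng.exponential(100, 60), index=genes)
        cats = pd.Series("protein-coding", index=genes)
        tab, flags = concordance_by_biotype(cpm, cpm, cats)
        assert tab.loc["protein-coding", "r"] == pytest.approx(1.0)
        assert flags.sum() == 0

    def test_flagging_formula(self):
        cpm_a = pd.Series({"g1": 0.0, "g2": 50.0})
        cpm_b = pd.Series({"g1": 100.0, "g2": 50.0})
        cats = pd.Series({"g1": "small RNA", "g2": "small RNA"})
        tab, flags = concordance_by_biotype(cpm_a, cpm_b, cats)
        assert bool(flags["g1"]) is True  # |log2(101/1)| ~ 6.7 > 4
        assert bool(flags["g2"]) is False
        assert tab.loc["small RNA", "n_flagged"] == 1

    def test_flags_match_loop_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        a = pd.Series(rng.exponential(50, 300), index=genes)
        b = pd.Series(rng.exponential(50, 300), index=genes)
        cats = pd.Series(rng.choice(["protein-coding", "lncRNA"], 300), index=genes)
        _, flags = concordance_by_biotype(a, b, cats)
        for g in genes:
            expected = abs(np.log2((b[g] + 1) / (a[g] + 1))) > 4
            assert bool(flags[g]) == expected

    def test_empty_category_r_missing(self):
        cpm = pd.Series({"g1": 10.0})
        cats = pd.Series({"g1": "protein-coding"})
        tab, _ = concordance_by_biotype(cpm, cpm, cats)
        assert np.isnan(tab.loc["lncRNA", "r"])


class TestIntronRate:
    def build(self):
        recs = [
            # multi-intron gene, no overlaps
            RawGeneRecord("G1", "protein_coding", "c", "+",
                          [GenomicInterval("c", 0, 100, "+"),
                           GenomicInterval("c", 200, 300, "+"),
                           GenomicInterval("c", 400, 500, "+")]),
            # intron-less gene
            RawGeneRecord("G2", "lincRNA", "c", "+",
                          [GenomicInterval("c", 1000, 1500, "+")]),
            # overlapping pair
            RawGeneRecord("G3", "protein_coding", "c", "+",
                          [GenomicInterval("c", 2000, 2100, "+"),
                           GenomicInterval("c", 2500, 2600, "+")]),
            RawGeneRecord("G4", "miRNA", "c", "+",
                          [GenomicInterval("c", 2200, 2260, "+")]),
        ]
        models, _ = compute_overlap_flags(build_gene_models(recs))
        return {m.gene_id: m for m in models}

    def ct(self, exonic, intronic):
        genes = list(exonic)
        summary = pd.DataFrame({"total_sequenced_reads": [1000]}, index=["s"])
        return CountTable(
            pd.DataFrame({"s": pd.Series(exonic)}),
            pd.DataFrame({"s": pd.Series(intronic)}),
            summary,
        )

    def test_rate_formula_and_filters(self):
        models = self.build()
        ct = self.ct({"G1": 70, "G2": 50, "G3": 10, "G4": 5},
                     {"G1": 30, "G2": 0, "G3": 10, "G4": 0})
        rpkm = pd.DataFrame({"s": {"G1": 5.0, "G2": 5.0, "G3": 5.0, "G4": 5.0}})
        res = intron_rate_analysis(ct, models, rpkm)
        assert res.rates.loc["G1", "s"] == pytest.approx(0.30)
        rec = res.records
        assert not rec.loc["G2", "filter_pass"]  # no introns
        assert not rec.loc["G3", "filter_pass"]  # overlaps G4
        assert not rec.loc["G4", "filter_pass"]
        assert rec.loc["G1", "filter_pass"]

    def test_low_expression_excluded(self):
        models = self.build()
        ct = self.ct({"G1": 70, "G2": 1, "G3": 1, "G4": 1},
                     {"G1": 30, "G2": 0, "G3": 0, "G4": 0})
        rpkm = pd.DataFrame({"s1": {"G1": 5.0, "G2": 5, "G3": 5, "G4": 5},
                             "s2": {"G1": 0.5, "G2": 5, "G3": 5, "G4": 5}})
        res = intron_rate_analysis(ct, models, rpkm)
        assert not res.records.loc["G1", "filter_pass"]  # < 1 RPKM in s2

    def test_rates_bounded(self):
        models = self.build()
        ct = self.ct({"G1": 3, "G2": 5, "G3": 1, "G4": 1},
                     {"G1": 97, "G2": 0, "G3": 0, "G4": 0})
        rpkm = pd.DataFrame({"s": {"G1": 5.0, "G2": 5, "G3": 5, "G4": 5}})
        res = intron_rate_analysis(ct, models, rpkm)
        vals = res.rates.values
        ok = vals[~np.isnan(vals)]
        assert ((ok >= 0) & (ok <= 1)).all()
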
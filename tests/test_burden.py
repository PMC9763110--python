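"""Burden encoding: spans, NDD carrier status, gene and gene-set burden."""

import numpy as np
import pandas as pd
import pytest

from cnvburden import (
    BurdenEncoder,
    carrier_status,
    collapse_isoforms,
    gene_burden,
    genome_span,
    geneset_burden,
    ndd_overlap_fraction,
)
from conftest import make_calls
import oracles


class TestSpans:
    def test_spans_sum_per_type(self, tiny_annotation):
        calls = make_calls(
            [("chrT", 0, 100_000, "DEL"), ("chrT", 400_000, 650_000, "DUP")]
        )
        out = genome_span(calls, tiny_annotation)
        row = out.loc["S1"]
        assert row["span_total_mb"] == pytest.approx(0.35)
        assert row["span_del_mb"] == pytest.approx(0.10)
        assert row["span_dup_mb"] == pytest.approx(0.25)
        assert row["cnv_count"] == 2
        assert row["mean_cnv_length_mb"] == pytest.approx(0.175)

    def test_zero_burden_subject_retained_with_zeros(self, tiny_annotation):
        calls = make_calls([("chrT", 0, 100_000, "DEL")], sample="S1")
        out = genome_span(calls, tiny_annotation, subjects=["S1", "S2"])
        assert out.loc["S2"].eq(0).all()

    def test_ndd_partition_sums_to_type_total(self, tiny_annotation):
        # one DEL overlapping the NDD del region, one elsewhere
        calls = make_calls(
            [("chrT", 120_000, 170_000, "DEL"), ("chrT", 700_000, 760_000, "DEL")]
        )
        row = genome_span(calls, tiny_annotation).loc["S1"]
        assert row["span_ndd_del_mb"] == pytest.approx(0.05)
        assert row["span_nonndd_del_mb"] == pytest.approx(0.06)
        assert row["span_del_mb"] == pytest.approx(
            row["span_ndd_del_mb"] + row["span_nonndd_del_mb"]
        )

    def test_type_must_match_region_for_ndd_attribution(self, tiny_annotation):
        # DUP over the *deletion* NDD region stays non-NDD
        calls = make_calls([("chrT", 120_000, 170_000, "DUP")])
        row = genome_span(calls, tiny_annotation).loc["S1"]
        assert row["span_ndd_dup_mb"] == 0
        assert row["span_nonndd_dup_mb"] == pytest.approx(0.05)

    def test_overlapping_same_type_calls_rejected(self, tiny_annotation):
        calls = make_calls(
            [("chrT", 0, 100_000, "DEL"), ("chrT", 50_000, 150_000, "DEL")]
        )
        with pytest.raises(ValueError, match="overlapping"):
            genome_span(calls, tiny_annotation)

    def test_spans_match_per_basepair_oracle(self, tiny_annotation):
        rng = np.random.default_rng(8)
        rows = []
        pos = 0
        for _ in range(6):
            pos += int(rng.integers(5_000, 30_000))
            ln = int(rng.integers(1_000, 20_000))
            rows.append(("chrT", pos, pos + ln, str(rng.choice(["DEL", "DUP"]))))
            pos += ln + 1_500_000 // 100
        calls = make_calls([r for r in rows if r[2] <= 1_000_000])
        row = genome_span(calls, tiny_annotation).loc["S1"]
        mask = oracles.coverage_mask(calls, 1_000_000)
        assert row["span_total_mb"] == pytest.approx(mask.sum() / 1e6)


class TestCarriers:
    def test_union_overlap_fraction(self, tiny_annotation):
        region = tiny_annotation.ndd_regions.iloc[0]  # [100000, 150000) DEL
        calls = make_calls(
            [("chrT", 100_000, 120_000, "DEL"), ("chrT", 130_000, 150_000, "DEL")]
        )
        assert ndd_overlap_fraction(calls, region) == pytest.approx(0.8)

    def test_no_overlap_and_containment(self, tiny_annotation):
        region = tiny_annotation.ndd_regions.iloc[0]
        assert ndd_overlap_fraction(make_calls([("chrT", 0, 1000, "DEL")]), region) == 0
        covering = make_calls([("chrT", 90_000, 160_000, "DEL")])
        assert ndd_overlap_fraction(covering, region) == 1.0

    def test_wrong_type_call_does_not_count(self, tiny_annotation):
        region = tiny_annotation.ndd_regions.iloc[0]  # DEL region
        calls = make_calls([("chrT", 100_000, 150_000, "DUP")])
        assert ndd_overlap_fraction(calls, region) == 0

    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.8, (1, 1, 0)), (0.5, (1, 1, 0)), (0.0, (0, 0, 0)), (1.0, (1, 1, 1))],
    )
    def test_carrier_rules(self, fraction, expected):
        got = tuple(
            carrier_status(fraction, rule, region_length=100_000)
            for rule in ("gt0", "ge50", "eq100")
        )
        assert got == expected

    def test_eq100_one_basepair_tolerance(self):
        assert carrier_status(1 - 1 / 100_000, "eq100", region_length=100_000) == 1
        assert carrier_status(1 - 10 / 100_000, "eq100", region_length=100_000) == 0

    def test_carrier_monotone_across_rules_on_fixture(self, tiny_annotation):
        rng = np.random.default_rng(6)
        parts = []
        for i in range(30):
            s = int(rng.integers(50_000, 200_000))
            ln = int(rng.integers(5_000, 80_000))
            parts.append(
                make_calls([("chrT", s, s + ln, "DEL")], sample=f"S{i}")
            )
        calls = pd.concat(parts, ignore_index=True)
        enc = BurdenEncoder(tiny_annotation, features=("carriers",))
        out = enc.transform(calls)
        for label in tiny_annotation.ndd_regions["label"]:
            gt0 = out[f"carrier__{label}__gt0"]
            ge50 = out[f"carrier__{label}__ge50"]
            eq100 = out[f"carrier__{label}__eq100"]
            assert (eq100 <= ge50).all() and (ge50 <= gt0).all()


class TestGenes:
    def test_one_basepair_overlap_counts(self, tiny_annotation):
        # GENE2 spans [400000, 420000)
        calls = make_calls([("chrT", 419_999, 450_000, "DUP")])
        out = gene_burden(calls, tiny_annotation, strata=("all",))
        assert out.loc["S1", "gene__GENE2"] == 1

    def test_half_open_abutting_is_no_overlap(self, tiny_annotation):
        calls = make_calls([("chrT", 420_000, 450_000, "DUP")])
        out = gene_burden(calls, tiny_annotation, strata=("all",))
        assert out.loc["S1", "gene__GENE2"] == 0

    def test_isoform_collapse_uses_min_start_max_end(self):
        isoforms = pd.DataFrame(
            [
                ("G", "chr1", 1000, 2000, "NM_1.1"),
                ("G", "chr1", 1500, 3000, "NM_1.2"),
            ],
            columns=["symbol", "chrom", "start", "end", "accession"],
        )
        genes = collapse_isoforms(isoforms)
        assert (genes.loc[0, "start"], genes.loc[0, "end"]) == (1000, 3000)

    def test_non_coding_genes_excluded(self, tiny_annotation):
        # GENE3 has an NR_ accession and must not appear
        cols = gene_burden(
            make_calls([("chrT", 600_000, 640_000, "DEL")]), tiny_annotation
        ).columns
        assert not any("GENE3" in c for c in cols)

    def test_del_dup_strata_separate(self, tiny_annotation):
        calls = make_calls([("chrT", 405_000, 415_000, "DEL")])
        out = gene_burden(calls, tiny_annotation)
        assert out.loc["S1", "gene_del__GENE2"] == 1
        assert out.loc["S1", "gene_dup__GENE2"] == 0
        assert out.loc["S1", "gene__GENE2"] == 1

    def test_indicator_monotone_under_call_extension(self, tiny_annotation):
        short = make_calls([("chrT", 395_000, 405_000, "DEL")])
        long = make_calls([("chrT", 390_000, 430_000, "DEL")])
        g_short = gene_burden(short, tiny_annotation, strata=("all",)).loc["S1"]
        g_long = gene_burden(long, tiny_annotation, strata=("all",)).loc["S1"]
        assert (g_long >= g_short).all()

    def test_indicators_match_exhaustive_scan(self, tiny_annotation):
        rng = np.random.default_rng(13)
        genes = tiny_annotation.genes
        for _ in range(25):
            n = int(rng.integers(1, 6))
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, 950_000))
                ln = int(rng.integers(1_000, 50_000))
                rows.append(("chrT", s, min(s + ln, 1_000_000), "DEL"))
            calls = make_calls(rows)
            calls = calls.drop_duplicates(subset=["start"])  # keep disjointness plausible
            try:
                out = gene_burden(calls, tiny_annotation, strata=("all",))
            except ValueError:
                continue  # overlapping same-type random draw
            got = {g for g in genes["symbol"] if out.loc["S1", f"gene__{g}"] == 1}
            assert got == oracles.genes_hit(calls, genes)


class TestGeneSets:
    def test_count_is_sum_of_member_indicators(self, tiny_annotation):
        ind = pd.DataFrame(
            {"gene__GENE1": [1, 0], "gene__GENE2": [1, 1]}, index=["S1", "S2"]
        )
        counts = geneset_burden(ind, ["GENE1", "GENE2"])
        assert counts.tolist() == [2, 1]

    def test_empty_set_counts_zero(self, tiny_annotation):
        ind = pd.DataFrame({"gene__GENE1": [1]}, index=["S1"])
        assert geneset_burden(ind, []).tolist() == [0]

    def test_singleton_sets_sum_to_total_hits(self, tiny_annotation):
        calls = make_calls(
            [("chrT", 200_000, 230_000, "DEL"), ("chrT", 410_000, 430_000, "DEL")]
        )
        ind = gene_burden(calls, tiny_annotation, strata=("all",))
        total = int(ind.loc["S1"].sum())
        singles = sum(
            int(geneset_burden(ind, [g]).loc["S1"])
            for g in tiny_annotation.genes["symbol"]
        )
        assert singles == total

    def test_encoder_geneset_block(self, tiny_annotation):
        calls = make_calls([("chrT", 200_000, 230_000, "DEL")])  # hits GENE1 only
        enc = BurdenEncoder(tiny_annotation, features=("genes", "genesets"), gene_strata=("all",))
        out = enc.transform(calls)
        assert out.loc["S1", "geneset__setA"] == 1
        assert out.loc["S1", "geneset__setB"] == 0
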
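"""Sample outlier rules, CNV frequency clustering and CNV-level filters."""

import numpy as np
import pandas as pd
import pytest

from cnvburden import (
    CNVCallFilter,
    FilterConfig,
    compute_cnv_frequency,
    filter_cnvs,
    flag_sample_outliers,
)
from cnvburden.qc import chromosome_cnv_fractions
from conftest import make_calls


def _metrics(lrr_values, cohort="c1"):
    # non-focal metrics vary mildly so no other rule fires
    n = len(lrr_values)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "cohort_id": cohort,
            "lrr_sd": lrr_values,
            "baf_sd": np.linspace(0.03, 0.05, n),
            "waviness": np.linspace(0.01, 0.04, n),
            "cnv_count": np.arange(n) % 3,
            "kb_burden": 100.0 + 10.0 * np.arange(n),
        }
    )


class TestSampleOutliers:
    def test_q3_plus_3iqr_cutoff_with_interpolated_quartiles(self):
        # values 1..7 and 100: Q1=2.75, Q3=6.25, IQR=3.5 -> cutoff 16.75
        report = flag_sample_outliers(_metrics([1, 2, 3, 4, 5, 6, 7, 100]))
        failed = report.loc[~report["pass"], "sample_id"].tolist()
        assert failed == ["S7"]
        assert "outlier_lrr_sd" in report.loc[7, "reasons"]

    def test_aneuploidy_rule_over_20_percent_of_chromosome(self):
        metrics = _metrics([0.10, 0.11, 0.12, 0.13, 0.14])
        fractions = pd.DataFrame(
            {"sample_id": ["S0", "S1"], "chrom": "chr2", "fraction": [0.25, 0.19]}
        )
        report = flag_sample_outliers(metrics, fractions)
        assert not report.loc[0, "pass"]
        assert "aneuploidy" in report.loc[0, "reasons"]
        assert report.loc[1, "pass"]

    def test_degenerate_identical_metrics_fail_everyone(self):
        # IQR 0 puts every sample at the cutoff, and the rule is >=
        report = flag_sample_outliers(_metrics([0.1] * 6))
        assert (~report["pass"]).all()

    def test_fewer_than_four_samples_rejected(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            flag_sample_outliers(_metrics([1, 2, 3]))

    def test_genotype_flags_fail_samples(self):
        metrics = _metrics([1, 2, 3, 4])
        metrics["genotype_qc_sex_check"] = [True, False, True, True]
        report = flag_sample_outliers(metrics)
        assert not report.loc[1, "pass"]
        assert "genotype_sex_check" in report.loc[1, "reasons"]

    def test_exclusion_invariant_to_sample_order(self):
        m = _metrics([1, 2, 3, 4, 5, 6, 7, 100])
        shuffled = m.sample(frac=1, random_state=3).reset_index(drop=True)
        r1 = flag_sample_outliers(m).set_index("sample_id")["pass"]
        r2 = flag_sample_outliers(shuffled).set_index("sample_id")["pass"]
        pd.testing.assert_series_equal(r1.sort_index(), r2.sort_index())

    def test_cutoffs_computed_within_cohort(self):
        a = _metrics([1, 2, 3, 4], cohort="c1")
        b = _metrics([100, 101, 102, 103], cohort="c2")
        b["sample_id"] = [f"T{i}" for i in range(4)]
        report = flag_sample_outliers(pd.concat([a, b], ignore_index=True))
        # c2's large values are not outliers within c2
        assert report.loc[report["cohort_id"] == "c2", "pass"].all()


class TestFrequency:
    def test_shared_locus_frequency_counts_distinct_samples(self):
        calls = pd.concat(
            [make_calls([("chr1", 1000, 20_000, "DEL")], sample=f"S{i}") for i in range(3)],
            ignore_index=True,
        )
        freq = compute_cnv_frequency(calls, n_samples=200)
        assert np.allclose(freq, 3 / 200)

    def test_singleton_frequency(self):
        calls = make_calls([("chr1", 1000, 20_000, "DEL")])
        assert np.allclose(compute_cnv_frequency(calls, 200), 1 / 200)

    def test_forty_percent_reciprocal_overlap_keeps_clusters_distinct(self):
        # overlap 40 of 100 for both calls: below the 50% threshold
        calls = pd.concat(
            [
                make_calls([("chr1", 0, 100, "DEL")], sample="S1"),
                make_calls([("chr1", 60, 160, "DEL")], sample="S2"),
            ],
            ignore_index=True,
        )
        freq = compute_cnv_frequency(calls, n_samples=100)
        assert np.allclose(freq, [0.01, 0.01])

    def test_same_interval_opposite_types_not_clustered(self):
        calls = pd.concat(
            [
                make_calls([("chr1", 0, 100, "DEL")], sample="S1"),
                make_calls([("chr1", 0, 100, "DUP")], sample="S2"),
            ],
            ignore_index=True,
        )
        assert np.allclose(compute_cnv_frequency(calls, 100), [0.01, 0.01])

    def test_clusters_match_exhaustive_pairwise_check(self):
        rng = np.random.default_rng(4)
        parts = []
        for i in range(30):
            s = int(rng.integers(0, 80_000))
            ln = int(rng.integers(5_000, 20_000))
            parts.append(make_calls([("chr1", s, s + ln, "DEL")], sample=f"S{i % 10}"))
        calls = pd.concat(parts, ignore_index=True)
        freq = compute_cnv_frequency(calls, n_samples=10)
        # exhaustive single-linkage clustering
        n = len(calls)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                si, ei = calls.loc[i, "start"], calls.loc[i, "end"]
                sj, ej = calls.loc[j, "start"], calls.loc[j, "end"]
                ov = min(ei, ej) - max(si, sj)
                if ov >= 0.5 * (ei - si) and ov >= 0.5 * (ej - sj):
                    adj[i, j] = True
        import networkx as nx  # exercise independent component finder

        comp = list(nx.connected_components(nx.from_numpy_array(adj)))
        expected = np.empty(n)
        for c in comp:
            carriers = calls.loc[sorted(c), "sample_id"].nunique()
            for i in c:
                expected[i] = carriers / 10
        assert np.allclose(freq, expected)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_cnv_frequency(make_calls([("chr1", 0, 100, "DEL")]), 0)


class TestCNVFilters:
    def test_segdup_just_over_half_removed(self, tiny_annotation):
        # segdup track covers [700000, 720000); call of 20000 with 10001 inside
        calls = make_calls([("chrT", 690_000 + 1, 710_002, "DEL")])
        calls["n_probes"] = 20
        kept, report = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 0
        assert report.loc[0, "primary_reason"] == "segdup"

    def test_segdup_exactly_half_retained(self, tiny_annotation):
        calls = make_calls([("chrT", 690_000, 710_000, "DEL")])
        calls["n_probes"] = 20
        kept, _ = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 1

    def test_special_region_half_overlap_removed(self, tiny_annotation):
        # centromere [480000, 520000): call half-covered -> removed (>= rule)
        calls = make_calls([("chrT", 460_000, 500_000, "DEL")])
        calls["n_probes"] = 40
        kept, report = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 0
        assert report.loc[0, "primary_reason"] == "special_region"

    def test_short_call_removed_regardless(self, tiny_annotation):
        calls = make_calls([("chrT", 200_000, 209_999, "DEL")])
        calls["n_probes"] = 100
        kept, report = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 0
        assert "min_length" in report.loc[0, "reasons"]

    def test_clean_call_retained(self, tiny_annotation):
        calls = make_calls([("chrT", 200_000, 210_000, "DEL")])
        calls["n_probes"] = 10
        kept, _ = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 1

    def test_few_probes_removed(self, tiny_annotation):
        calls = make_calls([("chrT", 200_000, 215_000, "DEL")])
        calls["n_probes"] = 9
        kept, report = filter_cnvs(calls, tiny_annotation, n_samples=1000)
        assert len(kept) == 0
        assert "min_probes" in report.loc[0, "reasons"]

    def test_unknown_chromosome_rejected(self, tiny_annotation):
        calls = make_calls([("chrZ", 0, 50_000, "DEL")])
        f = CNVCallFilter(tiny_annotation).fit(calls, n_samples=10)
        with pytest.raises(ValueError, match="chrZ"):
            f.transform(calls)

    def test_reason_completeness_partition(self, small_study, tiny_annotation):
        rng = np.random.default_rng(12)
        parts = []
        for i in range(60):
            s = int(rng.integers(0, 900_000))
            ln = int(rng.integers(5_000, 60_000))
            c = make_calls([("chrT", s, min(s + ln, 1_000_000), "DEL")], sample=f"S{i % 20}")
            c["n_probes"] = int(rng.integers(5, 60))
            parts.append(c)
        calls = pd.concat(parts, ignore_index=True)
        kept, report = filter_cnvs(calls, tiny_annotation, n_samples=2000)
        by_reason = report.loc[~report["pass"], "primary_reason"].value_counts().sum()
        assert len(calls) == len(kept) + by_reason
        assert (report.loc[~report["pass"], "reasons"].str.len() > 0).all()

    def test_filter_monotone_under_tightening(self, tiny_annotation):
        rng = np.random.default_rng(77)
        parts = []
        for i in range(80):
            s = int(rng.integers(0, 900_000))
            ln = int(rng.integers(8_000, 80_000))
            c = make_calls([("chrT", s, min(s + ln, 1_000_000), "DEL")], sample=f"S{i % 8}")
            c["n_probes"] = int(rng.integers(5, 90))
            parts.append(c)
        calls = pd.concat(parts, ignore_index=True)
        base_kept, _ = filter_cnvs(calls, tiny_annotation, n_samples=500)
        tighter = [
            FilterConfig(min_length_bp=20_000),
            FilterConfig(min_probes=20),
            FilterConfig(max_frequency=0.004),
            FilterConfig(segdup_overlap=0.25),
            FilterConfig(special_region_overlap=0.25),
        ]
        for cfg in tighter:
            kept, _ = filter_cnvs(calls, tiny_annotation, n_samples=500, config=cfg)
            assert len(kept) <= len(base_kept)

    def test_track_fraction_matches_per_basepair_oracle(self, tiny_annotation):
        import oracles

        rng = np.random.default_rng(31)
        parts = []
        for i in range(40):
            s = int(rng.integers(0, 950_000))
            ln = int(rng.integers(1_000, 50_000))
            parts.append(make_calls([("chrT", s, min(s + ln, 1_000_000), "DEL")], sample=f"S{i}"))
        calls = pd.concat(parts, ignore_index=True)
        calls["n_probes"] = 50
        f = CNVCallFilter(tiny_annotation).fit(calls, n_samples=10_000)
        f.transform(calls)
        track_mask = oracles.coverage_mask(tiny_annotation.special, 1_000_000)
        for i, r in f.report_.iterrows():
            expected = track_mask[r["start"]: r["end"]].sum() / (r["end"] - r["start"])
            assert abs(r["special_fraction"] - expected) < 1e-12


def test_chromosome_fraction_uses_union_of_calls():
    calls = make_calls(
        [("chr1", 0, 60_000, "DEL"), ("chr1", 40_000, 100_000, "DUP")]
    )
    out = chromosome_cnv_fractions(calls, {"chr1": 1_000_000})
    assert np.allclose(out["fraction"], 0.1)
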
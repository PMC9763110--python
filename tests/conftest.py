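import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from cnvburden import AnnotationBundle, SyntheticConfig, run_pipeline, simulate_study


def make_calls(rows, sample="S1", caller="A"):
    """Hand-built call table from (chrom, start, end, type) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cnv_type"])
    df.insert(0, "sample_id", sample)
    df["n_probes"] = 0
    df["caller"] = caller
    df["confidence"] = np.nan
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@pytest.fixture(scope="session")
def tiny_annotation():
    """A 1 Mb single-chromosome annotation built by hand."""
    chrom_lengths = {"chrT": 1_000_000}
    probes = {"chrT": np.arange(0, 1_000_000, 1_000, dtype=np.int64)}
    special = pd.DataFrame(
        [("chrT", 0, 10_000, "telomere"), ("chrT", 480_000, 520_000, "centromere")],
        columns=["chrom", "start", "end", "name"],
    )
    segdups = pd.DataFrame([("chrT", 700_000, 720_000)], columns=["chrom", "start", "end"])
    ndd = pd.DataFrame(
        [
            ("ndd_del_1", "chrT", 100_000, 150_000, "DEL"),
            ("ndd_dup_1", "chrT", 300_000, 340_000, "DUP"),
        ],
        columns=["label", "chrom", "start", "end", "cnv_type"],
    )
    isoforms = pd.DataFrame(
        [
            ("GENE1", "chrT", 200_000, 210_000, "NM_0001.1"),
            ("GENE1", "chrT", 205_000, 230_000, "NM_0001.2"),
            ("GENE2", "chrT", 400_000, 420_000, "NM_0002.1"),
            ("GENE3", "chrT", 600_000, 640_000, "NR_0003.1"),
        ],
        columns=["symbol", "chrom", "start", "end", "accession"],
    )
    genesets = {"setA": ("neuro", ["GENE1", "GENE2"]), "setB": ("control", ["GENE2"])}
    return AnnotationBundle(
        chrom_lengths=chrom_lengths,
        probes=probes,
        special=special,
        segdups=segdups,
        ndd_regions=ndd,
        isoforms=isoforms,
        genesets=genesets,
    )


@pytest.fixture(scope="session")
def small_study():
    cfg = SyntheticConfig(n_cohorts=3, subjects_per_cohort=150, seed=42)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_result(small_study):
    st = small_study
    return run_pipeline(
        st.callsets, st.qc_metrics, st.subjects, st.annotation,
        ordinal_terms=("span_ndd_del_mb",),
    )
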
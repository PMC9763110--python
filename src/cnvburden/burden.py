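"""Per-subject CNV burden encoding at four genomic scales.

* **Genome-wide span** — total megabases covered by a subject's CNVs,
  stratified by type (deletion/duplication) and by overlap with
  neurodevelopmental-disorder (NDD) CNV regions. A call counts toward the
  NDD stratum if it overlaps any NDD region of matching type by at least one
  basepair; a call is never split between strata, so the NDD / non-NDD spans
  partition the per-type total.
* **NDD carrier status** — per region, the fraction of the region covered by
  the union of the subject's matching-type calls, dichotomised under three
  rules: any overlap (``gt0``), at least half (``ge50``), or complete
  coverage (``eq100``, judged with a 1 bp tolerance).
* **Gene indicators** — 1 if any call overlaps the isoform-collapsed
  protein-coding gene span by >= 1 bp, computed for all calls and for the
  deletion-only and duplication-only strata.
* **Gene-set counts** — the number of a set's member genes overlapped.

Inputs are assumed post-QC and post-annealing, so same-type calls within a
subject are disjoint; overlapping same-type calls are rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import intervals
from .annotation import AnnotationBundle
from .consensus import _encode_keys

__all__ = [
    "BurdenEncoder",
    "genome_span",
    "ndd_overlap_fraction",
    "carrier_status",
    "gene_burden",
    "geneset_burden",
]

CARRIER_RULES = ("gt0", "ge50", "eq100")
MB = 1e-6


def _check_disjoint(calls: pd.DataFrame) -> pd.DataFrame:
    calls = calls.sort_values(["sample_id", "chrom", "cnv_type", "start"]).reset_index(drop=True)
    if len(calls) > 1:
        key = _encode_keys(calls, ("sample_id", "chrom", "cnv_type"))
        s = calls["start"].to_numpy()
        e = calls["end"].to_numpy()
        bad = (key[1:] == key[:-1]) & (s[1:] < e[:-1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                "overlapping same-type calls within a subject (annealing "
                f"postcondition violated), e.g. rows {i} and {i + 1}:\n"
                f"{calls.iloc[i:i + 2]}"
            )
    return calls


def carrier_status(
    fraction: float, rule: str, region_length: int | None = None, tol_bp: int = 1
) -> int:
    """Dichotomise an NDD-region overlap fraction under one overlap rule."""
    if rule == "gt0":
        return int(fraction > 0)
    if rule == "ge50":
        return int(fraction >= 0.5)
    if rule == "eq100":
        if region_length is not None:
            return int(fraction * region_length >= region_length - tol_bp)
        return int(fraction >= 1.0 - 1e-9)
    raise ValueError(f"unknown carrier rule {rule!r}")


def ndd_overlap_fraction(calls: pd.DataFrame, region: pd.Series | dict) -> float:
    """Fraction of one NDD region covered by a subject's matching-type calls."""
    sel = calls[
        (calls["chrom"] == region["chrom"])
        & (calls["cnv_type"] == region["cnv_type"])
    ]
    length = region["end"] - region["start"]
    if not len(sel):
        return 0.0
    k = np.zeros(1, dtype=np.int64)
    cov = intervals.covered_length(
        k,
        np.array([region["start"]]),
        np.array([region["end"]]),
        np.zeros(len(sel), dtype=np.int64),
        sel["start"].to_numpy(),
        sel["end"].to_numpy(),
    )
    return float(cov[0]) / length


class BurdenEncoder(BaseEstimator):
    """Transformer from a post-QC callset to the subject-by-feature matrix.

    Parameters
    ----------
    annotation : AnnotationBundle
        Supplies NDD regions, gene models and gene sets.
    features : tuple of {"spans", "carriers", "genes", "genesets"}
        Which feature blocks to compute (genes/genesets are the expensive
        blocks; simulation loops typically only need spans).
    carrier_rules : tuple
        Overlap rules to encode for every NDD region.
    gene_strata : tuple of {"all", "DEL", "DUP"}
        Call strata for gene indicators and gene-set counts.
    eq100_tol_bp : int
        Basepair tolerance when judging complete coverage of a region.
    """

    def __init__(
        self,
        annotation: AnnotationBundle,
        features: tuple[str, ...] = ("spans", "carriers", "genes", "genesets"),
        carrier_rules: tuple[str, ...] = CARRIER_RULES,
        gene_strata: tuple[str, ...] = ("all", "DEL", "DUP"),
        eq100_tol_bp: int = 1,
    ):
        self.annotation = annotation
        self.features = features
        self.carrier_rules = carrier_rules
        self.gene_strata = gene_strata
        self.eq100_tol_bp = eq100_tol_bp

    def fit(self, calls: pd.DataFrame, y=None):  # stateless
        return self

    def transform(self, calls: pd.DataFrame, subjects=None) -> pd.DataFrame:
        """Encode burden features; rows cover ``subjects`` (zero-filled).

        ``subjects`` defaults to the samples present in ``calls``; passing
        the full analysis roster keeps zero-burden subjects in the matrix.
        """
        calls = _check_disjoint(calls)
        if subjects is None:
            subjects = calls["sample_id"].unique()
        index = pd.Index(pd.unique(pd.Series(subjects)), name="sample_id")
        blocks = []
        if "spans" in self.features:
            blocks.append(self._spans(calls, index))
        if "carriers" in self.features:
            blocks.append(self._carriers(calls, index))
        gene_ind = None
        if "genes" in self.features or "genesets" in self.features:
            gene_ind = self._gene_indicators(calls, index)
        if "genes" in self.features:
            blocks.append(gene_ind)
        if "genesets" in self.features:
            blocks.append(self._geneset_counts(gene_ind))
        out = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=index)
        return out

    # -- feature blocks ----------------------------------------------------

    def _spans(self, calls: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
        ndd = self.annotation.ndd_regions
        out = pd.DataFrame(0.0, index=index, columns=[
            "span_total_mb", "span_del_mb", "span_dup_mb",
            "span_ndd_del_mb", "span_ndd_dup_mb",
            "span_nonndd_del_mb", "span_nonndd_dup_mb",
            "cnv_count", "mean_cnv_length_mb",
        ])
        if not len(calls):
            return out
        length_mb = (calls["end"] - calls["start"]).to_numpy() * MB
        is_ndd = np.zeros(len(calls), dtype=bool)
        for _, r in ndd.iterrows():
            is_ndd |= (
                (calls["chrom"].to_numpy() == r["chrom"])
                & (calls["cnv_type"].to_numpy() == r["cnv_type"])
                & (calls["start"].to_numpy() < r["end"])
                & (calls["end"].to_numpy() > r["start"])
            )
        df = pd.DataFrame(
            {
                "sample_id": calls["sample_id"].to_numpy(),
                "mb": length_mb,
                "is_del": calls["cnv_type"].to_numpy() == "DEL",
                "is_ndd": is_ndd,
            }
        )
        g = df.groupby("sample_id")
        out.loc[g.size().index, "cnv_count"] = g.size().astype(float)
        out.loc[g["mb"].sum().index, "span_total_mb"] = g["mb"].sum()
        out.loc[g["mb"].mean().index, "mean_cnv_length_mb"] = g["mb"].mean()

        def acc(mask: np.ndarray, col: str) -> None:
            sub = df[mask].groupby("sample_id")["mb"].sum()
            out.loc[sub.index, col] = sub

        acc(df["is_del"].to_numpy(), "span_del_mb")
        acc(~df["is_del"].to_numpy(), "span_dup_mb")
        acc((df["is_del"] & df["is_ndd"]).to_numpy(), "span_ndd_del_mb")
        acc((~df["is_del"] & df["is_ndd"]).to_numpy(), "span_ndd_dup_mb")
        acc((df["is_del"] & ~df["is_ndd"]).to_numpy(), "span_nonndd_del_mb")
        acc((~df["is_del"] & ~df["is_ndd"]).to_numpy(), "span_nonndd_dup_mb")
        return out

    def _carriers(self, calls: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
        cols = {}
        for _, r in self.annotation.ndd_regions.iterrows():
            length = int(r["end"] - r["start"])
            sel = calls[
                (calls["chrom"] == r["chrom"])
                & (calls["cnv_type"] == r["cnv_type"])
                & (calls["start"] < r["end"])
                & (calls["end"] > r["start"])
            ]
            covered = pd.Series(0.0, index=index)
            if len(sel):
                clip = (
                    np.minimum(sel["end"].to_numpy(), r["end"])
                    - np.maximum(sel["start"].to_numpy(), r["start"])
                )
                per = pd.DataFrame({"sample_id": sel["sample_id"].to_numpy(), "bp": clip})
                bp = per.groupby("sample_id")["bp"].sum()
                covered.loc[bp.index] = bp
            frac = covered / length
            for rule in self.carrier_rules:
                if rule == "gt0":
                    flag = (frac > 0).astype(int)
                elif rule == "ge50":
                    flag = (frac >= 0.5).astype(int)
                elif rule == "eq100":
                    flag = (covered >= length - self.eq100_tol_bp).astype(int)
                else:
                    raise ValueError(f"unknown carrier rule {rule!r}")
                cols[f"carrier__{r['label']}__{rule}"] = flag
        return pd.DataFrame(cols, index=index)

    def _gene_indicators(self, calls: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
        genes = self.annotation.genes
        codes = self.annotation.chrom_codes()
        strata = {
            "all": ("gene", np.ones(len(calls), dtype=bool)),
            "DEL": ("gene_del", (calls["cnv_type"] == "DEL").to_numpy()),
            "DUP": ("gene_dup", (calls["cnv_type"] == "DUP").to_numpy()),
        }
        gk = genes["chrom"].map(codes).to_numpy(dtype=np.int64)
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        blocks = []
        for name in self.gene_strata:
            prefix, mask = strata[name]
            sub = calls[mask]
            ind = pd.DataFrame(
                0, index=index, columns=[f"{prefix}__{s}" for s in genes["symbol"]]
            )
            if len(sub):
                ck = sub["chrom"].map(codes).to_numpy(dtype=np.int64)
                ci, gi = intervals.pair_overlaps(
                    ck, sub["start"].to_numpy(), sub["end"].to_numpy(), gk, gs, ge
                )
                if len(ci):
                    hits = pd.DataFrame(
                        {
                            "sample_id": sub["sample_id"].to_numpy()[ci],
                            "col": [f"{prefix}__{genes['symbol'].iloc[j]}" for j in gi],
                        }
                    ).drop_duplicates()
                    for sid, col in zip(hits["sample_id"], hits["col"]):
                        ind.at[sid, col] = 1
            blocks.append(ind)
        return pd.concat(blocks, axis=1)

    def _geneset_counts(self, gene_ind: pd.DataFrame) -> pd.DataFrame:
        prefix_map = {"all": ("gene", "geneset"), "DEL": ("gene_del", "geneset_del"), "DUP": ("gene_dup", "geneset_dup")}
        cols = {}
        for stratum in self.gene_strata:
            gprefix, sprefix = prefix_map[stratum]
            for name, (_cat, members) in self.annotation.genesets.items():
                member_cols = [
                    f"{gprefix}__{m}" for m in members if f"{gprefix}__{m}" in gene_ind.columns
                ]
                cols[f"{sprefix}__{name}"] = (
                    gene_ind[member_cols].sum(axis=1) if member_cols else pd.Series(0, index=gene_ind.index)
                )
        return pd.DataFrame(cols, index=gene_ind.index)


# -- thin functional wrappers ----------------------------------------------


def genome_span(
    calls: pd.DataFrame, annotation: AnnotationBundle, subjects=None
) -> pd.DataFrame:
    """Genome-wide span block (megabases) of the burden profile."""
    enc = BurdenEncoder(annotation, features=("spans",))
    return enc.transform(calls, subjects=subjects)


def gene_burden(
    calls: pd.DataFrame, annotation: AnnotationBundle, subjects=None,
    strata: tuple[str, ...] = ("all", "DEL", "DUP"),
) -> pd.DataFrame:
    """Per-gene 0/1 indicators (>=1 bp overlap with collapsed gene span)."""
    enc = BurdenEncoder(annotation, features=("genes",), gene_strata=strata)
    return enc.transform(calls, subjects=subjects)


def geneset_burden(gene_indicators: pd.DataFrame, members: list[str], prefix: str = "gene") -> pd.Series:
    """Number of a set's member genes hit, from an indicator block."""
    cols = [f"{prefix}__{m}" for m in members if f"{prefix}__{m}" in gene_indicators.columns]
    if not cols:
        return pd.Series(0, index=gene_indicators.index)
    return gene_indicators[cols].sum(axis=1)
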
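"""Sample-level outlier exclusion and CNV-level filtering.

Sample QC removes arrays whose quality metrics (log-R-ratio SD, BAF SD,
waviness) or CNV load (call count, kilobase burden) are extreme outliers
within their cohort — at or above Q3 + 3*IQR — plus putative aneuploidies
(>20% of any chromosome covered by CNV) and subjects failing upstream
genotype QC. CNV-level filters then drop calls in artefact-prone sequence
(centromeres, telomeres, Ig/TCR loci, segmental duplications), common calls
(>1% frequency within the data), and calls too short (<10 kb) or supported
by too few probes (<10).

Quartiles use linear interpolation between order statistics (numpy's
default, R type 7); with a degenerate all-equal metric the IQR is 0 and
every sample sits at the cutoff, so the >= rule fails all of them — callers
should treat a zero IQR as a pathological cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import intervals
from .annotation import AnnotationBundle
from .consensus import _encode_keys

__all__ = [
    "FilterConfig",
    "SampleOutlierFilter",
    "CNVCallFilter",
    "flag_sample_outliers",
    "compute_cnv_frequency",
    "filter_cnvs",
    "chromosome_cnv_fractions",
]

OUTLIER_METRICS = ("lrr_sd", "baf_sd", "waviness", "cnv_count", "kb_burden")

#: fixed order used to attribute a single primary exclusion reason
CNV_REASON_ORDER = ("special_region", "segdup", "frequency", "min_length", "min_probes")


@dataclass
class FilterConfig:
    """Thresholds of the sample- and CNV-level filters."""

    iqr_multiplier: float = 3.0
    aneuploidy_fraction: float = 0.20
    special_region_overlap: float = 0.50  # removed when fraction >= this
    segdup_overlap: float = 0.50          # removed when fraction > this
    max_frequency: float = 0.01           # removed when frequency > this
    min_length_bp: int = 10_000           # removed when length < this
    min_probes: int = 10                  # removed when probes < this

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        for name in ("aneuploidy_fraction", "special_region_overlap", "segdup_overlap", "max_frequency"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def chromosome_cnv_fractions(
    calls: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Fraction of each chromosome covered by a sample's CNVs (union of calls).

    Returns a long table (sample_id, chrom, fraction); absent pairs are zero.
    """
    if not len(calls):
        return pd.DataFrame(columns=["sample_id", "chrom", "fraction"])
    key = _encode_keys(calls, ("sample_id", "chrom"))
    mk, ms, me = intervals.merge_keyed(key, calls["start"].to_numpy(), calls["end"].to_numpy())
    cov = pd.DataFrame({"_key": mk, "bases": me - ms}).groupby("_key")["bases"].sum()
    lookup = (
        calls.assign(_key=key)
        .drop_duplicates("_key")
        .set_index("_key")[["sample_id", "chrom"]]
    )
    out = lookup.join(cov).reset_index(drop=True)
    out["fraction"] = out["bases"] / out["chrom"].map(chrom_lengths)
    return out[["sample_id", "chrom", "fraction"]]


class SampleOutlierFilter(BaseEstimator):
    """Cohort-wise Q3 + k*IQR outlier exclusion of samples.

    ``fit`` learns the per-cohort cutoffs from the metric table and builds
    the pass/fail report; ``transform`` drops calls belonging to failed
    samples.

    Attributes
    ----------
    cutoffs_ : DataFrame
        Per cohort and metric, the Q3 + k*IQR exclusion threshold.
    report_ : DataFrame
        One row per sample: pass flag and semicolon-joined failure reasons.
    passed_ : set
        Sample IDs surviving all rules.
    """

    def __init__(self, iqr_multiplier: float = 3.0, aneuploidy_fraction: float = 0.20):
        self.iqr_multiplier = iqr_multiplier
        self.aneuploidy_fraction = aneuploidy_fraction

    def fit(self, metrics: pd.DataFrame, chrom_fractions: pd.DataFrame | None = None):
        if "cohort_id" not in metrics.columns:
            metrics = metrics.assign(cohort_id="all")
        counts = metrics.groupby("cohort_id")["sample_id"].count()
        small = counts[counts < 4]
        if len(small):
            raise ValueError(
                f"quartiles undefined: cohorts with fewer than 4 samples: {dict(small)}"
            )
        present = [m for m in OUTLIER_METRICS if m in metrics.columns]
        cut_rows = []
        reasons = {sid: [] for sid in metrics["sample_id"]}
        for cohort, g in metrics.groupby("cohort_id"):
            for m in present:
                x = g[m].to_numpy(dtype=float)
                q1, q3 = np.quantile(x, [0.25, 0.75])
                cutoff = q3 + self.iqr_multiplier * (q3 - q1)
                cut_rows.append((cohort, m, cutoff))
                for sid in g.loc[g[m] >= cutoff, "sample_id"]:
                    reasons[sid].append(f"outlier_{m}")
        self.cutoffs_ = pd.DataFrame(cut_rows, columns=["cohort_id", "metric", "cutoff"])
        if chrom_fractions is not None and len(chrom_fractions):
            aneu = chrom_fractions.loc[
                chrom_fractions["fraction"] > self.aneuploidy_fraction, "sample_id"
            ].unique()
            for sid in aneu:
                if sid in reasons:
                    reasons[sid].append("aneuploidy")
        flag_cols = [c for c in metrics.columns if c.startswith("genotype_qc_")]
        for c in flag_cols:
            for sid in metrics.loc[~metrics[c].astype(bool), "sample_id"]:
                reasons[sid].append(c.replace("genotype_qc_", "genotype_"))
        self.report_ = pd.DataFrame(
            {
                "sample_id": metrics["sample_id"].to_numpy(),
                "cohort_id": metrics["cohort_id"].to_numpy(),
                "pass": [not reasons[s] for s in metrics["sample_id"]],
                "reasons": [";".join(reasons[s]) for s in metrics["sample_id"]],
            }
        )
        self.passed_ = set(self.report_.loc[self.report_["pass"], "sample_id"])
        return self

    def transform(self, calls: pd.DataFrame) -> pd.DataFrame:
        return calls[calls["sample_id"].isin(self.passed_)].reset_index(drop=True)


def compute_cnv_frequency(
    calls: pd.DataFrame,
    n_samples: int,
    reciprocal_overlap: float = 0.5,
) -> np.ndarray:
    """Within-data frequency of each call's CNV locus.

    Calls are clustered by >=50% reciprocal overlap and identical type
    (single linkage across the whole dataset); a call's frequency is the
    number of distinct samples represented in its cluster divided by the
    total number of analysis samples.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    n = len(calls)
    if n == 0:
        return np.zeros(0)
    key = _encode_keys(calls, ("chrom", "cnv_type"))
    s = calls["start"].to_numpy()
    e = calls["end"].to_numpy()
    ai, bi = intervals.pair_overlaps(key, s, e, key, s, e)
    ov = np.minimum(e[ai], e[bi]) - np.maximum(s[ai], s[bi])
    t = reciprocal_overlap
    recip = (ov >= t * (e[ai] - s[ai])) & (ov >= t * (e[bi] - s[bi]))
    ai, bi = ai[recip], bi[recip]

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(ai.tolist(), bi.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
    cluster = pd.DataFrame({"root": roots, "sample_id": calls["sample_id"].to_numpy()})
    carriers = cluster.groupby("root")["sample_id"].nunique()
    return carriers.loc[roots].to_numpy(dtype=float) / n_samples


class CNVCallFilter(BaseEstimator):
    """CNV-level exclusion filters over the consensus callset.

    ``fit`` computes within-data locus frequencies on the supplied callset
    (the post-consensus, pre-filter analysis set); ``transform`` applies all
    exclusion rules and records per-call reasons in ``report_``.

    Parameters mirror :class:`FilterConfig`; ``annotation`` supplies the
    special-region and segmental-duplication tracks and chromosome bounds.
    """

    def __init__(
        self,
        annotation: AnnotationBundle,
        special_region_overlap: float = 0.50,
        segdup_overlap: float = 0.50,
        max_frequency: float = 0.01,
        min_length_bp: int = 10_000,
        min_probes: int = 10,
        frequency_reciprocal_overlap: float = 0.5,
    ):
        self.annotation = annotation
        self.special_region_overlap = special_region_overlap
        self.segdup_overlap = segdup_overlap
        self.max_frequency = max_frequency
        self.min_length_bp = min_length_bp
        self.min_probes = min_probes
        self.frequency_reciprocal_overlap = frequency_reciprocal_overlap

    def fit(self, calls: pd.DataFrame, n_samples: int | None = None):
        if n_samples is None:
            n_samples = calls["sample_id"].nunique()
        self.n_samples_ = int(n_samples)
        self.frequencies_ = compute_cnv_frequency(
            calls, self.n_samples_, self.frequency_reciprocal_overlap
        )
        self._fit_index = calls.index.to_numpy()
        return self

    def transform(self, calls: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "frequencies_"):
            raise RuntimeError("fit must be called before transform")
        if len(calls) != len(self._fit_index) or not (calls.index.to_numpy() == self._fit_index).all():
            raise ValueError("transform must receive the callset passed to fit")
        ann = self.annotation
        unknown = set(calls["chrom"].unique()) - set(ann.chrom_lengths)
        if unknown:
            raise ValueError(f"calls on chromosomes absent from annotation: {sorted(unknown)}")
        codes = ann.chrom_codes()
        ck = calls["chrom"].map(codes).to_numpy(dtype=np.int64)
        s = calls["start"].to_numpy()
        e = calls["end"].to_numpy()
        length = e - s

        def track_fraction(track: pd.DataFrame) -> np.ndarray:
            if not len(track):
                return np.zeros(len(calls))
            tk = track["chrom"].map(codes).to_numpy(dtype=np.int64)
            cov = intervals.covered_length(
                ck, s, e, tk, track["start"].to_numpy(), track["end"].to_numpy()
            )
            return cov / length

        special_frac = track_fraction(ann.special)
        segdup_frac = track_fraction(ann.segdups)
        fail = {
            "special_region": special_frac >= self.special_region_overlap,
            "segdup": segdup_frac > self.segdup_overlap,
            "frequency": self.frequencies_ > self.max_frequency,
            "min_length": length < self.min_length_bp,
            "min_probes": calls["n_probes"].to_numpy() < self.min_probes,
        }
        any_fail = np.zeros(len(calls), dtype=bool)
        primary = np.full(len(calls), "", dtype=object)
        reason_lists = [[] for _ in range(len(calls))]
        for name in CNV_REASON_ORDER:
            mask = fail[name]
            for i in np.flatnonzero(mask):
                reason_lists[i].append(name)
            primary[mask & ~any_fail] = name
            any_fail |= mask
        self.report_ = pd.DataFrame(
            {
                "sample_id": calls["sample_id"].to_numpy(),
                "chrom": calls["chrom"].to_numpy(),
                "start": s,
                "end": e,
                "cnv_type": calls["cnv_type"].to_numpy(),
                "frequency": self.frequencies_,
                "special_fraction": special_frac,
                "segdup_fraction": segdup_frac,
                "pass": ~any_fail,
                "primary_reason": primary,
                "reasons": [";".join(r) for r in reason_lists],
            }
        )
        self.summary_ = {
            "input_cnvs": len(calls),
            "surviving_cnvs": int((~any_fail).sum()),
            **{f"removed_{k}": int((primary == k).sum()) for k in CNV_REASON_ORDER},
        }
        return calls.loc[~any_fail].reset_index(drop=True)


# -- thin functional wrappers ----------------------------------------------


def flag_sample_outliers(
    metrics: pd.DataFrame,
    chrom_fractions: pd.DataFrame | None = None,
    iqr_multiplier: float = 3.0,
    aneuploidy_fraction: float = 0.20,
) -> pd.DataFrame:
    """Per-sample pass/fail report under the cohort outlier rules."""
    f = SampleOutlierFilter(iqr_multiplier, aneuploidy_fraction)
    f.fit(metrics, chrom_fractions)
    return f.report_


def filter_cnvs(
    calls: pd.DataFrame,
    annotation: AnnotationBundle,
    n_samples: int | None = None,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all CNV-level filters; returns (surviving calls, report)."""
    cfg = config or FilterConfig()
    filt = CNVCallFilter(
        annotation,
        special_region_overlap=cfg.special_region_overlap,
        segdup_overlap=cfg.segdup_overlap,
        max_frequency=cfg.max_frequency,
        min_length_bp=cfg.min_length_bp,
        min_probes=cfg.min_probes,
    )
    filt.fit(calls, n_samples=n_samples)
    kept = filt.transform(calls)
    return kept, filt.report_
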
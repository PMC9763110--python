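"""Dual-caller consensus CNV calling.

Two calling algorithms run on the same array intensities disagree on
boundaries, fragment long events and make private false calls. The consensus
step keeps only copy-number changes supported by both callers at the same
locus with the same direction:

1. *Conflict exclusion* — a gain by one caller that reciprocally overlaps a
   loss by the other (>50% both ways) marks an unreliable locus; both calls
   are dropped.
2. *Intersection* — per sample, chromosome and CNV type, the surviving calls
   are reduced to the basepair runs covered by both callers.
3. *Annealing* — a long CNV fragmented into pieces is re-joined when the gap
   between adjacent same-type pieces is less than 30% of the length of the
   joined event; merging is greedy left-to-right and iterated to a fixed
   point.

Probe counts of derived intervals are re-counted from the probe map rather
than inherited from either caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import intervals
from .io import CALL_COLUMNS, validate_calls

__all__ = [
    "ConsensusCaller",
    "consensus_intersect",
    "resolve_type_conflicts",
    "anneal_fragments",
    "count_probes",
]

_TYPE_CODE = {"DEL": 0, "DUP": 1}


def _encode_keys(df: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    """Dense int64 key per row for a column combination (order-stable)."""
    key = np.zeros(len(df), dtype=np.int64)
    for c in cols:
        if c == "cnv_type":
            codes = df[c].map(_TYPE_CODE).to_numpy(dtype=np.int64)
            n = 2
        else:
            codes, uniques = pd.factorize(df[c], sort=True)
            codes = codes.astype(np.int64)
            n = max(len(uniques), 1)
        key = key * n + codes
    return key


def count_probes(
    calls: pd.DataFrame, probes: dict[str, np.ndarray] | None
) -> np.ndarray:
    """Number of probe positions falling in each call's half-open interval."""
    if probes is None:
        return np.zeros(len(calls), dtype=np.int64)
    out = np.zeros(len(calls), dtype=np.int64)
    for chrom, idx in calls.groupby("chrom", sort=False).indices.items():
        pos = np.asarray(probes.get(chrom, np.empty(0, dtype=np.int64)))
        s = calls["start"].to_numpy()[idx]
        e = calls["end"].to_numpy()[idx]
        out[idx] = np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
    return out


class ConsensusCaller(BaseEstimator):
    """Transformer from a two-caller call table to the consensus callset.

    Parameters
    ----------
    conflict_reciprocal_overlap : float, default 0.5
        Opposite-type calls from different callers overlapping more than this
        fraction of *both* calls are removed from both callsets before
        intersection.
    anneal_gap_fraction : float, default 0.3
        Adjacent same-type consensus calls are merged while
        gap / (merged span) < this fraction.
    anneal : bool, default True
        Whether to run the annealing pass after intersection.
    probes : dict[str, ndarray], optional
        Sorted probe positions per chromosome used to re-count ``n_probes``
        for derived intervals. Without it probe counts are reported as 0.

    Attributes
    ----------
    report_ : dict
        Record counts at each stage and the table of removed conflict pairs.
    """

    def __init__(
        self,
        conflict_reciprocal_overlap: float = 0.5,
        anneal_gap_fraction: float = 0.3,
        anneal: bool = True,
        probes: dict[str, np.ndarray] | None = None,
    ):
        self.conflict_reciprocal_overlap = conflict_reciprocal_overlap
        self.anneal_gap_fraction = anneal_gap_fraction
        self.anneal = anneal
        self.probes = probes

    def fit(self, calls: pd.DataFrame, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, calls: pd.DataFrame) -> pd.DataFrame:
        """Run conflict exclusion, intersection and (optionally) annealing.

        ``calls`` must contain exactly two distinct values in its ``caller``
        column; any number of samples is allowed (all operations are keyed by
        sample).
        """
        validate_calls(calls)
        callers = sorted(calls["caller"].unique()) if len(calls) else []
        if len(callers) > 2:
            raise ValueError(
                f"consensus requires exactly two callers, got {callers}"
            )
        # one caller silent on this input -> nothing is dual-supported
        a = calls[calls["caller"] == callers[0]] if callers else calls
        b = (
            calls[calls["caller"] == callers[1]]
            if len(callers) == 2
            else calls.iloc[0:0]
        )

        a_kept, b_kept, conflicts = self._resolve_conflicts(a, b)
        consensus = self._intersect(a_kept, b_kept, callers)
        n_pre_anneal = len(consensus)
        if self.anneal:
            consensus = self._anneal(consensus)
        consensus["n_probes"] = count_probes(consensus, self.probes)
        self.report_ = {
            "input_calls": len(calls),
            "conflict_pairs_removed": len(conflicts),
            "consensus_calls": n_pre_anneal,
            "annealed_calls": len(consensus),
            "conflicts": conflicts,
        }
        return consensus

    # -- stages ------------------------------------------------------------

    def _resolve_conflicts(self, a: pd.DataFrame, b: pd.DataFrame):
        t = self.conflict_reciprocal_overlap
        if not len(a) or not len(b):
            return a, b, pd.DataFrame(columns=["sample_id", "chrom", "a_start", "a_end", "b_start", "b_end"])
        both = pd.concat([a, b], ignore_index=True)
        key = _encode_keys(both, ("sample_id", "chrom"))
        ka, kb = key[: len(a)], key[len(a):]
        as_, ae = a["start"].to_numpy(), a["end"].to_numpy()
        bs, be = b["start"].to_numpy(), b["end"].to_numpy()
        ai, bi = intervals.pair_overlaps(ka, as_, ae, kb, bs, be)
        opposite = (
            a["cnv_type"].to_numpy()[ai] != b["cnv_type"].to_numpy()[bi]
        )
        ai, bi = ai[opposite], bi[opposite]
        ov = np.minimum(ae[ai], be[bi]) - np.maximum(as_[ai], bs[bi])
        recip = (ov > t * (ae[ai] - as_[ai])) & (ov > t * (be[bi] - bs[bi]))
        ai, bi = ai[recip], bi[recip]
        conflicts = pd.DataFrame(
            {
                "sample_id": a["sample_id"].to_numpy()[ai],
                "chrom": a["chrom"].to_numpy()[ai],
                "a_start": as_[ai],
                "a_end": ae[ai],
                "b_start": bs[bi],
                "b_end": be[bi],
            }
        )
        a_kept = a.drop(a.index[np.unique(ai)]) if len(ai) else a
        b_kept = b.drop(b.index[np.unique(bi)]) if len(bi) else b
        return a_kept, b_kept, conflicts

    def _intersect(self, a: pd.DataFrame, b: pd.DataFrame, callers: list[str]) -> pd.DataFrame:
        cols = ("sample_id", "chrom", "cnv_type")
        both = pd.concat([a[list(cols) + ["start", "end"]], b[list(cols) + ["start", "end"]]], ignore_index=True)
        if not len(both):
            out = both.reindex(columns=CALL_COLUMNS)
            return out.astype({"start": np.int64, "end": np.int64})
        key = _encode_keys(both, cols)
        ka, kb = key[: len(a)], key[len(a):]
        ik, istart, iend = intervals.intersect_keyed(
            ka, a["start"].to_numpy(), a["end"].to_numpy(),
            kb, b["start"].to_numpy(), b["end"].to_numpy(),
        )
        # map keys back to (sample, chrom, type) via a lookup of first occurrence
        lookup = (
            both.assign(_key=key)
            .drop_duplicates("_key")
            .set_index("_key")[list(cols)]
        )
        meta = lookup.loc[ik].reset_index(drop=True)
        out = pd.DataFrame(
            {
                "sample_id": meta["sample_id"],
                "chrom": meta["chrom"],
                "start": istart,
                "end": iend,
                "cnv_type": meta["cnv_type"],
                "n_probes": 0,
                "caller": "+".join(callers),
                "confidence": np.nan,
            }
        )
        return out.sort_values(["sample_id", "chrom", "cnv_type", "start"]).reset_index(drop=True)

    def _anneal(self, calls: pd.DataFrame) -> pd.DataFrame:
        if len(calls) < 2:
            return calls
        calls = calls.sort_values(["sample_id", "chrom", "cnv_type", "start"]).reset_index(drop=True)
        key = _encode_keys(calls, ("sample_id", "chrom", "cnv_type"))
        s = calls["start"].to_numpy()
        e = calls["end"].to_numpy()
        frac = self.anneal_gap_fraction
        # conservative pre-screen: a key can only merge if some adjacent pair
        # is mergeable as-is (merging only ever shrinks later gap fractions)
        same = key[1:] == key[:-1]
        cand = same & ((s[1:] - e[:-1]) < frac * (e[1:] - s[:-1]))
        hot = np.unique(key[:-1][cand])
        if not hot.size:
            return calls
        keep = np.ones(len(calls), dtype=bool)
        hot_set = set(hot.tolist())
        for k, idx in pd.Series(range(len(calls))).groupby(key).groups.items():
            if k not in hot_set:
                continue
            idx = np.asarray(idx)
            ms, me = _anneal_run(s[idx], e[idx], frac)
            keep[idx[len(ms):]] = False
            s[idx[: len(ms)]] = ms
            e[idx[: len(ms)]] = me
        calls = calls.loc[keep].copy()
        calls["start"] = s[keep]
        calls["end"] = e[keep]
        return calls.reset_index(drop=True)


def _anneal_run(starts: np.ndarray, ends: np.ndarray, frac: float) -> tuple[list, list]:
    """Greedy left-to-right annealing of one sorted run, to a fixed point."""
    s, e = list(starts), list(ends)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(s) - 1:
            gap = s[i + 1] - e[i]
            span = e[i + 1] - s[i]
            if gap < frac * span:
                e[i] = max(e[i], e[i + 1])
                del s[i + 1], e[i + 1]
                changed = True
            else:
                i += 1
    return s, e


# -- thin functional wrappers over the estimator ---------------------------


def _check_single_sample(*callsets: pd.DataFrame) -> None:
    samples = set()
    for cs in callsets:
        samples.update(cs["sample_id"].unique())
    if len(samples) > 1:
        raise ValueError(f"mixed-sample callsets: {sorted(samples)}")


def consensus_intersect(
    a: pd.DataFrame, b: pd.DataFrame, probes: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Intersection-only consensus of two single-sample callsets."""
    _check_single_sample(a, b)
    caller = ConsensusCaller(anneal=False, conflict_reciprocal_overlap=1.0, probes=probes)
    # reciprocal threshold 1.0 disables conflict removal: pure intersection
    return caller.transform(pd.concat([a, b], ignore_index=True))


def resolve_type_conflicts(
    a: pd.DataFrame, b: pd.DataFrame, reciprocal_overlap: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove opposite-type reciprocally-overlapping pairs from both callsets."""
    _check_single_sample(a, b)
    caller = ConsensusCaller(conflict_reciprocal_overlap=reciprocal_overlap)
    a_kept, b_kept, conflicts = caller._resolve_conflicts(a, b)
    return a_kept.reset_index(drop=True), b_kept.reset_index(drop=True), conflicts


def anneal_fragments(
    calls: pd.DataFrame,
    gap_fraction: float = 0.3,
    probes: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Anneal adjacent same-type calls per sample/chromosome."""
    caller = ConsensusCaller(anneal_gap_fraction=gap_fraction, probes=probes)
    out = caller._anneal(calls.sort_values(["sample_id", "chrom", "cnv_type", "start"]).reset_index(drop=True))
    out["n_probes"] = count_probes(out, probes)
    return out
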
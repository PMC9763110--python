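"""Independent brute-force oracles used to validate the pipeline.

Everything here is deliberately naive — per-basepair boolean masks, O(n^2)
scans, definitional formulas — and shares no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def coverage_mask(calls: pd.DataFrame, genome_len: int) -> np.ndarray:
    """Boolean per-basepair coverage of a set of [start, end) intervals."""
    mask = np.zeros(genome_len, dtype=bool)
    for _, r in calls.iterrows():
        mask[r["start"]: r["end"]] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) pairs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def consensus_by_masks(a: pd.DataFrame, b: pd.DataFrame, genome_len: int) -> dict:
    """Per-type consensus intervals as AND of the two callers' masks."""
    out = {}
    for t in ("DEL", "DUP"):
        ma = coverage_mask(a[a["cnv_type"] == t], genome_len)
        mb = coverage_mask(b[b["cnv_type"] == t], genome_len)
        out[t] = mask_to_intervals(ma & mb)
    return out


def anneal_by_rule(intervals: list[tuple[int, int]], frac: float = 0.3) -> list[tuple[int, int]]:
    """Direct restatement of the annealing rule on a sorted interval list."""
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(ivs) - 1:
            (s1, e1), (s2, e2) = ivs[i], ivs[i + 1]
            gap = s2 - e1
            span = e2 - s1
            if gap < frac * span:
                ivs[i] = (s1, max(e1, e2))
                del ivs[i + 1]
                changed = True
            else:
                i += 1
    return ivs


def region_overlap_fraction(calls: pd.DataFrame, region_start: int, region_end: int,
                            genome_len: int) -> float:
    """Per-basepair overlap fraction of a region by the calls' union."""
    mask = coverage_mask(calls, genome_len)
    return mask[region_start:region_end].sum() / (region_end - region_start)


def genes_hit(calls: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Exhaustive O(n*m) >=1 bp overlap scan (single chromosome)."""
    hit = set()
    for _, c in calls.iterrows():
        for _, g in genes.iterrows():
            if c["start"] < g["end"] and c["end"] > g["start"]:
                hit.add(g["symbol"])
    return hit


def ivw_closed_form(betas, ses) -> tuple[float, float]:
    w = [1.0 / s**2 for s in ses]
    beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    se = (1.0 / sum(w)) ** 0.5
    return beta, se


def bh_stepup(ps: list[float]) -> list[float]:
    """Definitional BH step-up: q(i) = min_{j >= i} m * p_(j) / j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    qs = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * ps[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        qs[i] = min(1.0, min(candidates))
    return qs


def hc3_se(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Definitional HC3 sandwich: (X'X)^-1 X' diag(e^2/(1-h)^2) X (X'X)^-1."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    H = X @ XtX_inv @ X.T
    h = np.diag(H)
    meat = X.T @ np.diag(e**2 / (1 - h) ** 2) @ X
    cov = XtX_inv @ meat @ XtX_inv
    return np.sqrt(np.diag(cov))


def random_callset(rng: np.random.Generator, n: int, genome_len: int = 100_000,
                   sample: str = "S1", caller: str = "A",
                   max_len: int = 30_000) -> pd.DataFrame:
    lengths = rng.integers(500, max_len, n)
    starts = rng.integers(0, genome_len - lengths, n)
    return pd.DataFrame(
        {
            "sample_id": sample,
            "chrom": "chrT",
            "start": starts,
            "end": starts + lengths,
            "cnv_type": rng.choice(["DEL", "DUP"], n),
            "n_probes": 0,
            "caller": caller,
            "confidence": np.nan,
        }
    )
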
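"""Fixed-effects inverse-variance-weighted meta-analysis and BH-FDR.

Cohort estimates for one term are combined with weights w_i = 1/se_i^2:
beta = sum(w_i b_i)/sum(w_i), se = 1/sqrt(sum(w_i)), z = beta/se, with a
two-sided normal p-value. Odds ratios from ordinal/logistic fits are
meta-analysed on the log-OR scale without rescaling and reported as
exp(beta) with a 95% CI.

Multiple testing is controlled within test *families* — genome-wide span
terms form one family, NDD-region carrier terms one family per overlap
rule, genes one family per type stratum, gene-sets likewise — using the
Benjamini-Hochberg step-up q-value q_(i) = min_{j>=i} m p_(j) / j.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator

__all__ = [
    "InverseVarianceMeta",
    "ivw_meta",
    "meta_or",
    "bh_fdr",
    "assign_family",
    "meta_analyze",
    "cochran_q",
]


def ivw_meta(betas, ses) -> dict:
    """Fixed-effects IVW combination of cohort estimates for one term."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("empty input to meta-analysis")
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * st.norm.sf(abs(z)))
    return {"beta": beta, "se": se, "z": z, "p": max(p, np.nextafter(0, 1)), "k": int(betas.size)}


def meta_or(log_ors, ses) -> dict:
    """IVW meta-analysis on the log-odds-ratio scale, reported as an OR."""
    m = ivw_meta(log_ors, ses)
    m["or"] = float(np.exp(m["beta"]))
    m["or_ci_low"] = float(np.exp(m["beta"] - 1.96 * m["se"]))
    m["or_ci_high"] = float(np.exp(m["beta"] + 1.96 * m["se"]))
    return m


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cochran_q(betas, ses) -> dict:
    """Cochran's heterogeneity Q and its chi-square p-value (optional)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    w = 1.0 / ses**2
    mu = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - mu) ** 2))
    df = max(betas.size - 1, 0)
    p = float(st.chi2.sf(q, df)) if df else 1.0
    return {"Q": q, "df": df, "p": p}


def assign_family(term: str) -> str:
    """Map a burden term name to its multiple-testing family."""
    if term.startswith("span_"):
        return "genomewide_burden"
    if term.startswith("carrier__"):
        rule = term.rsplit("__", 1)[1]
        return f"ndd_regions_{rule}"
    for prefix, fam in [
        ("gene_del__", "genes_del"),
        ("gene_dup__", "genes_dup"),
        ("gene__", "genes_all"),
        ("geneset_del__", "genesets_del"),
        ("geneset_dup__", "genesets_dup"),
        ("geneset__", "genesets_all"),
    ]:
        if term.startswith(prefix):
            return fam
    return "other"


class InverseVarianceMeta(BaseEstimator):
    """Combine cohort-level association results and control FDR per family.

    ``fit`` takes the long results table produced by the association stage
    (columns cohort_id, term, beta, se, p, n, model_family, estimable) and
    produces ``meta_`` with one row per term: the IVW estimate, z, p, and a
    BH q-value computed within the term's test family. Inestimable cohort
    results are excluded (their count is kept per term).

    Parameters
    ----------
    heterogeneity : bool, default False
        Also report Cochran's Q per term.
    or_scale : bool, default False
        Treat betas as log-odds-ratios and add OR columns.
    """

    def __init__(self, heterogeneity: bool = False, or_scale: bool = False):
        self.heterogeneity = heterogeneity
        self.or_scale = or_scale

    def fit(self, results: pd.DataFrame, y=None):
        rows = []
        for term, g in results.groupby("term", sort=True):
            est = g[g["estimable"].astype(bool) & g["se"].gt(0)]
            if not len(est):
                continue
            m = ivw_meta(est["beta"].to_numpy(), est["se"].to_numpy())
            row = {
                "term": term,
                "family": assign_family(term),
                "k": m["k"],
                "n": int(est["n"].sum()),
                "beta": m["beta"],
                "se": m["se"],
                "z": m["z"],
                "p": m["p"],
                "dropped_cohorts": int(len(g) - len(est)),
            }
            if self.or_scale:
                row["or"] = float(np.exp(m["beta"]))
                row["or_ci_low"] = float(np.exp(m["beta"] - 1.96 * m["se"]))
                row["or_ci_high"] = float(np.exp(m["beta"] + 1.96 * m["se"]))
            if self.heterogeneity:
                het = cochran_q(est["beta"].to_numpy(), est["se"].to_numpy())
                row["het_q"] = het["Q"]
                row["het_p"] = het["p"]
            rows.append(row)
        meta = pd.DataFrame(rows)
        if len(meta):
            meta["q"] = np.nan
            for _fam, idx in meta.groupby("family").groups.items():
                meta.loc[idx, "q"] = bh_fdr(meta.loc[idx, "p"].to_numpy())
        self.meta_ = meta
        return self


def meta_analyze(
    results: pd.DataFrame, heterogeneity: bool = False, or_scale: bool = False
) -> pd.DataFrame:
    """One-call wrapper: IVW meta per term plus within-family BH q-values."""
    return InverseVarianceMeta(heterogeneity, or_scale).fit(results).meta_
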
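"""Per-cohort regression of PTSD on CNV burden terms.

Cohorts assessed with a symptom inventory are analysed by linear regression
on the score rescaled to [0, 1] by the instrument's theoretical range (0 =
no symptoms, 1 = theoretical maximum); case/control cohorts use logistic
regression, with the log-odds estimate interpreted as the censored
observation of the same latent symptom scale. Every model adjusts for five
genotype-derived principal components and the per-sample log-R-ratio SD
array-quality metric. Gene-set (enrichment) models additionally adjust for
genome-wide CNV count and mean CNV length, so a set-specific signal must
exceed what global burden alone explains.

Sensitivity fits: HC3 heteroskedasticity-consistent standard errors for the
linear model, and a proportional-odds ordinal logistic fit that yields
odds-ratio effect estimates for score cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "AssociationResult",
    "BurdenRegression",
    "EnrichmentRegression",
    "rescale_phenotype",
    "fit_burden_model",
    "fit_enrichment_model",
    "fit_hc3",
    "fit_ordinal",
    "joint_prs_cnv",
]

DEFAULT_COVARIATES = ("PC1", "PC2", "PC3", "PC4", "PC5", "lrr_sd")
ENRICHMENT_COVARIATES = ("cnv_count", "mean_cnv_length_mb")


@dataclass
class AssociationResult:
    """One cohort-level regression estimate for one burden term."""

    cohort_id: str
    term: str
    beta: float
    se: float
    p: float
    n: int
    model_family: str
    estimable: bool = True
    reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def rescale_phenotype(
    raw, assessment_min: float, assessment_max: float, sample_ids=None
):
    """Rescale raw inventory scores to [0, 1] by the theoretical range."""
    if assessment_max <= assessment_min:
        raise ValueError("assessment_max must exceed assessment_min")
    raw = np.asarray(raw, dtype=float)
    out_of_range = (raw < assessment_min) | (raw > assessment_max)
    if out_of_range.any():
        bad = np.flatnonzero(out_of_range)
        who = (
            [sample_ids[i] for i in bad[:5]]
            if sample_ids is not None
            else bad[:5].tolist()
        )
        raise ValueError(
            f"{out_of_range.sum()} raw scores outside theoretical range "
            f"[{assessment_min}, {assessment_max}], e.g. {who}"
        )
    return (raw - assessment_min) / (assessment_max - assessment_min)


def _design(data: pd.DataFrame, term: str, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [term] + list(covariates)
    X = data[cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    return X, ["const"] + cols


def _fit_one(
    y: np.ndarray,
    data: pd.DataFrame,
    term: str,
    covariates,
    family: str,
    cohort_id: str = "",
) -> AssociationResult:
    n = len(data)
    base = dict(cohort_id=cohort_id, term=term, n=n, model_family=family)
    x = data[term].to_numpy(dtype=float)
    if np.std(x) == 0:
        return AssociationResult(
            **base, beta=np.nan, se=np.nan, p=np.nan,
            estimable=False, reason="zero_variance",
        )
    X, names = _design(data, term, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return AssociationResult(
            **base, beta=np.nan, se=np.nan, p=np.nan,
            estimable=False, reason="collinear",
        )
    try:
        if family == "linear":
            res = sm.OLS(y, X).fit()
        elif family == "linear_hc3":
            h = _leverage(X)
            if np.any(h >= 1 - 1e-12):
                return AssociationResult(
                    **base, beta=np.nan, se=np.nan, p=np.nan,
                    estimable=False, reason="leverage_one_hc3_undefined",
                )
            res = sm.OLS(y, X).fit(cov_type="HC3")
        elif family == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                return AssociationResult(
                    **base, beta=np.nan, se=np.nan, p=np.nan,
                    estimable=False, reason="no_convergence",
                )
        else:
            raise ValueError(f"unknown model family {family!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        return AssociationResult(
            **base, beta=np.nan, se=np.nan, p=np.nan,
            estimable=False, reason=f"fit_failed:{exc}",
        )
    i = names.index(term)
    return AssociationResult(
        **base,
        beta=float(res.params[i]),
        se=float(res.bse[i]),
        p=float(res.pvalues[i]),
    )


def _leverage(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->i", Q, Q)


class BurdenRegression(BaseEstimator):
    """Per-cohort regression of the (rescaled) phenotype on one burden term.

    ``fit`` expects a subject table with columns ``cohort_id``, the burden
    term, the covariates, and either ``phenotype01`` (scores already on the
    0-1 theoretical scale) or ``case`` (0/1) per cohort; the family is
    chosen per cohort unless forced.

    Attributes
    ----------
    results_ : list of AssociationResult, one per cohort.
    """

    def __init__(
        self,
        term: str,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        family: str = "auto",
    ):
        self.term = term
        self.covariates = covariates
        self.family = family

    def _cohort_family(self, g: pd.DataFrame) -> str:
        if self.family != "auto":
            return self.family
        if "phenotype01" in g.columns and g["phenotype01"].notna().all():
            return "linear"
        return "logistic"

    def fit(self, data: pd.DataFrame, y=None):
        results = []
        for cohort, g in data.groupby("cohort_id", sort=True):
            fam = self._cohort_family(g)
            yv = (
                g["phenotype01"].to_numpy(dtype=float)
                if fam.startswith("linear")
                else g["case"].to_numpy(dtype=float)
            )
            results.append(
                _fit_one(yv, g, self.term, self.covariates, fam, cohort_id=str(cohort))
            )
        self.results_ = results
        return self

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results_])


class EnrichmentRegression(BurdenRegression):
    """Gene-set burden regression with global-burden covariates.

    Follows the enrichment-test design: the standard covariates plus
    genome-wide CNV count and mean CNV length, so the gene-set count term is
    tested above and beyond global CNV load.
    """

    def __init__(
        self,
        term: str,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        family: str = "auto",
    ):
        super().__init__(term=term, covariates=covariates, family=family)

    def fit(self, data: pd.DataFrame, y=None):
        full = tuple(self.covariates) + ENRICHMENT_COVARIATES
        inner = BurdenRegression(self.term, full, self.family).fit(data)
        self.results_ = inner.results_
        return self


def fit_burden_model(
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    family: str = "auto",
) -> list[AssociationResult]:
    return BurdenRegression(term, covariates, family).fit(data).results_


def fit_enrichment_model(
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    family: str = "auto",
) -> list[AssociationResult]:
    return EnrichmentRegression(term, covariates, family).fit(data).results_


def fit_hc3(
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Linear fit with HC3 sandwich standard errors (same betas, robust SE)."""
    return BurdenRegression(term, covariates, family="linear_hc3").fit(data).results_


def fit_ordinal(
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    max_levels: int = 50,
) -> list[AssociationResult]:
    """Proportional-odds ordinal logistic fit yielding log-OR estimates.

    Raw score levels are used as ordered categories; with more than
    ``max_levels`` distinct values the scores are decile-binned to bound the
    threshold-parameter count. Cohorts with fewer than 3 distinct levels
    fall back to ordinary logistic regression on a median split (flagged in
    the result's model_family).
    """
    results = []
    for cohort, g in data.groupby("cohort_id", sort=True):
        yraw = (
            g["phenotype01"]
            if "phenotype01" in g.columns and g["phenotype01"].notna().all()
            else g["case"]
        ).to_numpy(dtype=float)
        levels = np.unique(yraw)
        base = dict(cohort_id=str(cohort), term=term, n=len(g))
        if len(levels) < 3:
            res = _fit_one(yraw, g, term, covariates, "logistic", cohort_id=str(cohort))
            res.model_family = "logistic_fallback"
            results.append(res)
            continue
        if len(levels) > max_levels:
            ycat = pd.qcut(yraw, 10, labels=False, duplicates="drop").astype(int)
        else:
            ycat = np.searchsorted(levels, yraw)
        x = g[term].to_numpy(dtype=float)
        if np.std(x) == 0:
            results.append(AssociationResult(
                **base, beta=np.nan, se=np.nan, p=np.nan,
                model_family="ordinal", estimable=False, reason="zero_variance",
            ))
            continue
        cols = [term] + list(covariates)
        X = g[cols].to_numpy(dtype=float)
        try:
            mod = OrderedModel(ycat, X, distr="logit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mod.fit(method="bfgs", disp=0, maxiter=200)
            results.append(AssociationResult(
                **base,
                beta=float(fit.params[0]),
                se=float(fit.bse[0]),
                p=float(fit.pvalues[0]),
                model_family="ordinal",
            ))
        except (np.linalg.LinAlgError, ValueError) as exc:
            results.append(AssociationResult(
                **base, beta=np.nan, se=np.nan, p=np.nan,
                model_family="ordinal", estimable=False, reason=f"fit_failed:{exc}",
            ))
    return results


# -- PRS + CNV joint model -------------------------------------------------


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    res = sm.OLS(y, X).fit()
    return float(res.rsquared), X.shape[1]


def cohen_r2_se(r2: float, n: int, k: int) -> float:
    """Large-sample SE of a squared multiple correlation (Cohen's formula)."""
    r2 = max(r2, 0.0)
    num = 4.0 * r2 * (1.0 - r2) ** 2 * (n - k - 1) ** 2
    den = (n**2 - 1.0) * (n + 3.0)
    return float(np.sqrt(num / den))


def joint_prs_cnv(
    data: pd.DataFrame,
    cnv_term: str = "span_ndd_del_mb",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> dict:
    """Hierarchical variance partition: covariates -> +PRS -> +PRS+CNV.

    PRS is standardised to mean 0 / SD 1 within the analysis sample; subjects
    with missing PRS are dropped (count reported). Returns per-increment
    delta-R^2 with a large-sample (Cohen) SE and a partial-F p-value, plus
    the full-model coefficients for PRS and the CNV term.
    """
    n_missing = int(data["prs"].isna().sum())
    d = data.dropna(subset=["prs"]).copy()
    prs = d["prs"].to_numpy(dtype=float)
    sd = prs.std()
    if sd == 0:
        raise ValueError("PRS has zero variance; cannot standardise")
    d["prs_std"] = (prs - prs.mean()) / sd
    y = d["phenotype01"].to_numpy(dtype=float)
    n = len(d)

    def X_of(cols):
        return np.column_stack([np.ones(n)] + [d[c].to_numpy(dtype=float) for c in cols])

    base_cols = list(covariates)
    r2_base, k_base = _r2(y, X_of(base_cols))
    r2_prs, k_prs = _r2(y, X_of(base_cols + ["prs_std"]))
    r2_full, k_full = _r2(y, X_of(base_cols + ["prs_std", cnv_term]))

    full = sm.OLS(y, X_of(base_cols + ["prs_std", cnv_term])).fit()
    names = ["const"] + base_cols + ["prs_std", cnv_term]

    def increment(r2_small, r2_big, k_small, k_big):
        delta = r2_big - r2_small
        df2 = n - k_big
        f = max(delta, 0.0) / (k_big - k_small) / max((1 - r2_big) / df2, 1e-300)
        p = float(st.f.sf(f, k_big - k_small, df2))
        return {
            "delta_r2": float(delta),
            "se": cohen_r2_se(delta, n, k_big - 1),
            "p": p,
        }

    i_prs = names.index("prs_std")
    i_cnv = names.index(cnv_term)
    return {
        "n": n,
        "n_dropped_missing_prs": n_missing,
        "r2_baseline": r2_base,
        "prs": {
            "beta": float(full.params[i_prs]),
            "se": float(full.bse[i_prs]),
            "p": float(full.pvalues[i_prs]),
        },
        "cnv": {
            "beta": float(full.params[i_cnv]),
            "se": float(full.bse[i_cnv]),
            "p": float(full.pvalues[i_cnv]),
        },
        "delta_r2_prs": increment(r2_base, r2_prs, k_base, k_prs),
        "delta_r2_cnv": increment(r2_prs, r2_full, k_prs, k_full),
    }
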
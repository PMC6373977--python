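"""Phenome scan engine: one regression per derived outcome.

The standardized allele score is the independent variable throughout; the
regression family follows the outcome's data type (linear for rank-
transformed continuous outcomes, logistic for binary, proportional-odds
for ordered, multinomial with a likelihood-ratio test for unordered).
Each model adjusts for the supplied covariates and analyses complete
cases for that outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .phenome import DerivedOutcome

TEST_FOR_TYPE = {
    "continuous": "linear",
    "binary": "logistic",
    "ordered_categorical": "ordered_logistic",
    "unordered_categorical": "multinomial_logistic",
}


@dataclass
class ScanResult:
    outcome_id: str
    data_type: str
    test: str
    estimate: float
    se: float
    p_value: float
    n: int
    exposure_phenotype: bool = False
    degenerate: bool = False
    note: str = ""


def _complete_cases(score, values, covariates):
    s = pd.Series(score).astype(float).reset_index(drop=True)
    y = pd.Series(values).astype(float).reset_index(drop=True)
    C = (
        pd.DataFrame(covariates).reset_index(drop=True)
        if covariates is not None
        else pd.DataFrame(index=s.index)
    )
    mask = s.notna() & y.notna()
    if len(C.columns):
        mask &= C.notna().all(axis=1)
    return s[mask], y[mask], C.loc[mask]


def test_outcome(score, outcome: DerivedOutcome, covariates=None) -> ScanResult:
    """Association test of the score with one derived outcome."""
    s, y, C = _complete_cases(score, outcome.values, covariates)
    n = len(y)
    base = dict(outcome_id=outcome.outcome_id, data_type=outcome.data_type,
                test=TEST_FOR_TYPE[outcome.data_type], n=n,
                exposure_phenotype=outcome.exposure_phenotype)
    if n < 10 or y.nunique() < 2:
        return ScanResult(estimate=np.nan, se=np.nan, p_value=np.nan,
                          degenerate=True, note="degenerate after complete-case filter",
                          **base)
    X = sm.add_constant(pd.concat([s.rename("score"), C], axis=1))
    try:
        if outcome.data_type == "continuous":
            fit = sm.OLS(y, X).fit()
            est, se, p = fit.params["score"], fit.bse["score"], fit.pvalues["score"]
        elif outcome.data_type == "binary":
            fit = sm.Logit(y, X).fit(disp=0)
            est, se, p = fit.params["score"], fit.bse["score"], fit.pvalues["score"]
        elif outcome.data_type == "ordered_categorical":
            Xo = pd.concat([s.rename("score"), C], axis=1)
            fit = OrderedModel(y.astype(int), Xo, distr="logit").fit(method="bfgs", disp=0)
            est, se, p = fit.params["score"], fit.bse["score"], fit.pvalues["score"]
        else:  # multinomial: LR test of the score across all category contrasts
            yc = y.astype(int)
            full = sm.MNLogit(yc, X).fit(disp=0, maxiter=200)
            red = sm.MNLogit(yc, X.drop(columns="score")).fit(disp=0, maxiter=200)
            lr = 2 * (full.llf - red.llf)
            df = yc.nunique() - 1
            p = stats.chi2.sf(max(lr, 0.0), df)
            # report the largest-magnitude per-category score coefficient
            coefs = full.params.loc["score"]
            est = float(coefs.iloc[np.argmax(np.abs(coefs.to_numpy()))])
            se = float(full.bse.loc["score"].iloc[np.argmax(np.abs(coefs.to_numpy()))])
    except Exception as exc:  # non-convergence etc.
        return ScanResult(estimate=np.nan, se=np.nan, p_value=np.nan,
                          degenerate=True, note=f"fit failure: {exc}", **base)
    return ScanResult(estimate=float(est), se=float(se), p_value=float(p), **base)


def run_scan(score, outcomes: list[DerivedOutcome], covariates=None) -> pd.DataFrame:
    """Scan every outcome and return the table ranked by ascending p."""
    if not outcomes:
        raise ValueError("empty outcome set")
    rows = [test_outcome(score, o, covariates).__dict__ for o in outcomes]
    table = pd.DataFrame(rows)
    return table.sort_values(
        "p_value", kind="mergesort", na_position="last"
    ).reset_index(drop=True)


def qq_data(results: pd.DataFrame, category_ids=None) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a QQ plot.

    Expected quantiles are ``-log10(i / (n + 1))`` for rank ``i``. An
    optional id subset restricts the plot to one phenotype category.
    """
    r = results.dropna(subset=["p_value"])
    if category_ids is not None:
        r = r[r["outcome_id"].isin(set(category_ids))]
    if r.empty:
        raise ValueError("no results to plot")
    p = np.sort(r["p_value"].to_numpy())
    n = p.size
    return pd.DataFrame({
        "expected_log10p": -np.log10(np.arange(1, n + 1) / (n + 1)),
        "observed_log10p": -np.log10(np.clip(p, np.finfo(float).tiny, 1.0)),
    })


def bulk_linear_pvalues(score, Y: np.ndarray) -> np.ndarray:
    """Vectorized score-vs-outcome simple linear regression p-values.

    Used for large calibration/FDR simulations where fitting one model per
    column would dominate runtime; equivalent to the linear branch of
    ``test_outcome`` without covariates.
    """
    s = np.asarray(score, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = s.size
    sc = s - s.mean()
    Yc = Y - Y.mean(axis=0)
    sxx = np.sum(sc**2)
    beta = sc @ Yc / sxx
    resid = Yc - np.outer(sc, beta)
    sigma2 = np.sum(resid**2, axis=0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    return 2 * stats.t.sf(np.abs(t), df=n - 2)
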
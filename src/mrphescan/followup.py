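"""One-sample instrumental-variable follow-up for flagged binary outcomes.

The causal effect of the exposure on a binary outcome is estimated with a
two-stage control-function probit (Rivers-Vuong): stage 1 regresses the
exposure on the allele score and covariates by OLS; stage 2 fits a probit
of the outcome on the exposure, the covariates and the stage-1 residual.
Including the residual absorbs the endogenous part of the latent error, so
the exposure coefficient identifies the latent-scale causal effect when
the liability noise conditional on the residual is standard normal.

The probit coefficient is converted to an approximate odds ratio as
``exp(1.6 * beta)`` (the logistic/probit scale factor). A four-item
"worry" score (count of yes answers over the nervousness items, range
0-4) is modelled by ordered logistic regression, and the observational
exposure-outcome association by plain logistic regression for contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

PROBIT_TO_LOGIT = 1.6


@dataclass
class IVProbitResult:
    outcome_id: str
    probit_beta: float
    se: float
    or_approx: float
    or_ci: tuple[float, float]
    n: int
    first_stage_f: float
    instrument_tag: str = "score"
    sample_tag: str = "full"
    scale_tag: str = "per-unit"
    se_method: str = "plugin"


def probit_to_or(probit_beta: float, se: float) -> tuple[float, tuple[float, float]]:
    """Approximate odds ratio exp(1.6*beta) with its Wald 95% CI."""
    or_ = float(np.exp(PROBIT_TO_LOGIT * probit_beta))
    lo = float(np.exp(PROBIT_TO_LOGIT * (probit_beta - 1.96 * se)))
    hi = float(np.exp(PROBIT_TO_LOGIT * (probit_beta + 1.96 * se)))
    return or_, (lo, hi)


def _design(covariates, n):
    if covariates is None:
        return pd.DataFrame(index=pd.RangeIndex(n))
    return pd.DataFrame(covariates).reset_index(drop=True)


def two_stage_probit(
    outcome,
    exposure,
    score,
    covariates=None,
    scale: str = "per-unit",
    se_method: str = "bootstrap",
    bootstrap_reps: int = 500,
    seed: int = 0,
    outcome_id: str = "outcome",
    instrument_tag: str = "score",
    sample_tag: str = "full",
) -> IVProbitResult:
    """Control-function two-stage IV probit.

    ``scale='per-sd'`` divides the exposure by its sample SD first so the
    coefficient is per 1 SD of exposure; the default is per raw unit.
    SEs come from a nonparametric participant bootstrap by default, or the
    stage-2 MLE covariance with ``se_method='plugin'`` (faster; ignores
    first-stage noise).
    """
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    x = pd.Series(exposure).astype(float).reset_index(drop=True)
    s = pd.Series(score).astype(float).reset_index(drop=True)
    C = _design(covariates, len(y))
    mask = y.notna() & x.notna() & s.notna() & (C.notna().all(axis=1) if len(C.columns) else True)
    y, x, s, C = y[mask], x[mask], s[mask], C.loc[mask]
    if set(y.unique()) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if scale == "per-sd":
        x = x / x.std(ddof=1)
    elif scale != "per-unit":
        raise ValueError("scale must be 'per-unit' or 'per-sd'")

    def fit_once(yv, xv, sv, Cv):
        X1 = sm.add_constant(pd.concat([sv.rename("score"), Cv], axis=1))
        st1 = sm.OLS(xv, X1).fit()
        resid = xv - st1.fittedvalues
        X2 = sm.add_constant(
            pd.concat([xv.rename("exposure"), Cv, resid.rename("cf_resid")], axis=1)
        )
        st2 = sm.Probit(yv, X2).fit(disp=0)
        return st1, st2

    st1, st2 = fit_once(y, x, s, C)
    f_stat = float(st1.tvalues["score"] ** 2)
    beta = float(st2.params["exposure"])
    if se_method == "plugin":
        se = float(st2.bse["exposure"])
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(len(y))
        boots = []
        for _ in range(bootstrap_reps):
            b = rng.choice(idx, size=idx.size, replace=True)
            try:
                _, bs2 = fit_once(
                    y.iloc[b].reset_index(drop=True), x.iloc[b].reset_index(drop=True),
                    s.iloc[b].reset_index(drop=True), C.iloc[b].reset_index(drop=True),
                )
                boots.append(float(bs2.params["exposure"]))
            except Exception:  # non-convergence in a resample: skip it
                continue
        if len(boots) < 2:
            raise RuntimeError("bootstrap failed to produce enough fits")
        se = float(np.std(boots, ddof=1))
    else:
        raise ValueError("se_method must be 'bootstrap' or 'plugin'")
    or_, ci = probit_to_or(beta, se)
    return IVProbitResult(
        outcome_id=outcome_id, probit_beta=beta, se=se, or_approx=or_, or_ci=ci,
        n=int(len(y)), first_stage_f=f_stat, instrument_tag=instrument_tag,
        sample_tag=sample_tag, scale_tag=scale, se_method=se_method,
    )


def naive_probit(outcome, exposure, covariates=None) -> tuple[float, float]:
    """Observational (non-IV) probit of outcome on exposure; (beta, se)."""
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    x = pd.Series(exposure).astype(float).reset_index(drop=True)
    C = _design(covariates, len(y))
    X = sm.add_constant(pd.concat([x.rename("exposure"), C], axis=1))
    fit = sm.Probit(y, X).fit(disp=0)
    return float(fit.params["exposure"]), float(fit.bse["exposure"])


def build_worry_score(items: pd.DataFrame) -> pd.Series:
    """Count of 'yes' answers over exactly four binary items, range 0-4.

    Complete-case: any missing component gives a missing score.
    """
    if items.shape[1] != 4:
        raise ValueError("worry score requires exactly 4 binary items")
    vals = items.astype(float)
    bad = ~vals.isin([0.0, 1.0]) & vals.notna()
    if bad.any().any():
        raise ValueError("worry items must be binary 0/1")
    score = vals.sum(axis=1)
    score[vals.isna().any(axis=1)] = np.nan
    return score


def worry_ordered_logistic(worry, score, covariates=None) -> dict:
    """Proportional-odds fit of the worry score on the genetic score."""
    w = pd.Series(worry).reset_index(drop=True)
    s = pd.Series(score).astype(float).reset_index(drop=True)
    C = _design(covariates, len(w))
    mask = w.notna() & s.notna() & (C.notna().all(axis=1) if len(C.columns) else True)
    w, s, C = w[mask], s[mask], C.loc[mask]
    if w.nunique() < 2:
        raise ValueError("worry score must have >= 2 observed levels")
    X = pd.concat([s.rename("score"), C], axis=1)
    fit = OrderedModel(w.astype(int), X, distr="logit").fit(method="bfgs", disp=0)
    return {
        "beta": float(fit.params["score"]),
        "se": float(fit.bse["score"]),
        "p_value": float(fit.pvalues["score"]),
        "n": int(mask.sum()),
    }


def observational_logistic(exposure, outcome, covariates=None) -> dict:
    """Logistic regression OR per unit exposure with 95% CI."""
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    x = pd.Series(exposure).astype(float).reset_index(drop=True)
    C = _design(covariates, len(y))
    mask = y.notna() & x.notna() & (C.notna().all(axis=1) if len(C.columns) else True)
    y, x, C = y[mask], x[mask], C.loc[mask]
    X = sm.add_constant(pd.concat([x.rename("exposure"), C], axis=1))
    fit = sm.Logit(y, X).fit(disp=0)
    b, se = float(fit.params["exposure"]), float(fit.bse["exposure"])
    return {
        "beta": b, "se": se, "or": float(np.exp(b)),
        "or_ci": (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
        "p_value": float(fit.pvalues["exposure"]), "n": int(mask.sum()),
    }


def split_discovery_replication(
    participant_ids, discovery_ids, kinship_pairs=None
) -> tuple[set, set]:
    """Discovery/replication split with relatedness pruning.

    Replication = all participants minus the discovery set minus anyone
    directly related (via ``kinship_pairs``) to a discovery participant.
    Only direct relations are removed, not the transitive closure.
    """
    all_ids = set(participant_ids)
    discovery = set(discovery_ids)
    if not discovery <= all_ids:
        raise ValueError("discovery ids not a subset of cohort")
    related = set()
    for a, b in kinship_pairs or []:
        if a in discovery and b not in discovery:
            related.add(b)
        if b in discovery and a not in discovery:
            related.add(a)
    replication = all_ids - discovery - related
    assert not (replication & discovery)
    return discovery, replication
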
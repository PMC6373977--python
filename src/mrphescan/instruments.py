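"""Weighted allele score construction, instrument strength and per-SNP
association estimates.

The genetic instrument is a weighted sum of effect-allele dosages, the
weights being externally published per-allele effect sizes on the exposure
(in SD units). The raw score is standardized to mean 0, SD 1 before use.
Instrument strength is summarized by the first-stage F statistic of the
exposure regressed on the score; per-SNP exposure and outcome association
estimates feed the two-sample MR estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class SnpPanel:
    """Instrument definition: SNP ids, alleles and published weights."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, other_allele, weight, se_weight

    def __post_init__(self):
        required = {"snp_id", "effect_allele", "other_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("panel weights must be finite")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].astype(str).tolist()

    def subset(self, snp_ids) -> "SnpPanel":
        keep = self.table["snp_id"].astype(str).isin([str(s) for s in snp_ids])
        return SnpPanel(self.table[keep].reset_index(drop=True))

    def drop(self, snp_ids) -> "SnpPanel":
        drop = self.table["snp_id"].astype(str).isin([str(s) for s in snp_ids])
        return SnpPanel(self.table[~drop].reset_index(drop=True))


@dataclass
class FirstStageResult:
    beta: float
    se: float
    ci: tuple[float, float]
    f_statistic: float
    n: int


def harmonize(panel: SnpPanel, local_alleles: pd.DataFrame, strict: bool = True):
    """Orient a panel to the effect/other alleles of a local genotype file.

    ``local_alleles`` has columns ``snp_id, effect_allele, other_allele``
    describing how the dosage matrix is coded. Where the local effect
    allele is the published other allele the SNP is marked for a dosage
    flip (d -> 2 - d). Strand-ambiguous SNPs (A/T, C/G) are flagged and,
    under ``strict``, excluded.

    Returns ``(oriented_panel, flip_mask_by_snp_id, flagged_ids)``.
    """
    loc = local_alleles.set_index(local_alleles["snp_id"].astype(str))
    flips: dict[str, bool] = {}
    flagged: list[str] = []
    keep_rows = []
    for _, row in panel.table.iterrows():
        sid = str(row["snp_id"])
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        if sid not in loc.index:
            raise ValueError(f"SNP {sid} absent from local allele table")
        lea, loa = str(loc.loc[sid, "effect_allele"]), str(loc.loc[sid, "other_allele"])
        if frozenset((ea, oa)) in AMBIGUOUS_PAIRS:
            flagged.append(sid)
            if strict:
                continue
        if (lea, loa) == (ea, oa):
            flips[sid] = False
        elif (lea, loa) == (oa, ea):
            flips[sid] = True
        else:
            raise ValueError(f"SNP {sid}: alleles {lea}/{loa} incompatible with {ea}/{oa}")
        keep_rows.append(row)
    oriented = SnpPanel(pd.DataFrame(keep_rows).reset_index(drop=True))
    return oriented, flips, flagged


def build_allele_score(
    dosages: pd.DataFrame,
    panel: SnpPanel,
    flips: dict[str, bool] | None = None,
    impute_missing: bool = True,
) -> pd.Series:
    """Weighted, standardized allele score.

    raw_i = sum_j w_j * d_ij over the panel SNPs (dosages flipped to the
    published effect allele first); the returned score is standardized to
    sample mean 0 and SD 1. Missing dosages are mean-imputed per SNP.
    """
    snps = panel.snp_ids
    missing_cols = [s for s in snps if s not in dosages.columns]
    if missing_cols:
        raise ValueError(f"dosage matrix lacks SNP columns {missing_cols}")
    D = dosages[snps].astype(float).copy()
    if D.isna().any().any():
        if not impute_missing:
            raise ValueError("missing dosages present and imputation disabled")
        D = D.fillna(D.mean())
    if flips:
        for sid, flip in flips.items():
            if flip and sid in D.columns:
                D[sid] = 2.0 - D[sid]
    w = panel.table.set_index(panel.table["snp_id"].astype(str))["weight"].reindex(snps)
    raw = D.to_numpy() @ w.to_numpy(dtype=float)
    sd = raw.std()  # population SD: mean 0, SD exactly 1 in-sample
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("raw allele score is constant; cannot standardize")
    return pd.Series((raw - raw.mean()) / sd, index=dosages.index, name="score")


def first_stage(score, exposure, covariates=None, weak_f: float = 10.0) -> FirstStageResult:
    """OLS of exposure on the standardized score (plus covariates).

    The F statistic for the score term uses the identity F = t^2 for a
    single regressor; F below ``weak_f`` raises a weak-instrument warning.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(exposure, dtype=float)
    X = pd.DataFrame({"score": s})
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    t = fit.tvalues["score"]
    f_stat = float(t * t)
    if f_stat < weak_f:
        warnings.warn(f"weak instrument: first-stage F = {f_stat:.2f} < {weak_f}")
    lo, hi = fit.conf_int().loc["score"]
    return FirstStageResult(
        beta=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        ci=(float(lo), float(hi)),
        f_statistic=f_stat,
        n=int(fit.nobs),
    )


def iv_wald(score, exposure, outcome) -> tuple[float, float]:
    """One-sample Wald (ratio) IV estimate for a continuous outcome.

    beta = cov(score, outcome) / cov(score, exposure), with the standard
    two-stage least-squares SE based on the structural residual
    ``outcome - beta * exposure``.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    sc, xc, yc = s - s.mean(), x - x.mean(), y - y.mean()
    sx = sc @ xc
    if sx == 0:
        raise ValueError("instrument uncorrelated with exposure")
    beta = float(sc @ yc / sx)
    resid = yc - beta * xc
    sigma2 = resid @ resid / (s.size - 2)
    se = float(np.sqrt(sigma2 * (sc @ sc)) / abs(sx))
    return beta, se


def snp_outcome_assocs(
    dosages: pd.DataFrame,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
) -> pd.DataFrame:
    """Per-SNP association of the outcome with each dosage column.

    Linear regression for continuous outcomes, logistic for binary; each
    model adjusts for the supplied covariates. Returns a table with
    ``snp_id, beta_outcome, se_outcome, n``.
    """
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    if outcome_type == "binary" and y.dropna().nunique() < 2:
        raise ValueError("degenerate binary outcome")
    cov = pd.DataFrame(covariates).reset_index(drop=True) if covariates is not None else None
    rows = []
    for sid in dosages.columns:
        d = dosages[sid].astype(float).reset_index(drop=True)
        X = pd.DataFrame({"dosage": d})
        if cov is not None:
            X = pd.concat([X, cov], axis=1)
        X = sm.add_constant(X)
        mask = y.notna() & X.notna().all(axis=1)
        if outcome_type == "binary":
            fit = sm.Logit(y[mask], X[mask]).fit(disp=0)
        else:
            fit = sm.OLS(y[mask], X[mask]).fit()
        rows.append(
            {"snp_id": str(sid), "beta_outcome": float(fit.params["dosage"]),
             "se_outcome": float(fit.bse["dosage"]), "n": int(mask.sum())}
        )
    return pd.DataFrame(rows)


def summary_stats(panel: SnpPanel, outcome_assocs: pd.DataFrame) -> pd.DataFrame:
    """Align published exposure betas with local outcome betas by snp_id."""
    exp = panel.table[["snp_id", "weight"]].copy()
    exp["snp_id"] = exp["snp_id"].astype(str)
    exp = exp.rename(columns={"weight": "beta_exposure"})
    exp["se_exposure"] = (
        panel.table["se_weight"].to_numpy(dtype=float)
        if "se_weight" in panel.table.columns
        else np.zeros(len(panel.table))
    )
    merged = exp.merge(outcome_assocs, on="snp_id", how="inner")
    if merged.empty:
        raise ValueError("no SNPs shared between panel and outcome associations")
    return merged


def participant_flow(start_n: int, exclusions: list[tuple[str, int]]) -> pd.DataFrame:
    """Sequential exclusion arithmetic with an audit table.

    ``exclusions`` is an ordered list of (reason, count). Returns a table
    with one row per stage and a running remaining-n column.
    """
    if start_n < 0:
        raise ValueError("negative starting count")
    rows = [{"stage": "start", "removed": 0, "remaining": start_n}]
    n = start_n
    for reason, count in exclusions:
        if count < 0 or count > n:
            raise ValueError(f"exclusion {reason!r} ({count}) exceeds remaining {n}")
        n -= count
        rows.append({"stage": reason, "removed": int(count), "remaining": int(n)})
    return pd.DataFrame(rows)
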
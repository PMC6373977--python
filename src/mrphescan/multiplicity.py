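"""Multiple-testing control for a phenome scan.

Three complementary procedures are provided:

* a Bonferroni threshold ``alpha / n_tests``;
* a correlation-based threshold ``alpha / (T + U)`` where ``T`` is the
  effective number of independent tests estimated from the eigenvalue
  spectrum of the phenotype Spearman correlation matrix (Li-Ji estimator)
  and ``U`` is the number of unordered-categorical phenotypes for which a
  rank correlation cannot be computed;
* a rank-based FDR threshold: the largest rank ``k`` such that
  ``p_(k) < alpha * k / n`` defines the p-value cutoff ``alpha * k / n``
  controlling the false discovery rate at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ThresholdSet:
    """All three scan-wide significance thresholds plus their audit inputs."""

    alpha: float
    n_tests: int
    bonferroni_p: float
    fdr_rank_k: int
    fdr_p: float
    t_effective: float | None = None
    n_unordered: int | None = None
    correlation_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "bonferroni_p": self.bonferroni_p,
            "fdr_rank_k": self.fdr_rank_k,
            "fdr_p": self.fdr_p,
            "t_effective": self.t_effective,
            "n_unordered": self.n_unordered,
            "correlation_p": self.correlation_p,
            "notes": list(self.notes),
        }


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def fdr_threshold(
    p_values, alpha: float = 0.05, strict: bool = True
) -> tuple[int, float, np.ndarray]:
    """Rank-based FDR cutoff.

    Sorts p ascending and finds the largest rank ``k`` with
    ``p_(k) < alpha*k/n`` (strict inequality by default; ``strict=False``
    uses ``<=``, the textbook Benjamini-Hochberg step-up). Returns
    ``(k, threshold, discovery_mask)`` where the mask is aligned with the
    input order. With no qualifying rank, ``k=0`` and the threshold falls
    back to ``alpha/n`` (Bonferroni-like convention, no discoveries).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n + 1)
    crit = alpha * ranks / n
    sorted_p = p[order]
    ok = sorted_p < crit if strict else sorted_p <= crit
    if not ok.any():
        return 0, alpha / n, np.zeros(n, dtype=bool)
    k = int(ranks[ok][-1])
    threshold = alpha * k / n
    mask = p < threshold if strict else p <= threshold
    return k, float(threshold), mask


def spearman_matrix(
    outcomes: pd.DataFrame,
    data_types: dict[str, str] | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete Spearman correlation matrix over eligible outcomes.

    Unordered-categorical outcomes (per ``data_types``) are excluded up
    front: a rank correlation is undefined for them. Columns with fewer
    than ``min_pairs`` complete observations against every other column
    are dropped and reported. Returns ``(matrix, excluded_ids)``.
    """
    excluded: list[str] = []
    cols = []
    for c in outcomes.columns:
        if data_types is not None and data_types.get(c) == "unordered_categorical":
            excluded.append(c)
        else:
            cols.append(c)
    if len(cols) < 2:
        raise ValueError("need >= 2 eligible outcomes")
    sub = outcomes[cols].astype(float)
    corr = sub.corr(method="spearman", min_periods=min_pairs)
    # a column whose every off-diagonal entry is NaN has no usable pairs
    bad = [c for c in corr.columns if corr.loc[c].drop(c).isna().all()]
    if bad:
        excluded.extend(bad)
        corr = corr.drop(index=bad, columns=bad)
    np.fill_diagonal(corr.values, 1.0)
    return corr.fillna(0.0), excluded


def effective_tests(corr, method: str = "li-ji") -> float:
    """Effective number of independent tests from a correlation matrix.

    ``li-ji``: sum over eigenvalue magnitudes of
    ``1(|lambda| >= 1) + (|lambda| - floor(|lambda|))``; equals the matrix
    dimension for the identity and 1 for a rank-one all-ones matrix.
    ``nyholt``: ``1 + (M-1) * (1 - var(lambda)/M)``.
    """
    m = np.asarray(corr, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh((m + m.T) / 2.0)
    if method == "li-ji":
        a = np.abs(lam)
        t = float(np.sum((a >= 1).astype(float) + (a - np.floor(a))))
    elif method == "nyholt":
        M = m.shape[0]
        t = float(1 + (M - 1) * (1 - np.var(lam, ddof=1) / M))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(max(t, 1.0), m.shape[0]))


def correlation_threshold(t_effective: float, n_unordered: int, alpha: float = 0.05) -> float:
    """Threshold ``alpha / (T + U)`` with ``U`` unordered phenotypes."""
    if t_effective < 1:
        raise ValueError("t_effective must be >= 1")
    if n_unordered < 0:
        raise ValueError("n_unordered must be >= 0")
    return alpha / (t_effective + n_unordered)


def threshold_set(
    p_values,
    alpha: float = 0.05,
    t_effective: float | None = None,
    n_unordered: int | None = None,
    strict: bool = True,
) -> ThresholdSet:
    """Bundle all three thresholds computed on one scan's p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    k, fdr_p, _ = fdr_threshold(p, alpha, strict=strict)
    ts = ThresholdSet(
        alpha=alpha,
        n_tests=n,
        bonferroni_p=bonferroni_threshold(alpha, n),
        fdr_rank_k=k,
        fdr_p=fdr_p,
    )
    if k == 0:
        ts.notes.append("no rank satisfied the FDR condition; threshold set to alpha/n")
    if t_effective is not None:
        ts.t_effective = float(t_effective)
        ts.n_unordered = int(n_unordered or 0)
        ts.correlation_p = correlation_threshold(t_effective, ts.n_unordered, alpha)
    return ts
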
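"""Two-sample Mendelian randomization estimators and diagnostics.

Inputs are per-SNP summary statistics: the SNP-exposure association
``beta_exposure`` (with ``se_exposure``) from an external GWAS and the
SNP-outcome association ``beta_outcome`` (with ``se_outcome``) estimated in
the analysis sample. The suite covers:

* per-SNP Wald ratios with first-order delta-method SEs;
* inverse-variance weighted (IVW) estimate, with a multiplicative
  random-effects SE inflation when the heterogeneity Q exceeds its df;
* MR-Egger regression (slope = causal effect, intercept = directional
  pleiotropy test), valid under InSIDE;
* the I2GX regression-dilution diagnostic for the NOME assumption, and a
  SIMEX-corrected Egger slope (simulate extra exposure-side error at
  multipliers lambda, extrapolate back to lambda = -1);
* the weighted median (consistent while <50% of weight is invalid) and the
  simple/weighted mode-based estimator (consistent under ZEMPA), both with
  parametric-bootstrap SEs; the mode's kernel bandwidth is a modified
  Silverman rule scaled by the smoothing parameter phi;
* a two-instrument heterogeneity z-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    n_snps: int
    ci_95: tuple[float, float] | None = None
    p_value: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    i2gx: float | None = None
    phi: float | None = None
    bootstrap_reps: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_95 is None:
            self.ci_95 = (self.beta - Z95 * self.se, self.beta + Z95 * self.se)
        if self.p_value is None and self.se > 0:
            self.p_value = 2 * stats.norm.sf(abs(self.beta / self.se))


@dataclass
class SimexConfig:
    lambda_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    reps_per_lambda: int = 1000
    extrapolant: str = "quadratic"
    seed: int = 0

    def __post_init__(self):
        if 0.0 not in self.lambda_grid:
            raise ValueError("lambda grid must contain 0")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be non-negative")


def _arrays(stats_table: pd.DataFrame):
    bx = stats_table["beta_exposure"].to_numpy(dtype=float)
    sx = stats_table["se_exposure"].to_numpy(dtype=float)
    by = stats_table["beta_outcome"].to_numpy(dtype=float)
    sy = stats_table["se_outcome"].to_numpy(dtype=float)
    return bx, sx, by, sy


def ratio_estimates(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_out/beta_exp with first-order SEs."""
    bx, _, by, sy = _arrays(stats_table)
    if bx.size < 1:
        raise ValueError("need at least one SNP")
    if np.any(bx == 0):
        raise ValueError("zero SNP-exposure beta; Wald ratio undefined")
    out = pd.DataFrame(
        {"ratio": by / bx, "se_ratio": sy / np.abs(bx)},
        index=stats_table.index,
    )
    if "snp_id" in stats_table.columns:
        out.insert(0, "snp_id", stats_table["snp_id"].values)
    return out


def ivw(stats_table: pd.DataFrame, random_effects: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate.

    Zero-intercept WLS of beta_outcome on beta_exposure with weights
    1/se_outcome^2. When heterogeneity Q exceeds its df the SE is scaled
    by sqrt(Q/df) (multiplicative random effects).
    """
    bx, _, by, sy = _arrays(stats_table)
    L = bx.size
    if L < 2:
        raise ValueError("IVW requires >= 2 SNPs")
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = L - 1
    scale = np.sqrt(q / df) if (random_effects and df > 0 and q > df) else 1.0
    return MREstimate(
        method="ivw", beta=beta, se=se * scale, n_snps=L,
        diagnostics={"Q": q, "Q_df": df, "re_scale": float(scale)},
    )


def _egger_wls(bx, by, w):
    """Closed-form WLS of by on bx with intercept, weights w."""
    sw = np.sum(w)
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    slope = np.sum(w * (bx - mx) * (by - my)) / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    df = bx.size - 2
    # multiplicative random-effects scale, floored at 1
    sigma2 = max(np.sum(w * resid**2) / df, 1.0) if df > 0 else 1.0
    se_slope = np.sqrt(sigma2 / sxx)
    se_int = np.sqrt(sigma2 * (1.0 / sw + mx**2 / sxx))
    return slope, intercept, se_slope, se_int


def egger(stats_table: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: WLS with intercept, weights 1/se_outcome^2.

    SNPs are oriented so every beta_exposure is positive (outcome beta sign
    flipped along with it); the intercept estimates the average directional
    pleiotropic effect and its test is the Egger intercept test.
    """
    bx, _, by, sy = _arrays(stats_table)
    L = bx.size
    if L < 3:
        raise ValueError("MR-Egger requires >= 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    slope, intercept, se_slope, se_int = _egger_wls(bx, by, w)
    ip = 2 * stats.norm.sf(abs(intercept / se_int)) if se_int > 0 else np.nan
    return MREstimate(
        method="egger", beta=float(slope), se=float(se_slope), n_snps=L,
        intercept=float(intercept), intercept_se=float(se_int), intercept_p=float(ip),
    )


def i2gx(stats_table: pd.DataFrame) -> float:
    """Regression-dilution diagnostic for the NOME assumption.

    Q_GX is the inverse-variance weighted heterogeneity of the SNP-exposure
    betas; I2GX = max(0, (Q_GX - (L-1)) / Q_GX), in [0, 1]. Values below
    0.9 flag Egger estimates as attenuated by exposure-side error.
    """
    bx, sx, _, _ = _arrays(stats_table)
    L = bx.size
    if L < 2:
        raise ValueError("I2GX requires >= 2 SNPs")
    if np.any(sx <= 0):
        return 1.0  # error-free exposure betas: NOME holds exactly
    w = 1.0 / sx**2
    mu = np.sum(w * bx) / np.sum(w)
    q = np.sum(w * (bx - mu) ** 2)
    if q <= 0:
        return 0.0
    return float(min(max((q - (L - 1)) / q, 0.0), 1.0))


def egger_simex(stats_table: pd.DataFrame, config: SimexConfig | None = None) -> MREstimate:
    """SIMEX-corrected MR-Egger slope.

    For each lambda > 0, exposure betas are perturbed with
    N(0, lambda * se_exposure^2) noise ``reps_per_lambda`` times and the
    mean Egger slope recorded; a polynomial (quadratic by default) in
    lambda is fitted through the mean slopes (lambda = 0 being the plain
    Egger fit) and evaluated at lambda = -1, the error-free limit. The SE
    reported is the plain Egger SE (documented approximation).
    """
    cfg = config or SimexConfig()
    if cfg.reps_per_lambda < 2:
        raise ValueError("reps_per_lambda must be >= 2")
    base = egger(stats_table)
    bx, sx, by, sy = _arrays(stats_table)
    rng = np.random.default_rng(cfg.seed)
    lambdas = sorted(cfg.lambda_grid)
    means = []
    for lam in lambdas:
        if lam == 0:
            means.append(base.beta)
            continue
        slopes = np.empty(cfg.reps_per_lambda)
        for r in range(cfg.reps_per_lambda):
            bxp = bx + rng.normal(0.0, np.sqrt(lam) * sx)
            flip = np.sign(bxp)
            flip[flip == 0] = 1.0
            s, _, _, _ = _egger_wls(bxp * flip, by * flip, 1.0 / sy**2)
            slopes[r] = s
        means.append(float(slopes.mean()))
    beta = simex_extrapolate(lambdas, means, cfg.extrapolant)
    return MREstimate(
        method="egger-simex", beta=beta, se=base.se, n_snps=base.n_snps,
        intercept=base.intercept, intercept_se=base.intercept_se,
        diagnostics={"lambda_grid": lambdas, "mean_slopes": means,
                     "extrapolant": cfg.extrapolant},
    )


def simex_extrapolate(lambdas, mean_slopes, extrapolant: str = "quadratic") -> float:
    """Fit the extrapolant through (lambda, mean slope) points, read off -1."""
    lambdas = np.asarray(lambdas, dtype=float)
    deg = 2 if extrapolant == "quadratic" else 1
    deg = min(deg, lambdas.size - 1)
    coefs = np.polyfit(lambdas, np.asarray(mean_slopes, dtype=float), deg)
    return float(np.polyval(coefs, -1.0))


def _weighted_median_point(b, w):
    order = np.argsort(b)
    b, w = b[order], w[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight per order statistic
    if 0.5 <= cum[0]:
        return float(b[0])
    if 0.5 >= cum[-1]:
        return float(b[-1])
    return float(np.interp(0.5, cum, b))


def weighted_median(
    stats_table: pd.DataFrame, bootstrap_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios, inverse-variance weighted.

    Consistent when valid instruments carry more than half the weight. SE
    by parametric bootstrap: resample each beta from its normal and
    recompute the weighted median.
    """
    bx, sx, by, sy = _arrays(stats_table)
    if bx.size < 3:
        raise ValueError("weighted median requires >= 3 SNPs")
    r = ratio_estimates(stats_table)
    w = 1.0 / r["se_ratio"].to_numpy() ** 2
    if not np.any(w > 0):
        raise ValueError("all weights zero")
    beta = _weighted_median_point(r["ratio"].to_numpy(), w)
    rng = np.random.default_rng(seed)
    boots = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        bxs = rng.normal(bx, sx) if np.any(sx > 0) else bx
        bys = rng.normal(by, sy)
        rb = bys / bxs
        wb = 1.0 / (sy / np.abs(bxs)) ** 2
        boots[i] = _weighted_median_point(rb, wb)
    return MREstimate(
        method="weighted-median", beta=beta, se=float(boots.std(ddof=1)),
        n_snps=bx.size, bootstrap_reps=bootstrap_reps,
    )


def _silverman_bandwidth(b):
    s = np.std(b, ddof=1)
    iqr = np.subtract(*np.percentile(b, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    if spread == 0:
        spread = max(abs(np.mean(b)), 1.0) * 1e-6
    return 0.9 * spread * b.size ** (-0.2)


def _mbe_point(b, w, phi, grid_points=10000):
    h = phi * _silverman_bandwidth(b)
    s = np.std(b, ddof=1)
    span = 5 * s if s > 0 else max(5 * h, 1e-6)
    grid = np.linspace(b.mean() - span, b.mean() + span, grid_points)
    t = (grid[:, None] - b[None, :]) / h
    dens = (w[None, :] * np.exp(-0.5 * t * t)).sum(axis=1)  # unnormalized kernel
    return float(grid[int(np.argmax(dens))])  # argmax ties -> smallest grid value


def mode_based_estimate(
    stats_table: pd.DataFrame,
    phi: float = 0.75,
    weighted: bool = False,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    grid_points: int = 10000,
) -> MREstimate:
    """Mode of the smoothed density of the per-SNP Wald ratios.

    A Gaussian kernel density over the ratio estimates (inverse-variance
    weighted in the weighted variant) is evaluated on a fine grid spanning
    mean +/- 5 SD; the estimate is the density argmax. The bandwidth is
    ``phi`` times a modified Silverman rule. Consistent under ZEMPA: the
    largest homogeneous subset of instruments must be valid. SE by
    parametric bootstrap.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    bx, sx, by, sy = _arrays(stats_table)
    if bx.size < 3:
        raise ValueError("mode-based estimator requires >= 3 SNPs")
    r = ratio_estimates(stats_table)
    b = r["ratio"].to_numpy()
    w = 1.0 / r["se_ratio"].to_numpy() ** 2 if weighted else np.ones_like(b)
    w = w / w.sum()
    beta = _mbe_point(b, w, phi, grid_points)
    rng = np.random.default_rng(seed)
    boots = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        bxs = rng.normal(bx, sx) if np.any(sx > 0) else bx
        bys = rng.normal(by, sy)
        bb = bys / bxs
        wb = 1.0 / (sy / np.abs(bxs)) ** 2 if weighted else np.ones_like(bb)
        boots[i] = _mbe_point(bb, wb / wb.sum(), phi, grid_points)
    label = "weighted-mbe" if weighted else "simple-mbe"
    return MREstimate(
        method=label, beta=beta, se=float(boots.std(ddof=1)), n_snps=bx.size,
        phi=phi, bootstrap_reps=bootstrap_reps,
    )


def mbe_density_curves(
    stats_table: pd.DataFrame, phis=(0.5, 0.75, 1.0), weighted: bool = False,
    grid_points: int = 1000,
) -> pd.DataFrame:
    """Smoothed ratio-estimate densities for a range of phi (diagnostic)."""
    r = ratio_estimates(stats_table)
    b = r["ratio"].to_numpy()
    w = 1.0 / r["se_ratio"].to_numpy() ** 2 if weighted else np.ones_like(b)
    w = w / w.sum()
    s = np.std(b, ddof=1)
    grid = np.linspace(b.mean() - 5 * s, b.mean() + 5 * s, grid_points)
    frames = []
    for phi in phis:
        h = phi * _silverman_bandwidth(b)
        dens = (w[None, :] * stats.norm.pdf((grid[:, None] - b[None, :]) / h)).sum(axis=1) / h
        frames.append(pd.DataFrame({"phi": phi, "x": grid, "density": dens}))
    return pd.concat(frames, ignore_index=True)


def instrument_heterogeneity(est_a: MREstimate, est_b: MREstimate) -> float:
    """Two-sided z-test comparing estimates from disjoint instruments."""
    denom = np.sqrt(est_a.se**2 + est_b.se**2)
    if denom == 0:
        raise ValueError("zero combined SE")
    z = (est_a.beta - est_b.beta) / denom
    return float(2 * stats.norm.sf(abs(z)))


def run_suite(
    stats_table: pd.DataFrame,
    phi: float = 0.75,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    simex_config: SimexConfig | None = None,
) -> pd.DataFrame:
    """All estimators on one summary-statistics table, one row per method."""
    ests = [
        ivw(stats_table),
        egger(stats_table),
        egger_simex(stats_table, simex_config or SimexConfig(seed=seed)),
        weighted_median(stats_table, bootstrap_reps, seed),
        mode_based_estimate(stats_table, phi, False, bootstrap_reps, seed),
        mode_based_estimate(stats_table, phi, True, bootstrap_reps, seed),
    ]
    i2 = i2gx(stats_table)
    rows = []
    for e in ests:
        rows.append({
            "method": e.method, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_95[0], "ci_high": e.ci_95[1], "p_value": e.p_value,
            "intercept": e.intercept, "intercept_se": e.intercept_se,
            "intercept_p": e.intercept_p,
            "i2gx": i2 if e.method.startswith("egger") else None,
            "phi": e.phi, "n_snps": e.n_snps,
        })
    return pd.DataFrame(rows)
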
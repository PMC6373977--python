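"""Synthetic biobank-like cohort generator with known ground truth.

Every downstream stage (rule engine, scan, thresholds, IV follow-up,
two-sample MR) is exercised against data from this module, so each
discovery can be scored against a truth table.

The generative model
--------------------
* Dosages: ``d_ij ~ Binomial(2, f_j)`` per SNP, independent (no LD).
* Exposure (BMI-like, kg/m^2): a latent standardized exposure
  ``z = g_c + c*U + sigma_e * eps`` with ``g_c`` the centred weighted
  genetic value, ``U ~ N(0,1)`` a confounder and ``eps ~ N(0,1)``;
  ``exposure = 27 + 4.75 * z``. The default SNP effects are scaled so the
  score explains about 1.8% of exposure variance, matching the instrument
  strength regime of a large adult cohort.
* Continuous outcomes: ``y = theta*z + delta*v_std + N(0,1)`` where ``v``
  is the exposure's non-genetic residual (the confounded part) and
  ``theta`` the causal effect per SD exposure (0 for null outcomes).
* Binary / ordered outcomes: liability ``l = theta*z + delta*v_std + e``
  with ``e ~ N(0,1)``, thresholded at empirical quantiles. Because the
  confounder enters through the exposure residual and the liability noise
  is standard normal, the control-function probit's target equals
  ``theta`` exactly while the naive probit is biased.
* Unordered outcomes: multinomial logit on an age/sex/confounder mix
  (plus an exposure term on one category when causal).
* Categorical-multiple fields: sparse ICD-like code lists with
  independent per-code prevalences (null by construction).

Published instrument weights are the true per-allele effects plus
optional Gaussian noise (``weight_noise_sd``), emulating the two-sample
separation between an external GWAS and the analysis cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import SnpPanel

DEFAULT_OUTCOMES = {"continuous": 100, "binary": 100, "ordered": 50,
                    "unordered": 25, "cat_multiple": 5}


@dataclass
class SimulationConfig:
    n_participants: int = 20_000
    n_snps: int = 97
    effect_allele_freqs: np.ndarray | None = None  # drawn U(0.05, 0.5) if None
    snp_effects: np.ndarray | None = None  # SD exposure per allele; scaled draw if None
    score_r2: float = 0.018  # target variance explained when snp_effects is None
    exposure_noise_sd: float | None = None  # residual SD (SD units); completes var to 1
    confounder_effect_exposure: float = 0.3  # SD exposure per SD confounder
    confounder_effect_outcome: float = 0.5  # liability/outcome units per SD residual
    exposure_mean: float = 27.0  # kg/m^2
    exposure_sd: float = 4.75  # kg/m^2
    n_outcomes_per_type: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    causal_fraction: float = 0.1
    causal_effect_size: float = 0.1  # per SD exposure
    pleiotropy_spec: dict | None = None  # {outcome_id: per-SNP direct effects}
    weight_noise_sd: float = 0.0  # noise on published weights (two-sample emulation)
    missing_rate: float = 0.0
    n_pcs: int = 10
    seed: int = 0

    def validate(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")
        if self.effect_allele_freqs is not None:
            f = np.asarray(self.effect_allele_freqs, dtype=float)
            if f.size != self.n_snps:
                raise ValueError("effect_allele_freqs length != n_snps")
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.snp_effects is not None and len(self.snp_effects) != self.n_snps:
            raise ValueError("snp_effects length != n_snps")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    dosages: pd.DataFrame
    covariates: pd.DataFrame
    exposure: pd.Series
    exposure_sd_units: pd.Series
    confounder_residual: pd.Series  # standardized non-genetic exposure residual
    phenome: pd.DataFrame
    dictionary: pd.DataFrame
    truth: pd.DataFrame
    panel: SnpPanel
    config: SimulationConfig

    @property
    def n(self) -> int:
        return len(self.exposure)


def _draw_structure(cfg: SimulationConfig, rng: np.random.Generator):
    """Seed-stable draw of frequencies and per-allele effects."""
    freqs = (
        np.asarray(cfg.effect_allele_freqs, dtype=float)
        if cfg.effect_allele_freqs is not None
        else rng.uniform(0.05, 0.5, cfg.n_snps)
    )
    if cfg.snp_effects is not None:
        betas = np.asarray(cfg.snp_effects, dtype=float)
    else:
        raw = np.abs(rng.normal(0.0, 1.0, cfg.n_snps)) + 0.3
        var_raw = np.sum(raw**2 * 2 * freqs * (1 - freqs))
        betas = raw * np.sqrt(cfg.score_r2 / var_raw)
    return freqs, betas


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: genotypes, covariates, exposure, phenome, truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    freqs, betas = _draw_structure(cfg, rng)
    snp_ids = [f"rs{1000 + j}" for j in range(cfg.n_snps)]
    dosages = pd.DataFrame(
        rng.binomial(2, freqs, size=(n, cfg.n_snps)).astype(float), columns=snp_ids
    )

    # exposure on the latent SD scale
    g = dosages.to_numpy() @ betas
    g_c = g - np.sum(betas * 2 * freqs)
    var_g = float(np.sum(betas**2 * 2 * freqs * (1 - freqs)))
    c = cfg.confounder_effect_exposure
    sigma_e = (
        cfg.exposure_noise_sd
        if cfg.exposure_noise_sd is not None
        else np.sqrt(max(1.0 - var_g - c**2, 0.05))
    )
    U = rng.normal(0.0, 1.0, n)
    eps = rng.normal(0.0, 1.0, n)
    v = c * U + sigma_e * eps  # non-genetic residual of the exposure
    z = g_c + v
    v_std = v / np.sqrt(c**2 + sigma_e**2)
    exposure = pd.Series(cfg.exposure_mean + cfg.exposure_sd * z, name="exposure")

    covariates = pd.DataFrame({
        "age": rng.uniform(40, 69, n),
        "sex": rng.binomial(1, 0.5, n).astype(float),
        **{f"pc{k+1}": rng.normal(0.0, 1.0, n) for k in range(cfg.n_pcs)},
    })

    phenome, dict_rows, truth_rows = {}, [], []
    delta = cfg.confounder_effect_outcome
    counts = cfg.n_outcomes_per_type

    def causal_flags(k):
        m = int(round(cfg.causal_fraction * k))
        flags = np.zeros(k, dtype=bool)
        flags[:m] = True
        rng.shuffle(flags)
        return flags

    # continuous fields
    flags = causal_flags(counts.get("continuous", 0))
    for i, is_causal in enumerate(flags):
        fid = f"{1000 + i}"
        theta = cfg.causal_effect_size if is_causal else 0.0
        y = theta * z + delta * v_std + rng.normal(0.0, 1.0, n)
        if cfg.pleiotropy_spec and fid in cfg.pleiotropy_spec:
            alpha = np.asarray(cfg.pleiotropy_spec[fid], dtype=float)
            y = y + (dosages.to_numpy() - 2 * freqs) @ alpha
        phenome[fid] = y
        dict_rows.append((fid, "continuous", None))
        truth_rows.append((fid, "continuous", theta, delta))

    # binary fields via liability thresholds
    flags = causal_flags(counts.get("binary", 0))
    for i, is_causal in enumerate(flags):
        fid = f"{2000 + i}"
        theta = cfg.causal_effect_size if is_causal else 0.0
        liab = theta * z + delta * v_std + rng.normal(0.0, 1.0, n)
        prev = rng.uniform(0.15, 0.5)
        y = (liab > np.quantile(liab, 1 - prev)).astype(float)
        phenome[fid] = y
        dict_rows.append((fid, "integer", None))
        truth_rows.append((fid, "binary", theta, delta))

    # ordered categorical fields (4 liability bands)
    flags = causal_flags(counts.get("ordered", 0))
    for i, is_causal in enumerate(flags):
        fid = f"{3000 + i}"
        theta = cfg.causal_effect_size if is_causal else 0.0
        liab = theta * z + delta * v_std + rng.normal(0.0, 1.0, n)
        cuts = np.quantile(liab, [0.4, 0.7, 0.9])
        phenome[fid] = np.digitize(liab, cuts).astype(float)
        dict_rows.append((fid, "categorical_single", True))
        truth_rows.append((fid, "ordered_categorical", theta, delta))

    # unordered categorical fields (3 categories, multinomial logit)
    flags = causal_flags(counts.get("unordered", 0))
    for i, is_causal in enumerate(flags):
        fid = f"{4000 + i}"
        theta = cfg.causal_effect_size if is_causal else 0.0
        age_c = (covariates["age"] - 54.5) / 8.4
        u2 = 0.3 * age_c + 0.2 * U + theta * z
        u3 = -0.2 * age_c + 0.3 * covariates["sex"]
        expu = np.exp(np.column_stack([np.zeros(n), u2, u3]))
        p = expu / expu.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        draw = rng.uniform(size=(n, 1))
        phenome[fid] = (draw > cum[:, :-1]).sum(axis=1).astype(float)
        dict_rows.append((fid, "categorical_single", False))
        truth_rows.append((fid, "unordered_categorical", theta, delta))

    # categorical multiple: sparse ICD-like code lists (null by construction)
    for i in range(counts.get("cat_multiple", 0)):
        fid = f"{5000 + i}"
        n_codes = 6
        codes = [f"C{i}{k:02d}" for k in range(n_codes)]
        prevs = rng.uniform(0.02, 0.2, n_codes)
        member = rng.uniform(size=(n, n_codes)) < prevs
        vals = ["|".join(c for c, m in zip(codes, row) if m) for row in member]
        phenome[fid] = pd.Series(vals).replace("", np.nan)
        dict_rows.append((fid, "categorical_multiple", None))
        truth_rows.append((fid, "cat_multiple", 0.0, 0.0))

    phenome = pd.DataFrame(phenome)
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=phenome.shape) < cfg.missing_rate
        phenome = phenome.mask(mask)

    dictionary = pd.DataFrame(dict_rows, columns=["field_id", "field_type", "ordered"])
    truth = pd.DataFrame(
        truth_rows, columns=["field_id", "data_type", "causal_effect", "confounding"]
    )

    weights = betas + (
        rng.normal(0.0, cfg.weight_noise_sd, cfg.n_snps) if cfg.weight_noise_sd > 0 else 0.0
    )
    panel = SnpPanel(pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": ["A"] * cfg.n_snps,
        "other_allele": ["G"] * cfg.n_snps,
        "weight": weights,
        "se_weight": np.full(cfg.n_snps, max(cfg.weight_noise_sd, 1e-12)),
    }))

    return SyntheticCohort(
        dosages=dosages, covariates=covariates, exposure=exposure,
        exposure_sd_units=pd.Series(z, name="exposure_sd"),
        confounder_residual=pd.Series(v_std, name="v_std"),
        phenome=phenome, dictionary=dictionary, truth=truth,
        panel=panel, config=cfg,
    )


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-outcome ground truth for scoring scan discoveries."""
    t = cohort.truth.copy()
    t["is_causal"] = t["causal_effect"] != 0.0
    return t


def simulate_iv_probit_data(
    n: int,
    theta: float = 0.15,
    delta: float = 0.5,
    gamma: float = 0.3,
    seed: int = 0,
    prevalence: float = 0.3,
):
    """Compact endogenous-binary-outcome generator for IV probit checks.

    ``x = gamma*s + v`` with instrument ``s ~ N(0,1)`` and residual
    ``v ~ N(0,1)``; liability ``l = theta*x + delta*v + e``, ``e ~ N(0,1)``;
    ``y = 1(l > threshold)`` at the given prevalence. The control-function
    probit's estimand is exactly ``theta``; the naive probit's is not.
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, 1.0, n)
    v = rng.normal(0.0, 1.0, n)
    x = gamma * s + v
    liab = theta * x + delta * v + rng.normal(0.0, 1.0, n)
    y = (liab > np.quantile(liab, 1 - prevalence)).astype(float)
    return pd.DataFrame({"score": s, "exposure": x, "outcome": y})


def simulate_summary_stats(
    n_snps: int,
    true_effect: float,
    seed: int = 0,
    se_exposure: float = 0.0,
    se_outcome: float = 0.01,
    pleiotropy: np.ndarray | None = None,
    beta_exposure_range: tuple[float, float] = (0.02, 0.1),
) -> pd.DataFrame:
    """Two-sample summary statistics with known causal effect.

    ``beta_outcome_j = true_effect * bx_j + pleiotropy_j + noise`` with
    the observed exposure betas themselves measured with ``se_exposure``
    noise. Pleiotropy defaults to none (all instruments valid).
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*beta_exposure_range, n_snps)
    alpha = np.zeros(n_snps) if pleiotropy is None else np.asarray(pleiotropy, float)
    by = true_effect * bx_true + alpha + rng.normal(0.0, se_outcome, n_snps)
    bx = bx_true + rng.normal(0.0, se_exposure, n_snps) if se_exposure > 0 else bx_true
    return pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(n_snps)],
        "beta_exposure": bx,
        "se_exposure": np.full(n_snps, se_exposure),
        "beta_outcome": by,
        "se_outcome": np.full(n_snps, se_outcome),
    })


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write all cohort tables as TSV (dictionary also as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, obj in [
        ("dosages", cohort.dosages), ("covariates", cohort.covariates),
        ("phenome", cohort.phenome), ("dictionary", cohort.dictionary),
        ("truth", cohort.truth), ("panel", cohort.panel.table),
    ]:
        p = outdir / f"{name}.tsv"
        obj.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = outdir / "exposure.tsv"
    pd.DataFrame({"exposure": cohort.exposure}).to_csv(p, sep="\t", index=False)
    paths["exposure"] = p
    dj = outdir / "dictionary.json"
    dj.write_text(json.dumps(cohort.dictionary.to_dict(orient="records"), indent=1))
    paths["dictionary_json"] = dj
    return paths
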
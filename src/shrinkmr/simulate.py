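"""Sex-stratified two-sample GWAS simulator.

Emulates the study design the package targets: a small female and a large
male exposure GWAS (defaults 2,000 / 20,000), balanced outcome GWASs
(10,000 each), 100 independent biallelic SNPs with allele frequency 0.3.
Exposure and outcome samples are independent (the exposure is regenerated in
the outcome sample), giving a genuine two-sample design.

Three scenarios control the sex difference D_j = gamma_F,j - gamma_M,j in
variant-exposure effects:

``fixed_diff``
    D_j = ``d_value`` (default 0.05) on exactly ``d_size`` designated SNPs,
    zero elsewhere.
``random_diff``
    D_j drawn N(0, sd_delta^2) on every SNP (all SNPs differ), or, when
    ``corr`` is set, (gamma_F, gamma_M) drawn jointly with that correlation.
``osa_guided``
    Effects taken from a packaged deterministic fixture emulating an
    obstructive-sleep-apnea-like architecture: strong heterogeneous sex
    differences on every SNP and weak female effects (average female
    per-SNP F-statistic < 10 at n = 2,000).

Traits are simulated as continuous (linear models) by default so the true
causal effects are exact; a logistic variant is available via
``binary_traits``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .summary_stats import SummaryTable

__all__ = [
    "SimConfig",
    "SimReplicate",
    "make_effects",
    "simulate_replicate",
    "osa_like_fixture",
]


@dataclass
class SimConfig:
    """All knobs of the simulation; defaults are the study conditions."""

    n_exp_F: int = 2_000
    n_exp_M: int = 20_000
    n_out_F: int = 10_000
    n_out_M: int = 10_000
    p: int = 100
    maf: float = 0.3
    scenario: Literal["fixed_diff", "random_diff", "osa_guided"] = "fixed_diff"
    d_size: int = 10
    d_value: float = 0.05
    sd_delta: float = 0.05          # random_diff spread of D_j
    corr: float | None = None       # random_diff: correlation of (gamma_F, gamma_M)
    beta_F: float = 0.1
    beta_M: float = 0.1
    pleiotropy: Literal["none", "balanced", "directional"] = "none"
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.02   # directional only
    gamma_base_mean: float = 0.08
    gamma_base_sd: float = 0.03
    noise_sd: float = 1.0
    binary_traits: bool = False
    seed: int = 0
    fixture_seed: int = 20240

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not (0 <= self.d_size <= self.p):
            raise ValueError(f"d_size must lie in [0, p={self.p}], got {self.d_size}")
        for name in ("n_exp_F", "n_exp_M", "n_out_F", "n_out_M", "p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in ("fixed_diff", "random_diff", "osa_guided"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimReplicate:
    """One simulated dataset: four summary tables plus the ground truth."""

    exposure_female: SummaryTable
    exposure_male: SummaryTable
    outcome_female: SummaryTable | None
    outcome_male: SummaryTable | None
    truth: dict = field(default_factory=dict)


def _variant_frame(p: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1:04d}" for j in range(p)],
            "effect_allele": "A",
            "other_allele": "G",
            "chrom": [str((j % 22) + 1) for j in range(p)],
            "pos": [1_000_000 + 2_000_000 * (j // 22) for j in range(p)],
        }
    )


def osa_like_fixture(seed: int = 20240, p: int = 100) -> pd.DataFrame:
    """Deterministic effect table emulating an OSA-like architecture.

    Synthetic stand-in for a real sex-stratified sleep-apnea GWAS effect
    table (which is not shipped): male effects are moderately strong,
    female effects are weak and only loosely coupled to the male ones, so
    every SNP carries a sex difference and the implied female per-SNP
    F-statistics at n = 2,000 average well below 10.  Fully regenerable
    from ``seed``.
    """
    rng = np.random.default_rng(seed)
    gamma_M = np.abs(rng.normal(0.08, 0.03, size=p))
    gamma_M = np.maximum(gamma_M, 1e-3)
    gamma_F = 0.3 * gamma_M + rng.normal(0.0, 0.02, size=p)
    equal = gamma_F == gamma_M
    gamma_F[equal] += 1e-6  # ensure every SNP differs (measure-zero guard)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1:04d}" for j in range(p)],
            "gamma_F": gamma_F,
            "gamma_M": gamma_M,
        }
    )


def make_effects(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw true per-SNP variant-exposure effects (gamma_F, gamma_M)."""
    p = config.p
    if config.scenario == "osa_guided":
        fx = osa_like_fixture(config.fixture_seed, p)
        return fx["gamma_F"].to_numpy(), fx["gamma_M"].to_numpy()

    gamma_M = np.abs(rng.normal(config.gamma_base_mean, config.gamma_base_sd, size=p))
    gamma_M = np.maximum(gamma_M, 1e-6)
    if config.scenario == "fixed_diff":
        gamma_F = gamma_M.copy()
        gamma_F[: config.d_size] += config.d_value  # designated SNPs: the first d_size
        return gamma_F, gamma_M
    # random_diff
    if config.corr is not None:
        rho = float(config.corr)
        z = rng.standard_normal(p)
        e = rng.standard_normal(p)
        base = (gamma_M - config.gamma_base_mean) / config.gamma_base_sd
        gamma_F = config.gamma_base_mean + config.gamma_base_sd * (
            rho * base + np.sqrt(max(0.0, 1 - rho**2)) * e
        )
        return gamma_F, gamma_M
    gamma_F = gamma_M + rng.normal(0.0, config.sd_delta, size=p)
    return gamma_F, gamma_M


def _marginal_linear(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple linear regressions, vectorized across SNPs."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(Gc**2, axis=0)
    sxy = Gc.T @ yc
    beta = sxy / sxx
    syy = float(np.sum(yc**2))
    resid_var = np.maximum(syy - beta * sxy, 0.0) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return beta, se


def _marginal_logistic(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP logistic regressions (intercept + genotype), Newton, vectorized."""
    n, p = G.shape
    b0 = np.full(p, np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6)))
    b1 = np.zeros(p)
    for _ in range(25):
        eta = b0[None, :] + G * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (G * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * G).sum(axis=0)
        h11 = (w * G**2).sum(axis=0)
        det = h00 * h11 - h01**2
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        b0 += db0
        b1 += db1
        if max(np.max(np.abs(db0)), np.max(np.abs(db1))) < 1e-10:
            break
    eta = b0[None, :] + G * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * G).sum(axis=0)
    h11 = (w * G**2).sum(axis=0)
    se = np.sqrt(h00 / (h00 * h11 - h01**2))
    return b1, se


def _gwas_table(
    G: np.ndarray, y: np.ndarray, stratum: str, trait_label: str,
    binary: bool,
) -> SummaryTable:
    beta, se = (_marginal_logistic(G, y) if binary else _marginal_linear(G, y))
    p = G.shape[1]
    df = _variant_frame(p)
    df["eaf"] = G.mean(axis=0) / 2.0
    df["beta"] = beta
    df["se"] = se
    z = beta / se
    df["pvalue"] = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    df["n"] = G.shape[0]
    return SummaryTable(df, trait_label=trait_label, stratum=stratum)


def _draw_pleiotropy(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pleiotropy == "none":
        return np.zeros(config.p)
    if config.pleiotropy == "balanced":
        return rng.normal(0.0, config.pleiotropy_sd, size=config.p)
    return rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=config.p)


def simulate_replicate(
    config: SimConfig, rep_seed: int, exposure_only: bool = False
) -> SimReplicate:
    """Simulate one replicate; bitwise reproducible from (config, rep_seed).

    Four independent genotype panels are drawn Binomial(2, maf).  In each
    exposure panel the exposure is X = G @ gamma_s + noise; in each outcome
    panel the exposure is regenerated (two-sample independence) and
    Y = beta_s * X_latent + G @ alpha + noise, with alpha the per-SNP direct
    (pleiotropic) outcome effects.  Per-SNP marginal regressions produce the
    four summary tables.  ``exposure_only`` skips the outcome panels (useful
    for instrument-strength studies).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(rep_seed)]))
    gamma_F, gamma_M = make_effects(config, rng)
    alpha = _draw_pleiotropy(config, rng)

    def panel(n: int, gamma: np.ndarray, beta: float | None):
        G = rng.binomial(2, config.maf, size=(n, config.p)).astype(float)
        x = G @ gamma + rng.normal(0.0, config.noise_sd, size=n)
        if beta is None:
            y = x
        else:
            y = beta * x + G @ alpha + rng.normal(0.0, config.noise_sd, size=n)
        if config.binary_traits:
            prob = 1.0 / (1.0 + np.exp(-(y - np.mean(y))))
            y = rng.binomial(1, prob).astype(float)
        return G, y

    G, x = panel(config.n_exp_F, gamma_F, None)
    exp_F = _gwas_table(G, x, "female", "exposure", config.binary_traits)
    G, x = panel(config.n_exp_M, gamma_M, None)
    exp_M = _gwas_table(G, x, "male", "exposure", config.binary_traits)

    out_F = out_M = None
    if not exposure_only:
        G, y = panel(config.n_out_F, gamma_F, config.beta_F)
        out_F = _gwas_table(G, y, "female", "outcome", config.binary_traits)
        G, y = panel(config.n_out_M, gamma_M, config.beta_M)
        out_M = _gwas_table(G, y, "male", "outcome", config.binary_traits)

    truth = {
        "gamma_F": gamma_F,
        "gamma_M": gamma_M,
        "beta_F": config.beta_F,
        "beta_M": config.beta_M,
        "alpha": alpha,
    }
    return SimReplicate(exp_F, exp_M, out_F, out_M, truth)
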
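"""Two-sample Mendelian randomization estimators and sex-difference testing.

All estimators consume a :class:`~shrinkmr.summary_stats.HarmonizedSet`
(allele-aligned per-variant exposure effects ``gamma`` with SEs and outcome
effects ``Gamma`` with SEs) and return a :class:`CausalEstimate` with a
normal-theory 95% interval (beta +/- 1.96 se).

Implemented methods
-------------------
- Wald ratio (single instrument)
- IVW: fixed, penalized, robust (MM/Tukey), penalized+robust
- Egger meta-regression (optionally robust)
- weighted median (parametric-bootstrap SE)
- contamination mixture (profile likelihood over a beta grid, valid/invalid
  normal mixture per instrument)
- constrained maximum likelihood (cML) with BIC selection of the number of
  invalid instruments
- RAPS: robust adjusted profile score with optional overdispersion tau^2
- multivariable IVW

The convention throughout: for binary traits effects are log-odds ratios;
odds-ratio reporting is ``exp(beta)`` at the presentation layer only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, optimize, stats

from .summary_stats import HarmonizedSet, VariantAssoc

__all__ = [
    "CausalEstimate",
    "SexDiffResult",
    "ConvergenceError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "contamination_mixture",
    "cml",
    "raps",
    "mv_ivw",
    "sex_difference_test",
    "bh_fdr",
    "run_mr",
    "TwoSampleMR",
    "MR_METHODS",
]

_Z95 = 1.96


class ConvergenceError(RuntimeError):
    """An iterative estimator failed to converge after restarts."""


@dataclass
class CausalEstimate:
    """A causal effect estimate with normal-theory uncertainty.

    ``beta`` is on the log-odds-ratio scale for binary outcomes.  The 95%
    interval is beta +/- 1.96*se and the p-value the two-sided normal tail.
    """

    beta: float
    se: float
    method: str
    n_iv: int
    diagnostics: dict = field(default_factory=dict)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"{self.method}: se must be > 0, got {self.se}")
        self.ci_low = self.beta - _Z95 * self.se
        self.ci_high = self.beta + _Z95 * self.se
        z = self.beta / self.se
        self.pvalue = float(min(max(2.0 * stats.norm.sf(abs(z)), 5e-324), 1.0))

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "beta": self.beta,
                    "se": self.se,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "pvalue": self.pvalue,
                    "odds_ratio": self.odds_ratio,
                    "n_iv": self.n_iv,
                }
            ]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CausalEstimate {self.method}: beta={self.beta:.4f} "
            f"(95% CI {self.ci_low:.4f}, {self.ci_high:.4f}), p={self.pvalue:.3g}, "
            f"n_iv={self.n_iv}>"
        )


@dataclass
class SexDiffResult:
    """Two-sample z test of equal causal effects across strata."""

    diff: float
    se_diff: float
    statistic: float
    pvalue: float
    fdr_pvalue: float | None = None


def _arrays(hset: HarmonizedSet):
    g = hset.gamma
    sg = hset.gamma_se
    G = hset.Gamma
    sG = hset.Gamma_se
    if np.any(sg <= 0) or np.any(sG <= 0):
        raise ValueError("all standard errors must be > 0")
    return g, sg, G, sG


def _require(hset: HarmonizedSet, k: int, method: str) -> None:
    if len(hset) < k:
        raise ValueError(f"{method} requires >= {k} instruments, got {len(hset)}")


def wald_ratio(exposure: VariantAssoc, outcome: VariantAssoc) -> CausalEstimate:
    """Single-instrument ratio estimate: Gamma/gamma, first-order delta SE."""
    if exposure.beta == 0:
        raise ValueError("Wald ratio undefined for zero exposure effect")
    beta = outcome.beta / exposure.beta
    se = outcome.se / abs(exposure.beta)
    return CausalEstimate(beta, se, "wald_ratio", 1,
                          {"variant_id": exposure.variant_id})


def _ivw_weights(g, sG):
    return g**2 / sG**2


def _q_penalty(ratios, w, beta):
    """Heterogeneity penalty: one-sided chi2_1 p of each IV's Q contribution."""
    q = w * (ratios - beta) ** 2
    p = stats.chi2.sf(q, df=1)
    return np.minimum(1.0, 20.0 * p), q


def _robust_origin_fit(x, y):
    """MM-type robust regression through the origin on pre-weighted data."""
    ols = sm.OLS(y, x[:, None]).fit()
    resid = y - ols.params[0] * x
    if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(y))):
        # exact fit: robust iteration has nothing to do and MAD scale is 0
        se = float(ols.bse[0]) if np.isfinite(ols.bse[0]) and ols.bse[0] > 0 else 1e-12
        return float(ols.params[0]), max(se, 1e-12)
    rlm = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight()).fit()
    return float(rlm.params[0]), float(rlm.bse[0])


def ivw(hset: HarmonizedSet, variant: str = "fixed") -> CausalEstimate:
    """Inverse-variance weighted aggregation of per-IV Wald ratios.

    ``fixed``: weighted mean of ratios with weights gamma^2/se_Gamma^2 and
    SE (sum w)^-1/2.  ``penalized`` multiplies weights by a heterogeneity
    penalty min(1, 20*p_j) where p_j is the one-sided chi2_1 p-value of the
    IV's Cochran-Q contribution.  ``robust`` fits the origin regression of
    Gamma on gamma (precision-weighted) with an MM-type Tukey loss;
    ``penalized_robust`` combines both.
    """
    if variant not in ("fixed", "penalized", "robust", "penalized_robust"):
        raise ValueError(f"unknown ivw variant {variant!r}")
    _require(hset, 3 if "robust" in variant else 2, f"ivw_{variant}")
    g, sg, G, sG = _arrays(hset)
    if np.any(g == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    ratios = G / g
    w = _ivw_weights(g, sG)
    beta_fix = float(np.sum(w * ratios) / np.sum(w))
    diag: dict = {"weights": w.copy()}

    if variant == "fixed":
        se = float(1.0 / math.sqrt(np.sum(w)))
        diag["Q"] = float(np.sum(w * (ratios - beta_fix) ** 2))
        return CausalEstimate(beta_fix, se, "ivw_fixed", len(g), diag)

    if "penalized" in variant:
        pen, q = _q_penalty(ratios, w, beta_fix)
        w_eff = w * pen
        diag["penalty"] = pen
        diag["n_downweighted"] = int(np.sum(pen < 1.0))
    else:
        w_eff = w

    if "robust" in variant:
        sw = np.sqrt(w_eff / g**2)  # back to per-point scale on (gamma, Gamma)
        beta, se = _robust_origin_fit(g * sw, G * sw)
        return CausalEstimate(beta, se, f"ivw_{variant}", len(g), diag)

    beta = float(np.sum(w_eff * ratios) / np.sum(w_eff))
    se = float(1.0 / math.sqrt(np.sum(w_eff)))
    return CausalEstimate(beta, se, "ivw_penalized", len(g), diag)


def egger(hset: HarmonizedSet, robust: bool = False) -> CausalEstimate:
    """Egger meta-regression: weighted regression of Gamma on gamma with
    intercept (the average directional-pleiotropy effect).

    Instruments are reoriented so gamma >= 0 before fitting.  Weights are
    1/se_Gamma^2; the residual scale multiplier is floored at 1 (no
    "underdispersion" credit).  ``robust=True`` swaps in an MM-type fit.
    """
    _require(hset, 3, "egger")
    g, sg, G, sG = _arrays(hset)
    flip = np.where(g < 0, -1.0, 1.0)
    g, G = g * flip, G * flip
    sw = 1.0 / sG
    X = np.column_stack([sw, g * sw])
    y = G * sw
    if robust:
        ols = sm.OLS(y, X).fit()
        resid = y - X @ ols.params
        if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(y))):
            beta, se = float(ols.params[1]), max(float(ols.bse[1]), 1e-12)
            intercept = float(ols.params[0])
        else:
            fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
            beta, se = float(fit.params[1]), float(fit.bse[1])
            intercept = float(fit.params[0])
        diag = {"egger_intercept": intercept, "robust": True}
    else:
        fit = sm.OLS(y, X).fit()
        scale = fit.ssr / fit.df_resid if fit.df_resid > 0 else 1.0
        infl = math.sqrt(max(1.0, scale) / scale) if scale > 0 else 1.0
        beta = float(fit.params[1])
        se = max(float(fit.bse[1]) * infl, 1e-12)
        diag = {
            "egger_intercept": float(fit.params[0]),
            "egger_intercept_se": float(fit.bse[0]) * infl,
            "scale": float(scale),
            "robust": False,
        }
    return CausalEstimate(beta, se, "egger_robust" if robust else "egger",
                          len(g), diag)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] < 0.5:
        return float(v[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(v[k - 1] + (v[k] - v[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 20240
) -> CausalEstimate:
    """Weighted median of Wald ratios; SE by parametric bootstrap.

    Weights are the inverse first-order (delta-method) variances of the
    per-IV ratios, se_Gamma^2/gamma^2, as in the original estimator.
    Bootstrap draws resample (gamma, Gamma) from their sampling normals with
    a fixed seed (>= 1000 draws by default).
    """
    _require(hset, 3, "weighted_median")
    g, sg, G, sG = _arrays(hset)
    flip = np.where(g < 0, -1.0, 1.0)  # orientation invariance, exact
    g, G = g * flip, G * flip
    ratios = G / g
    var = sG**2 / g**2
    w = 1.0 / var
    beta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    gb = rng.normal(g, sg, size=(n_boot, len(g)))
    Gb = rng.normal(G, sG, size=(n_boot, len(g)))
    est = np.empty(n_boot)
    for b in range(n_boot):
        rb = Gb[b] / gb[b]
        vb = sG**2 / gb[b] ** 2
        est[b] = _weighted_median(rb, 1.0 / vb)
    se = float(np.std(est, ddof=1))
    se = max(se, 1e-12)
    return CausalEstimate(beta, se, "weighted_median", len(g),
                          {"n_boot": n_boot, "bootstrap_seed": seed})


def contamination_mixture(
    hset: HarmonizedSet, psi: float | str = "auto", n_grid: int = 2000
) -> CausalEstimate:
    """Contamination-mixture estimator.

    Per-IV ratio estimates are modelled as a two-component normal mixture:
    valid IVs ~ N(beta, se_j^2), invalid IVs ~ N(0, psi^2 + se_j^2).  The
    profile log-likelihood over a beta grid (range of ratios +/- 3 SD of the
    ratios, >= 1000 points) classifies each IV at each grid point by the
    larger component density; the estimate maximizes the profile.  The 95%
    set is the union of grid points within the chi2_1 likelihood-ratio
    cutoff; disconnected sets are flagged as multimodal.

    ``psi="auto"`` uses 1.5x the SD of the ratio estimates.  A smaller psi
    makes the invalid component mimic the sampling spread of valid ratios
    and the hard classification then absorbs the tail nearest zero,
    biasing the estimate away from the null.
    """
    _require(hset, 3, "contamination_mixture")
    g, sg, G, sG = _arrays(hset)
    ratios = G / g
    se_r = sG / np.abs(g)
    sd_r = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else float(se_r[0])
    if psi == "auto":
        psi_val = 1.5 * sd_r if sd_r > 0 else 1.0
    else:
        psi_val = float(psi)
    lo = float(np.min(ratios) - 3.0 * sd_r)
    hi = float(np.max(ratios) + 3.0 * sd_r)
    if hi - lo < 1e-8:
        lo, hi = lo - 1.0, hi + 1.0
    grid = np.linspace(lo, hi, max(n_grid, 1000))

    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=se_r[None, :])
    sd_inv = np.sqrt(psi_val**2 + se_r**2)
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=sd_inv)[None, :]
    ll = np.maximum(ll_valid, ll_invalid).sum(axis=1)

    k = int(np.argmax(ll))
    beta = float(grid[k])
    cutoff = ll[k] - 0.5 * stats.chi2.ppf(0.95, df=1)
    inside = ll >= cutoff
    # connected components of the 95% likelihood set
    edges = np.flatnonzero(np.diff(inside.astype(int)))
    comp_bounds = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            comp_bounds.append((start, i - 1))
            start = None
    if start is not None:
        comp_bounds.append((start, len(grid) - 1))
    multimodal = len(comp_bounds) > 1
    this = next((b for b in comp_bounds if b[0] <= k <= b[1]), (k, k))
    ci_lo, ci_hi = float(grid[this[0]]), float(grid[this[1]])
    se = max((ci_hi - ci_lo) / (2 * _Z95), (grid[1] - grid[0]) / _Z95)

    valid = ll_valid[k] >= ll_invalid[0]
    return CausalEstimate(
        beta, se, "conmix", len(g),
        {
            "psi": psi_val,
            "valid_mask": valid,
            "n_invalid": int(np.sum(~valid)),
            "multimodal": multimodal,
            "likelihood_ci_components": [
                (float(grid[a]), float(grid[b])) for a, b in comp_bounds
            ],
            "grid_step": float(grid[1] - grid[0]),
        },
    )


def _cml_profile_terms(beta, g, sg, G, sG):
    """Per-IV profiled -2loglik contribution when forced valid."""
    return (G - beta * g) ** 2 / (sG**2 + beta**2 * sg**2)


def _cml_fit_K(g, sg, G, sG, K, beta0, bounds):
    """Coordinate descent: alternate invalid-set selection and 1-D beta fit."""
    p = len(g)
    beta = beta0
    invalid = frozenset()
    for _ in range(200):
        r = _cml_profile_terms(beta, g, sg, G, sG)
        new_invalid = frozenset(np.argsort(r)[::-1][:K]) if K > 0 else frozenset()
        valid = np.array(sorted(set(range(p)) - new_invalid), dtype=int)

        def obj(b, v=valid):
            return float(np.sum(_cml_profile_terms(b, g[v], sg[v], G[v], sG[v])))

        res = optimize.minimize_scalar(obj, bounds=bounds, method="bounded",
                                       options={"xatol": 1e-12})
        new_beta = float(res.x)
        if new_invalid == invalid and abs(new_beta - beta) < 1e-12:
            beta = new_beta
            invalid = new_invalid
            break
        beta, invalid = new_beta, new_invalid
    valid = np.array(sorted(set(range(p)) - invalid), dtype=int)
    nll = float(np.sum(_cml_profile_terms(beta, g[valid], sg[valid], G[valid], sG[valid])))
    return beta, invalid, nll


def cml(
    hset: HarmonizedSet, k_grid: Sequence[int] | None = None,
) -> CausalEstimate:
    """Constrained maximum likelihood with BIC selection of #invalid IVs.

    For each candidate K the bivariate-normal likelihood of (gamma_hat,
    Gamma_hat) is maximized with exactly K instruments allowed free direct
    (pleiotropy) effects — those contribute nothing to the profiled
    objective, so the fit alternates between picking the K largest per-IV
    deviations and a 1-D beta optimization over the valid set.  K is chosen
    by BIC with n = median over IVs of min(exposure n, outcome n); the SE is
    the profile-likelihood curvature at the selected K.
    """
    _require(hset, 3, "cml")
    g, sg, G, sG = _arrays(hset)
    p = len(g)
    if k_grid is None:
        k_grid = range(0, p - 1)
    k_grid = [int(k) for k in k_grid]
    if any(k < 0 or k > p - 2 for k in k_grid):
        raise ValueError(f"k_grid values must lie in [0, {p - 2}]")

    ratios = G / g
    span = max(float(np.max(ratios) - np.min(ratios)), 1.0)
    bounds = (float(np.min(ratios) - 3 * span), float(np.max(ratios) + 3 * span))
    beta0 = ivw(hset, "fixed").beta

    ns = np.minimum(
        hset.data.get("n_exp", pd.Series(np.nan, index=hset.data.index)).to_numpy(float),
        hset.data.get("n_out", pd.Series(np.nan, index=hset.data.index)).to_numpy(float),
    )
    n_eff = float(np.nanmedian(ns)) if np.isfinite(ns).any() else float(p)
    log_n = math.log(max(n_eff, 2.0))

    best = None
    for K in k_grid:
        beta_k, invalid, nll = _cml_fit_K(g, sg, G, sG, K, beta0, bounds)
        bic = nll + K * log_n
        if best is None or bic < best[0]:
            best = (bic, K, beta_k, invalid)
    bic, K_sel, beta, invalid = best

    valid = np.array(sorted(set(range(p)) - invalid), dtype=int)

    def f(b):
        return 0.5 * float(
            np.sum(_cml_profile_terms(b, g[valid], sg[valid], G[valid], sG[valid]))
        )

    h = 1e-5 * max(1.0, abs(beta))
    info = (f(beta + h) - 2.0 * f(beta) + f(beta - h)) / h**2
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    if not np.isfinite(se):
        raise ConvergenceError("cml: non-positive curvature at the optimum")
    return CausalEstimate(
        beta, se, "cml", p,
        {
            "K_selected": K_sel,
            "bic": bic,
            "invalid_ivs": sorted(hset.data["variant_id"].iloc[list(invalid)])
            if invalid else [],
            "se_variant": "selected_K",
        },
    )


# --- RAPS ------------------------------------------------------------------

_TUKEY_C = 4.685
_HUBER_C = 1.345


def _psi_rho(loss: str):
    if loss == "l2":
        return (lambda t: t), (lambda t: 0.5 * t**2)
    if loss == "huber":
        c = _HUBER_C
        return (
            lambda t: np.clip(t, -c, c),
            lambda t: np.where(np.abs(t) <= c, 0.5 * t**2, c * np.abs(t) - 0.5 * c**2),
        )
    if loss == "tukey":
        c = _TUKEY_C

        def psi(t):
            u = t / c
            return np.where(np.abs(u) <= 1.0, t * (1.0 - u**2) ** 2, 0.0)

        def rho(t):
            u = np.clip(np.abs(t / c), 0.0, 1.0)
            return (c**2 / 6.0) * (1.0 - (1.0 - u**2) ** 3)

        return psi, rho
    raise ValueError(f"unknown loss {loss!r}; choose l2, huber or tukey")


@lru_cache(maxsize=None)
def _psi_moments(loss: str) -> tuple[float, float]:
    """E[psi(Z)Z] and E[psi(Z)^2] for Z ~ N(0,1)."""
    psi, _ = _psi_rho(loss)
    c1 = integrate.quad(lambda z: psi(np.asarray(z)) * z * stats.norm.pdf(z),
                        -np.inf, np.inf)[0]
    c2 = integrate.quad(lambda z: psi(np.asarray(z)) ** 2 * stats.norm.pdf(z),
                        -np.inf, np.inf)[0]
    return float(c1), float(c2)


def raps(
    hset: HarmonizedSet,
    overdispersion: bool = True,
    loss: str = "tukey",
    max_iter: int = 100,
) -> CausalEstimate:
    """Robust adjusted profile score estimator.

    Solves, jointly in (beta, tau^2 >= 0), the estimating equations built
    from the standardized residuals

        t_j(beta) = (Gamma_j - beta*gamma_j) / sqrt(sG_j^2 + beta^2 sg_j^2 + tau^2)

    passed through the chosen loss's psi-function.  The beta-score uses the
    adjusted direction a_j = (sG_j^2 gamma_j + beta sg_j^2 Gamma_j) / v^{3/2},
    which has mean zero at the truth even with weak instruments; tau^2 (the
    overdispersion of pleiotropic effects) solves the precision-weighted
    moment equation sum (psi(t_j) t_j - E[psi(Z)Z]) / v_j = 0.  The SE is the
    sandwich variance of the beta-score.
    """
    _require(hset, 3, "raps")
    g, sg, G, sG = _arrays(hset)
    psi, _rho = _psi_rho(loss)
    c1, c2 = _psi_moments(loss)

    ivw_fit = ivw(hset, "fixed")
    span = 10.0 * ivw_fit.se

    def tvals(beta, tau2):
        v = sG**2 + beta**2 * sg**2 + tau2
        return (G - beta * g) / np.sqrt(v), v

    def score_beta(beta, tau2):
        t, v = tvals(beta, tau2)
        a = (sG**2 * g + beta * sg**2 * G) / v**1.5
        return float(np.sum(psi(t) * a))

    def tau_eq(tau2, beta):
        t, v = tvals(beta, tau2)
        return float(np.sum((psi(t) * t - c1) / v))

    def solve_tau(beta):
        if not overdispersion:
            return 0.0
        if tau_eq(0.0, beta) <= 0.0:
            return 0.0
        hi = float(np.mean(sG**2))
        for _ in range(80):
            if tau_eq(hi, beta) < 0.0:
                break
            hi *= 2.0
        else:
            raise ConvergenceError("raps: tau^2 bracket not found")
        return float(optimize.brentq(lambda t2: tau_eq(t2, beta), 0.0, hi,
                                     xtol=1e-14))

    def solve_beta(tau2, center, width):
        lo, hi = center - width, center + width
        flo, fhi = score_beta(lo, tau2), score_beta(hi, tau2)
        tries = 0
        while flo * fhi > 0 and tries < 30:
            lo -= width
            hi += width
            flo, fhi = score_beta(lo, tau2), score_beta(hi, tau2)
            tries += 1
        if flo * fhi > 0:
            # no sign change (possible with redescending loss): minimize |score|
            res = optimize.minimize_scalar(
                lambda b: abs(score_beta(b, tau2)),
                bounds=(center - 10 * width, center + 10 * width), method="bounded",
                options={"xatol": 1e-12},
            )
            return float(res.x)
        return float(optimize.brentq(lambda b: score_beta(b, tau2), lo, hi,
                                     xtol=1e-13))

    trace = []
    rng = np.random.default_rng(0)
    for attempt in range(3):
        beta = ivw_fit.beta + (0.0 if attempt == 0 else rng.normal(0, span))
        tau2 = 0.0
        ok = False
        for it in range(max_iter):
            tau2_new = solve_tau(beta)
            beta_new = solve_beta(tau2_new, beta, span)
            trace.append((attempt, it, beta_new, tau2_new))
            if abs(beta_new - beta) < 1e-12 and abs(tau2_new - tau2) < 1e-14:
                beta, tau2 = beta_new, tau2_new
                ok = True
                break
            beta, tau2 = beta_new, tau2_new
        if ok:
            break
    else:
        raise ConvergenceError(f"raps failed to converge; trace={trace[-5:]}")

    t, v = tvals(beta, tau2)
    a = (sG**2 * g + beta * sg**2 * G) / v**1.5
    h = 1e-6 * max(1.0, abs(beta))
    A = (score_beta(beta + h, tau2) - score_beta(beta - h, tau2)) / (2 * h)
    # Var(psi(t_j)) = E[psi(Z)^2] = c2 at the truth, so Var(score) ~ c2 * sum a_j^2
    B = c2 * float(np.sum(a**2))
    if A == 0:
        raise ConvergenceError("raps: singular information")
    se = math.sqrt(B) / abs(A)
    n_down = int(np.sum(psi(t) == 0.0)) if loss == "tukey" else 0
    return CausalEstimate(
        beta, se, "raps", len(g),
        {
            "tau2": tau2,
            "overdispersion": overdispersion,
            "loss": loss,
            "n_fully_downweighted": n_down,
            "max_abs_t": float(np.max(np.abs(t))),
        },
    )


def mv_ivw(
    hsets: Sequence[HarmonizedSet], robust: bool = False,
    exposure_labels: Sequence[str] | None = None,
) -> list[CausalEstimate]:
    """Multivariable IVW: regress outcome effects on several exposures' effects.

    ``hsets`` share the same outcome; variants are intersected and aligned by
    variant_id.  Weighted regression of Gamma on the exposure-effect matrix
    without intercept (weights 1/se_Gamma^2); returns one estimate per
    exposure.  ``robust=True`` swaps in an MM-type fit.
    """
    k = len(hsets)
    if k < 1:
        raise ValueError("at least one exposure required")
    common = set(hsets[0].data["variant_id"])
    for h in hsets[1:]:
        common &= set(h.data["variant_id"])
    common = sorted(common)
    p = len(common)
    if p < k + 2:
        raise ValueError(f"mv_ivw requires >= {k + 2} instruments, got {p}")

    frames = [h.data.set_index("variant_id").loc[common] for h in hsets]
    X = np.column_stack([f["beta_exp"].to_numpy(float) for f in frames])
    y = frames[0]["beta_out"].to_numpy(float)
    sG = frames[0]["se_out"].to_numpy(float)
    # exposures with identically-zero effects carry no information: they are
    # excluded from the regression and reported as (0, inf) estimates
    nonzero = [i for i in range(k) if np.any(X[:, i] != 0.0)]
    Xn = X[:, nonzero]
    if Xn.shape[1] and np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        raise ValueError("exposure effect matrix is rank deficient")

    sw = 1.0 / sG
    Xw = Xn * sw[:, None]
    yw = y * sw
    labels = list(exposure_labels) if exposure_labels else [
        f"exposure_{i + 1}" for i in range(k)
    ]
    if robust:
        ols = sm.OLS(yw, Xw).fit()
        resid = yw - Xw @ ols.params
        if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(yw))):
            params, bses = ols.params, np.maximum(ols.bse, 1e-12)
        else:
            fit = sm.RLM(yw, Xw, M=sm.robust.norms.TukeyBiweight()).fit()
            params, bses = fit.params, fit.bse
        scale_note = "robust"
    else:
        fit = sm.OLS(yw, Xw).fit()
        scale = fit.ssr / fit.df_resid if fit.df_resid > 0 else 1.0
        infl = math.sqrt(max(1.0, scale) / scale) if scale > 0 else 1.0
        params, bses = fit.params, np.maximum(fit.bse * infl, 1e-12)
        scale_note = "fixed_floor"
    full_params = np.zeros(k)
    full_bses = np.full(k, np.inf)
    for j, i in enumerate(nonzero):
        full_params[i] = params[j]
        full_bses[i] = bses[j]
    return [
        CausalEstimate(
            float(full_params[i]), float(full_bses[i]),
            "mv_ivw_robust" if robust else "mv_ivw", p,
            {"exposure": labels[i], "n_exposures": k, "scale": scale_note,
             "informative": i in nonzero},
        )
        for i in range(k)
    ]


def sex_difference_test(
    est_F: CausalEstimate, est_M: CausalEstimate
) -> SexDiffResult:
    """Two-sample z test of H0: beta_F == beta_M assuming independence.

    diff = beta_F - beta_M, se = sqrt(se_F^2 + se_M^2), two-sided normal
    p-value.  Batch FDR adjustment via :func:`bh_fdr`.
    """
    diff = est_F.beta - est_M.beta
    se = math.sqrt(est_F.se**2 + est_M.se**2)
    z = diff / se
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), 5e-324), 1.0))
    return SexDiffResult(diff, se, z, p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def attach_fdr(results: Sequence[SexDiffResult]) -> list[SexDiffResult]:
    """Attach BH FDR p-values across a batch of sex-difference tests."""
    adj = bh_fdr([r.pvalue for r in results])
    for r, a in zip(results, adj):
        r.fdr_pvalue = float(a)
    return list(results)


MR_METHODS = {
    "ivw_fixed": lambda h, **o: ivw(h, "fixed"),
    "ivw_penalized": lambda h, **o: ivw(h, "penalized"),
    "ivw_robust": lambda h, **o: ivw(h, "robust"),
    "ivw_penalized_robust": lambda h, **o: ivw(h, "penalized_robust"),
    "egger": lambda h, **o: egger(h, robust=False),
    "egger_robust": lambda h, **o: egger(h, robust=True),
    "weighted_median": lambda h, **o: weighted_median(h, **o),
    "conmix": lambda h, **o: contamination_mixture(h, **o),
    "cml": lambda h, **o: cml(h, **o),
    "raps": lambda h, **o: raps(h, **o),
}


def run_mr(hset: HarmonizedSet, method: str, options: dict | None = None,
           calibration: str = "raw") -> CausalEstimate:
    """Dispatch to the named MR method; records the exposure-input provenance
    (raw / fe_meta / apm / aw) in diagnostics."""
    if method not in MR_METHODS:
        raise ValueError(
            f"unknown MR method {method!r}; valid: {sorted(MR_METHODS)}"
        )
    est = MR_METHODS[method](hset, **(options or {}))
    est.diagnostics["exposure_calibration"] = calibration
    return est


class TwoSampleMR:
    """Model object over a harmonized instrument set.

    ``TwoSampleMR(hset).fit("raps")`` returns a :class:`CausalEstimate`; the
    model remembers whether its exposure column came from raw or calibrated
    (fe_meta/apm/aw) summary statistics.
    """

    def __init__(self, hset: HarmonizedSet, calibration: str = "raw"):
        self.hset = hset
        self.calibration = calibration

    @classmethod
    def from_tables(cls, exposure, outcome, calibration: str = "raw", **harm_opts):
        from .summary_stats import harmonize

        return cls(harmonize(exposure, outcome, **harm_opts), calibration)

    def fit(self, method: str = "raps", **options) -> CausalEstimate:
        return run_mr(self.hset, method, options, self.calibration)

    def fit_all(self, methods: Sequence[str] | None = None, **options
                ) -> pd.DataFrame:
        methods = list(methods or MR_METHODS)
        rows = [self.fit(m, **options).summary() for m in methods]
        return pd.concat(rows, ignore_index=True)
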
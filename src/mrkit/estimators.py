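"""Two-sample MR causal-effect estimators.

All estimators consume a :class:`~mrkit.gwas_io.HarmonizedSet` of per-SNP
exposure and outcome effects and return an :class:`MREstimate` on the
log-odds (or linear) scale, with the odds-ratio scale exposed as derived
properties.

Implemented methods
-------------------
wald_ratio
    Single-SNP ratio estimate beta_out/beta_exp with first-order SE.
ivw
    Inverse-variance weighted meta-analysis of Wald ratios, equivalently a
    weighted regression of outcome on exposure effects through the origin.
    ``model="fixed"`` assumes all instruments valid; ``model="random"``
    inflates the SE by the multiplicative overdispersion factor
    sqrt(max(Q/(n-1), 1)); ``model="auto"`` applies the heterogeneity-gated
    rule: random effects when Cochran's Q has p < 0.05, fixed otherwise.
egger
    Weighted regression with an intercept after orienting exposure effects
    positive; a non-zero intercept estimates directional pleiotropy.
weighted_median
    Weight-interpolated median of Wald ratios; consistent when at least
    half the weight comes from valid instruments.  SE by seeded parametric
    bootstrap.
weighted_mode
    Mode of a kernel-smoothed weighted density of Wald ratios; consistent
    when the largest homogeneous cluster of instruments is valid.  SE by
    seeded parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInstrumentError, InsufficientInstrumentsError
from .gwas_io import HarmonizedSet

_Z95 = stats.norm.ppf(0.975)
_TINY_P = 5e-324  # keep p-values inside (0, 1]


def _normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory uncertainty.

    ``beta`` is on the scale of the harmonized effects (log-OR for binary
    outcomes); ``odds_ratio`` and its CI are the exponentiated equivalents.
    Method-specific quantities (Egger intercept, chosen IVW model, ...) live
    in ``extra``.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - _Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + _Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }

    def __str__(self) -> str:
        return (
            f"{self.method}: beta={self.beta:.4f} (se={self.se:.4f}), "
            f"OR={self.odds_ratio:.3f} [{self.or_ci_low:.3f}, "
            f"{self.or_ci_high:.3f}], p={self.pval:.3g}, n_snps={self.n_snps}"
        )


def _ratios_and_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order inverse-variance weights."""
    if (h.beta_exp == 0).any():
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    ratios = h.beta_out / h.beta_exp
    weights = h.beta_exp**2 / h.se_out**2
    return ratios, weights


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MREstimate:
    """Single-instrument ratio estimate (first-order SE, exposure SE ignored)."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return MREstimate("wald_ratio", beta, se, _normal_p(beta / se), n_snps=1)


def _ivw_fixed(h: HarmonizedSet) -> tuple[float, float, float]:
    """Closed-form weighted origin regression: (beta, se_fixed, Q)."""
    w = 1.0 / h.se_out**2
    sxx = float(np.sum(w * h.beta_exp**2))
    beta = float(np.sum(w * h.beta_exp * h.beta_out)) / sxx
    se = sxx**-0.5
    ratios, rw = _ratios_and_weights(h)
    q = float(np.sum(rw * (ratios - beta) ** 2))
    return beta, se, q


def ivw(h: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model="auto"`` mirrors the conventional analysis rule: test
    heterogeneity with Cochran's Q and use the multiplicative random-effects
    SE when its p-value is below 0.05, the fixed-effects SE otherwise.  The
    branch taken, Q, its df and p are recorded in ``extra``.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown IVW model '{model}'")
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("ivw requires at least 2 instruments")
    beta, se_fixed, q = _ivw_fixed(h)
    df = h.n_snps - 1
    q_pval = max(float(stats.chi2.sf(q, df)), _TINY_P)
    overdispersion = math.sqrt(max(q / df, 1.0))

    if model == "auto":
        chosen = "random" if q_pval < 0.05 else "fixed"
    else:
        chosen = model
    se = se_fixed * overdispersion if chosen == "random" else se_fixed
    est = MREstimate(
        f"ivw_{'fe' if chosen == 'fixed' else 're'}",
        beta,
        se,
        _normal_p(beta / se),
        n_snps=h.n_snps,
        extra={
            "model_requested": model,
            "model_used": chosen,
            "Q": q,
            "Q_df": df,
            "Q_pval": q_pval,
        },
    )
    return est


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of outcome on exposure effects with
    an intercept, after orienting every SNP so beta_exp >= 0.

    The slope is the pleiotropy-adjusted causal estimate; the intercept (in
    ``extra``: ``egger_intercept``, ``intercept_se``, ``intercept_pval``)
    estimates the average directional pleiotropic effect.  SEs use
    multiplicative overdispersion with the scale floored at 1.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("egger requires at least 3 instruments")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = sign * h.beta_exp
    by = sign * h.beta_out
    w = 1.0 / h.se_out**2

    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2)) / (h.n_snps - 2)
    cov = np.linalg.inv(xtwx) * max(sigma2, 1.0)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))

    return MREstimate(
        "egger",
        float(slope),
        float(se_slope),
        _normal_p(slope / se_slope),
        n_snps=h.n_snps,
        extra={
            "egger_intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_pval": _normal_p(intercept / se_int),
            "residual_scale": sigma2,
        },
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Percentile-interpolated weighted median: p_j = (S_j - w_j/2) / sum(w)."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the total weight are
    valid, unlike IVW which requires all of them to be.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError(
            "weighted_median requires at least 3 instruments"
        )
    ratios, weights = _ratios_and_weights(h)
    beta = _weighted_median(ratios, weights)
    boots = _bootstrap_ratio_estimator(h, _weighted_median, n_boot, seed)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        "weighted_median",
        beta,
        se,
        _normal_p(beta / se),
        n_snps=h.n_snps,
        extra={"n_boot": n_boot, "seed": seed},
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Silverman-style default on the MAD scale: 0.9 * s * n^(-1/5) * phi."""
    mad_sd = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    if mad_sd == 0:
        mad_sd = float(np.std(ratios)) or np.finfo(float).eps
    return phi * 0.9 * mad_sd * len(ratios) ** (-0.2)


def _weighted_mode(
    ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 10_000
) -> float:
    """Argmax of the normal-kernel weighted density on a fixed grid."""
    bw = _mode_bandwidth(ratios, phi)
    lo = ratios.min() - 3 * bw
    hi = ratios.max() + 3 * bw
    if lo == hi:
        return float(ratios[0])
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - ratios[None, :]) / bw
    density = np.exp(-0.5 * z**2) @ (weights / weights.sum())
    return float(grid[np.argmax(density)])


def weighted_mode(
    h: HarmonizedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 10_000,
    boot_grid_size: int = 2_000,
) -> MREstimate:
    """Weighted mode of Wald ratios with parametric-bootstrap SE.

    Consistent when the largest cluster of instruments sharing one ratio is
    valid (zero modal pleiotropy).  ``phi`` scales the kernel bandwidth; the
    bootstrap reuses the estimator on a coarser grid for speed.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError(
            "weighted_mode requires at least 3 instruments"
        )
    ratios, weights = _ratios_and_weights(h)
    beta = _weighted_mode(ratios, weights, phi, grid_size)
    boots = _bootstrap_ratio_estimator(
        h, lambda r, w: _weighted_mode(r, w, phi, boot_grid_size), n_boot, seed
    )
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        "weighted_mode",
        beta,
        se,
        _normal_p(beta / se),
        n_snps=h.n_snps,
        extra={"phi": phi, "n_boot": n_boot, "seed": seed},
    )


def _bootstrap_ratio_estimator(h, estimator, n_boot: int, seed: int) -> np.ndarray:
    """Parametric bootstrap: redraw per-SNP effects from their sampling
    normals and re-apply a (ratios, weights) -> float estimator."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, h.n_snps))
    by = rng.normal(h.beta_out, h.se_out, size=(n_boot, h.n_snps))
    bx[bx == 0] = np.finfo(float).eps  # ratios must stay defined
    ratios = by / bx
    weights = bx**2 / h.se_out**2
    return np.array([estimator(ratios[b], weights[b]) for b in range(n_boot)])


def all_estimates(
    h: HarmonizedSet,
    ivw_model: str = "auto",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """The five standard estimates, degrading gracefully for small sets.

    With one instrument only the Wald ratio is returned; with two, IVW as
    well; from three instruments on, all five methods.
    """
    if h.n_snps == 1:
        return [wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0])]
    out = [ivw(h, ivw_model)]
    if h.n_snps >= 3:
        out.append(egger(h))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(weighted_mode(h, phi=phi, n_boot=n_boot, seed=seed))
    return out


def estimates_table(estimates: list[MREstimate]) -> pd.DataFrame:
    """Forest-plot-shaped table: method, n_snps, OR, CI bounds, p."""
    return pd.DataFrame([e.to_dict() for e in estimates])
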
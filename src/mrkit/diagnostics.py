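"""Heterogeneity, pleiotropy and outlier diagnostics.

These tests gate the model choice and flag invalid instruments:

* :func:`cochran_q` — heterogeneity of per-SNP Wald ratios around the IVW
  fixed-effects estimate; chi-square with n-1 df under homogeneity.
* :func:`egger_intercept_test` — directional pleiotropy via the MR-Egger
  intercept.
* :func:`leave_one_out` — influence of each single instrument on the IVW
  estimate.
* :func:`funnel_data` — per-SNP ratio vs precision, for funnel plots.
* :func:`mr_presso` — simulation-based residual-sum-of-squares framework:
  a global pleiotropy test, per-SNP outlier tests (Bonferroni-adjusted),
  and a distortion test comparing raw and outlier-corrected estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators
from .estimators import MREstimate, _ratios_and_weights, _TINY_P
from .exceptions import DegenerateCorrectionError, InsufficientInstrumentsError
from .gwas_io import HarmonizedSet


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return {"Q": self.Q, "df": self.df, "pval": self.pval}


@dataclass
class PleiotropyResult:
    egger_intercept: float
    intercept_se: float
    pval: float

    def to_dict(self) -> dict:
        return {
            "egger_intercept": self.egger_intercept,
            "intercept_se": self.intercept_se,
            "pval": self.pval,
        }


def cochran_q(h: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios with first-order weights.

    Q = sum_j w_j (ratio_j - theta_IVW)^2 with w_j = beta_exp_j^2/se_out_j^2;
    the IVW fixed-effects estimate is the weighted mean of the ratios, so Q=0
    exactly when all ratios agree.
    """
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("cochran_q requires at least 2 SNPs")
    ratios, w = _ratios_and_weights(h)
    theta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = h.n_snps - 1
    return HeterogeneityResult(q, df, max(float(stats.chi2.sf(q, df)), _TINY_P))


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test from the MR-Egger intercept."""
    extra = estimators.egger(h).extra
    return PleiotropyResult(
        extra["egger_intercept"], extra["intercept_se"], extra["intercept_pval"]
    )


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW (heterogeneity-gated) with each instrument excluded in turn.

    Returns n_snps + 1 rows; the last ("<all>") is the full-set estimate.
    A row is flagged when its confidence interval lies entirely on the
    opposite side of zero from the full-set point estimate.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("leave_one_out requires at least 3 SNPs")
    full = estimators.ivw(h, "auto")
    rows = []
    idx = np.arange(h.n_snps)
    for j in range(h.n_snps):
        est = estimators.ivw(h.subset(idx[idx != j]), "auto")
        rows.append((h.variant_ids[j], est))
    rows.append(("<all>", full))

    sign = np.sign(full.beta)
    records = []
    for excluded, est in rows:
        flipped = (sign > 0 and est.ci_high < 0) or (sign < 0 and est.ci_low > 0)
        records.append(
            {
                "excluded": excluded,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "sign_flag": bool(flipped),
            }
        )
    return pd.DataFrame(records)


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios vs precision (1/se of the ratio) for funnel plots.

    The IVW and Egger reference-line parameters are attached in
    ``DataFrame.attrs`` (keys ``ivw_beta``, ``egger_slope``,
    ``egger_intercept``) when enough instruments are available.
    """
    ratios, w = _ratios_and_weights(h)
    table = pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "ratio": ratios,
            "precision": np.sqrt(w),
        }
    )
    if h.n_snps >= 2:
        table.attrs["ivw_beta"] = estimators.ivw(h, "auto").beta
    if h.n_snps >= 3:
        e = estimators.egger(h)
        table.attrs["egger_slope"] = e.beta
        table.attrs["egger_intercept"] = e.extra["egger_intercept"]
    return table


@dataclass
class PressoResult:
    """MR-PRESSO output: global test, outlier tests and distortion test."""

    global_rss: float
    global_pval: float
    outlier_indices: list[int]
    outlier_pvals: pd.DataFrame
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW-FE slopes, vectorized over trailing SNP axis.

    ``bx``/``by`` may be (n,) or (n_sim, n); ``w`` is (n,).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    n_boot_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual sum of squares and outlier test.

    Global test: the observed RSS — each SNP's weighted squared residual
    from the IVW slope fitted without it — is compared against ``n_sim``
    parametric replicates drawn from the no-pleiotropy model.  Outlier test:
    each SNP's observed residual is compared with its own simulated
    distribution; p-values are Bonferroni-adjusted and SNPs below
    ``outlier_alpha`` are flagged.  Distortion test: the raw-vs-corrected
    estimate difference is compared against differences from removing random
    subsets of the same size.

    Empirical p-values use the permutation convention (count+1)/(n_sim+1)
    so they remain within (0, 1].  Simulation order is canonicalized by
    variant_id, making results invariant to input SNP order for one seed.
    """
    if h.n_snps < 4:
        raise InsufficientInstrumentsError("mr_presso requires at least 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")

    canon = np.argsort(np.asarray(h.variant_ids, dtype=object))
    hc = h.subset(canon)
    n = hc.n_snps
    w = 1.0 / hc.se_out**2

    theta_loo = _loo_slopes(hc.beta_exp, hc.beta_out, w)
    obs_resid = w * (hc.beta_out - theta_loo * hc.beta_exp) ** 2
    rss_obs = float(np.sum(obs_resid))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(hc.beta_exp, hc.se_exp, size=(n_sim, n))
    by_sim = rng.normal(theta_loo * hc.beta_exp, hc.se_out, size=(n_sim, n))
    theta_sim = _loo_slopes(bx_sim, by_sim, w)
    sim_resid = w * (by_sim - theta_sim * bx_sim) ** 2
    rss_sim = sim_resid.sum(axis=1)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)

    pvals = (1 + np.sum(sim_resid >= obs_resid, axis=0)) / (n_sim + 1)
    adj = np.minimum(pvals * n, 1.0)
    outlier_canon = np.flatnonzero(adj < outlier_alpha)
    # map back to the caller's SNP order
    outlier_indices = sorted(int(canon[i]) for i in outlier_canon)

    inv = np.argsort(canon, kind="mergesort")  # canonical -> original order
    outlier_table = pd.DataFrame(
        {
            "variant_id": list(h.variant_ids),
            "pval": pvals[inv],
            "pval_bonferroni": adj[inv],
        }
    )

    estimate_raw = estimators.ivw(h, "auto")
    estimate_corrected = None
    distortion_pval = None
    if len(outlier_indices) > 0:
        keep = np.setdiff1d(np.arange(h.n_snps), outlier_indices)
        if keep.size < 2:
            raise DegenerateCorrectionError(
                f"{len(outlier_indices)} of {h.n_snps} instruments flagged; "
                "no corrected estimate possible"
            )
        estimate_corrected = estimators.ivw(h.subset(keep), "auto")
        diff_obs = estimate_raw.beta - estimate_corrected.beta
        k = len(outlier_indices)
        diffs = np.empty(n_boot_distortion)
        for b in range(n_boot_distortion):
            drop = rng.choice(h.n_snps, size=k, replace=False)
            sub = estimators.ivw(
                h.subset(np.setdiff1d(np.arange(h.n_snps), drop)), "auto"
            )
            diffs[b] = estimate_raw.beta - sub.beta
        distortion_pval = (1 + int(np.sum(np.abs(diffs) >= abs(diff_obs)))) / (
            n_boot_distortion + 1
        )

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_indices=list(outlier_indices),
        outlier_pvals=outlier_table,
        distortion_pval=distortion_pval,
        estimate_raw=estimate_raw,
        estimate_corrected=estimate_corrected,
        n_sim=n_sim,
        seed=seed,
    )
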
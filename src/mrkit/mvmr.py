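"""Multivariable MR: direct effects of several exposures on one outcome.

The outcome effects are regressed jointly on the matrix of exposure effects
(weighted by inverse outcome variance, no intercept), so each coefficient is
an exposure's direct effect conditional on the others — the summary-data
analogue of multivariable regression adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas_io, instruments
from .estimators import _TINY_P, _Z95
from .exceptions import CollinearExposuresError, UnderIdentifiedError
from .gwas_io import SummaryStats
from .instruments import InstrumentConfig, LdInfo


@dataclass
class MvmrDataset:
    """Jointly harmonized effects for k exposures and one outcome."""

    variant_ids: list[str]
    beta_exp_matrix: np.ndarray  # n_snps x k
    se_exp_matrix: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_ids: list[str]
    outcome_id: str = ""
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.beta_exp_matrix = np.atleast_2d(np.asarray(self.beta_exp_matrix, float))
        self.se_exp_matrix = np.atleast_2d(np.asarray(self.se_exp_matrix, float))
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        n, k = self.beta_exp_matrix.shape
        if self.se_exp_matrix.shape != (n, k):
            raise ValueError("effect and SE matrices must share a shape")
        if len(self.variant_ids) != n or self.beta_out.size != n:
            raise ValueError("row dimensions disagree")
        if len(self.exposure_ids) != k:
            raise ValueError("one exposure_id per column required")

    @property
    def n_snps(self) -> int:
        return self.beta_exp_matrix.shape[0]

    @property
    def k(self) -> int:
        return self.beta_exp_matrix.shape[1]


@dataclass
class MvmrEstimate:
    """Per-exposure direct effects conditional on the co-exposures."""

    table: pd.DataFrame  # exposure, beta, se, ci_low, ci_high, pval, odds_ratio...
    n_snps: int
    exposure_ids: list[str]

    def summary(self) -> str:
        cols = ["exposure", "n_snps", "odds_ratio", "or_ci_low", "or_ci_high", "pval"]
        body = self.table.assign(n_snps=self.n_snps)[cols]
        return (
            "Multivariable MR (IVW)\n"
            f"Conditioning set: {', '.join(self.exposure_ids)}\n"
            + body.to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )


def assemble_mvmr(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: LdInfo,
    cfg: InstrumentConfig | None = None,
    drop_palindromic: bool = True,
) -> MvmrDataset:
    """Build the joint instrument set for multivariable MR.

    Candidates are the union over exposures of genome-wide-significant
    variants, clumped jointly using each variant's smallest p-value across
    exposures as its index priority.  Retained variants must be present in
    every exposure and the outcome, and all datasets are aligned to the
    first exposure's effect-allele frame.  Every removal is logged.
    """
    cfg = cfg or InstrumentConfig()
    if len(exposures) < 2:
        raise UnderIdentifiedError("multivariable MR needs at least 2 exposures")

    sig_frames = [
        instruments.filter_significance(e, cfg.p_threshold).df for e in exposures
    ]
    union = pd.concat(sig_frames, ignore_index=True)
    if union.empty:
        raise UnderIdentifiedError("no genome-wide-significant candidates")
    # per-variant min p across exposures; first exposure's coordinates kept
    union = (
        union.sort_values(["variant_id", "pval"], kind="mergesort")
        .drop_duplicates("variant_id", keep="first")
        .reset_index(drop=True)
    )
    candidates = SummaryStats(union, trait_id="mvmr_candidates")
    clumped = instruments.clump(candidates, ld, cfg.clump_kb, cfg.clump_r2)

    drop_log: list[tuple[str, str]] = []
    ref = exposures[0]
    ref_idx = ref.df.set_index("variant_id")
    frames = [e.df.set_index("variant_id") for e in exposures]
    out_idx = outcome.df.set_index("variant_id")

    rows = []
    for vid in clumped.df["variant_id"]:
        if any(vid not in f.index for f in frames):
            drop_log.append((vid, "missing_in_exposure"))
            continue
        if vid not in out_idx.index:
            drop_log.append((vid, "missing_in_outcome"))
            continue
        ref_row = ref_idx.loc[vid]
        if gwas_io._is_palindromic(ref_row.effect_allele, ref_row.other_allele) and (
            drop_palindromic
        ):
            drop_log.append((vid, "palindromic"))
            continue
        betas, ses, ok = [], [], True
        for f in frames + [out_idx]:
            row = f.loc[vid]
            status, beta, _ = gwas_io.align_alleles(
                ref_row.effect_allele,
                ref_row.other_allele,
                row.effect_allele,
                row.other_allele,
                row.beta,
                row.eaf,
            )
            if status == "mismatch":
                drop_log.append((vid, "mismatch"))
                ok = False
                break
            betas.append(beta)
            ses.append(row.se)
        if ok:
            rows.append((vid, betas, ses))

    k = len(exposures)
    if len(rows) <= k:
        raise UnderIdentifiedError(
            f"{len(rows)} instruments for {k} exposures after assembly"
        )
    ids = [r[0] for r in rows]
    beta_matrix = np.array([r[1][:k] for r in rows])
    se_matrix = np.array([r[2][:k] for r in rows])
    beta_out = np.array([r[1][k] for r in rows])
    se_out = np.array([r[2][k] for r in rows])
    return MvmrDataset(
        ids,
        beta_matrix,
        se_matrix,
        beta_out,
        se_out,
        exposure_ids=[e.trait_id for e in exposures],
        outcome_id=outcome.trait_id,
        drop_log=drop_log,
    )


def mvmr_ivw(d: MvmrDataset, q_scaling: bool = False) -> MvmrEstimate:
    """Multivariable IVW: weighted least squares of outcome effects on the
    exposure-effect matrix without intercept, weights 1/se_out^2.

    With ``q_scaling`` the covariance is inflated multiplicatively by
    max(RSS/(n-k), 1); the default reports fixed-effects (unscaled) SEs.
    A mean marginal instrument F below 10 for any exposure triggers a
    weak-instrument warning.
    """
    if d.n_snps <= d.k:
        raise UnderIdentifiedError(f"n_snps={d.n_snps} <= k={d.k}")
    x = d.beta_exp_matrix
    w = 1.0 / d.se_out**2
    xtwx = x.T @ (w[:, None] * x)

    svals = np.linalg.svd(xtwx, compute_uv=False)
    if svals.min() <= svals.max() * np.finfo(float).eps * max(xtwx.shape):
        # name columns involved in the null space
        _, _, vt = np.linalg.svd(xtwx)
        bad = np.flatnonzero(np.abs(vt[-1]) > 1e-8)
        raise CollinearExposuresError([d.exposure_ids[i] for i in bad])

    coef = np.linalg.solve(xtwx, x.T @ (w * d.beta_out))
    cov = np.linalg.inv(xtwx)
    if q_scaling:
        resid = d.beta_out - x @ coef
        cov = cov * max(float(np.sum(w * resid**2)) / (d.n_snps - d.k), 1.0)
    se = np.sqrt(np.diag(cov))

    mean_f = np.mean(d.beta_exp_matrix**2 / d.se_exp_matrix**2, axis=0)
    for j, f in enumerate(mean_f):
        if f < 10:
            warnings.warn(
                f"exposure '{d.exposure_ids[j]}' has mean marginal F = {f:.1f} < 10",
                stacklevel=2,
            )

    z = coef / se
    pvals = np.maximum(2 * stats.norm.sf(np.abs(z)), _TINY_P)
    table = pd.DataFrame(
        {
            "exposure": d.exposure_ids,
            "beta": coef,
            "se": se,
            "ci_low": coef - _Z95 * se,
            "ci_high": coef + _Z95 * se,
            "pval": pvals,
            "odds_ratio": np.exp(coef),
            "or_ci_low": np.exp(coef - _Z95 * se),
            "or_ci_high": np.exp(coef + _Z95 * se),
            "mean_f": mean_f,
        }
    )
    return MvmrEstimate(table=table, n_snps=d.n_snps, exposure_ids=list(d.exposure_ids))
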
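"""Two-step MR mediation with delta-method uncertainty and FDR screening.

The exposure -> outcome total effect (TE) is decomposed through a candidate
mediator: step 1 estimates the exposure -> mediator effect (beta1) using the
exposure's instruments, step 2 the mediator -> outcome effect (beta2) using
the mediator's own instruments.  The indirect effect is the product
IE = beta1 * beta2, the direct effect DE = TE - IE, and the mediated
proportion IE/TE.  Standard errors for IE and the proportion use the
first-order (Sobel-type) delta method treating the three estimates as
independent, which holds for non-overlapping two-sample GWAS.

Screening many candidate mediators applies Benjamini-Hochberg FDR control
to the step-1 p-values; step-2 survivors get a full mediation decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators, gwas_io, instruments
from .estimators import MREstimate, _Z95
from .exceptions import MrkitError
from .gwas_io import SummaryStats
from .instruments import InstrumentConfig, LdInfo


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, q_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    returned in the input order.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of a total effect."""

    te: float
    te_se: float
    beta1: float
    beta1_se: float
    beta2: float
    beta2_se: float
    ie: float
    ie_se: float
    ie_ci_low: float
    ie_ci_high: float
    de: float
    proportion: float
    proportion_se: float
    proportion_ci_low: float
    proportion_ci_high: float
    mediator_id: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        return (
            f"Mediation through '{self.mediator_id}':\n"
            f"  TE = {self.te:.4f} (se {self.te_se:.4f})\n"
            f"  beta1 (exposure->mediator) = {self.beta1:.4f} (se {self.beta1_se:.4f})\n"
            f"  beta2 (mediator->outcome)  = {self.beta2:.4f} (se {self.beta2_se:.4f})\n"
            f"  IE = beta1*beta2 = {self.ie:.5f} (se {self.ie_se:.5f}, "
            f"95% CI [{self.ie_ci_low:.5f}, {self.ie_ci_high:.5f}])\n"
            f"  DE = TE - IE = {self.de:.4f}\n"
            f"  mediated proportion = {100 * self.proportion:.2f}% "
            f"(95% CI [{100 * self.proportion_ci_low:.2f}%, "
            f"{100 * self.proportion_ci_high:.2f}%])"
        )


def two_step_mediation(
    te: MREstimate, b1: MREstimate, b2: MREstimate, mediator_id: str = ""
) -> MediationResult:
    """Combine total-effect, step-1 and step-2 estimates.

    IE = b1*b2 with first-order delta-method variance
    b2^2 se1^2 + b1^2 se2^2; the proportion IE/TE uses the ratio delta
    method, all three estimates treated as independent.  When TE = 0 the
    proportion is undefined: IE and DE are still returned, the proportion
    fields are NaN and a warning is raised.
    """
    ie = b1.beta * b2.beta
    ie_se = math.sqrt(b2.beta**2 * b1.se**2 + b1.beta**2 * b2.se**2)
    de = te.beta - ie
    if te.beta == 0:
        warnings.warn("total effect is zero; mediated proportion undefined")
        prop = prop_se = math.nan
    else:
        prop = ie / te.beta
        prop_se = math.sqrt(
            ie_se**2 / te.beta**2 + ie**2 * te.se**2 / te.beta**4
        )
    return MediationResult(
        te=te.beta,
        te_se=te.se,
        beta1=b1.beta,
        beta1_se=b1.se,
        beta2=b2.beta,
        beta2_se=b2.se,
        ie=ie,
        ie_se=ie_se,
        ie_ci_low=ie - _Z95 * ie_se,
        ie_ci_high=ie + _Z95 * ie_se,
        de=de,
        proportion=prop,
        proportion_se=prop_se,
        proportion_ci_low=prop - _Z95 * prop_se,
        proportion_ci_high=prop + _Z95 * prop_se,
        mediator_id=mediator_id,
    )


@dataclass
class ScreenRow:
    """One candidate mediator's trajectory through the two-step screen."""

    mediator_id: str
    status: str  # no_instruments | fail_step1 | fail_step2 | mediator
    step1: MREstimate | None = None
    step1_q: float = math.nan
    step2: MREstimate | None = None
    mediation: MediationResult | None = None


def _mr_estimate(h: gwas_io.HarmonizedSet) -> MREstimate:
    """IVW with the heterogeneity-gated model, Wald ratio for one SNP."""
    if h.n_snps == 1:
        return estimators.wald_ratio(
            h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0]
        )
    return estimators.ivw(h, "auto")


def screen_mediators(
    exposure: SummaryStats,
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    ld: LdInfo,
    cfg: InstrumentConfig | None = None,
    alpha: float = 0.05,
    step2_alpha: float | None = None,
    te: MREstimate | None = None,
    drop_palindromic: bool = True,
) -> list[ScreenRow]:
    """Screen candidate mediators between one exposure and one outcome.

    Step 1 regresses every mediator on the exposure's instruments and keeps
    those with BH q-value < ``alpha``; step 2 regresses the outcome on each
    survivor's own instruments (selected with ``cfg``) and keeps those with
    p < ``step2_alpha`` (defaults to ``alpha``).  Survivors of both steps
    get a full mediation decomposition against the total effect ``te``
    (estimated internally from exposure -> outcome when not supplied).
    Mediators without usable instruments are flagged and skipped, never
    fatal.
    """
    cfg = cfg or InstrumentConfig()
    step2_alpha = alpha if step2_alpha is None else step2_alpha

    exp_inst = instruments.select_instruments(exposure, ld, cfg).data
    if te is None:
        te = _mr_estimate(
            gwas_io.harmonize(exp_inst, outcome, drop_palindromic=drop_palindromic)
        )

    rows: list[ScreenRow] = []
    for med in mediators:
        row = ScreenRow(mediator_id=med.trait_id, status="no_instruments")
        try:
            h1 = gwas_io.harmonize(exp_inst, med, drop_palindromic=drop_palindromic)
            row.step1 = _mr_estimate(h1)
            row.status = "fail_step1"
        except MrkitError:
            pass
        rows.append(row)

    estimable = [r for r in rows if r.step1 is not None]
    if estimable:
        qvals = bh_fdr([r.step1.pval for r in estimable])
        for r, q in zip(estimable, qvals):
            r.step1_q = float(q)

    for row, med in zip(rows, mediators):
        if row.step1 is None or not row.step1_q < alpha:
            continue
        try:
            med_inst = instruments.select_instruments(med, ld, cfg).data
            h2 = gwas_io.harmonize(med_inst, outcome, drop_palindromic=drop_palindromic)
            row.step2 = _mr_estimate(h2)
        except MrkitError:
            row.status = "no_instruments"
            continue
        if row.step2.pval < step2_alpha:
            row.status = "mediator"
            row.mediation = two_step_mediation(
                te, row.step1, row.step2, mediator_id=med.trait_id
            )
        else:
            row.status = "fail_step2"
    return rows


def screen_table(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flat table of the screen, mirroring the usual reporting columns."""
    records = []
    for r in rows:
        rec = {"mediator_id": r.mediator_id, "status": r.status, "step1_q": r.step1_q}
        if r.step1 is not None:
            rec.update(
                step1_or=r.step1.odds_ratio,
                step1_ci_low=r.step1.or_ci_low,
                step1_ci_high=r.step1.or_ci_high,
                step1_pval=r.step1.pval,
            )
        if r.step2 is not None:
            rec.update(
                step2_or=r.step2.odds_ratio,
                step2_ci_low=r.step2.or_ci_low,
                step2_ci_high=r.step2.or_ci_high,
                step2_pval=r.step2.pval,
            )
        if r.mediation is not None:
            rec.update(
                ie=r.mediation.ie,
                de=r.mediation.de,
                proportion=r.mediation.proportion,
                proportion_ci_low=r.mediation.proportion_ci_low,
                proportion_ci_high=r.mediation.proportion_ci_high,
            )
        records.append(rec)
    return pd.DataFrame(records)
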
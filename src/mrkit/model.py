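"""Model/Results facades over the estimator and diagnostic functions.

:class:`MRModel` is built from harmonized exposure/outcome effects (or
directly from two :class:`~mrkit.gwas_io.SummaryStats` via
:meth:`MRModel.from_summary_stats`, which runs instrument selection and
harmonization); ``fit()`` returns a single :class:`~mrkit.estimators.MREstimate`
and ``fit_all()`` an :class:`MRResults` bundling the five standard
estimators with the heterogeneity and pleiotropy diagnostics and a
``summary()`` table.  :class:`MVMRModel` wraps the multivariable analysis
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import diagnostics, estimators, gwas_io, instruments, mvmr
from .diagnostics import HeterogeneityResult, PleiotropyResult, PressoResult
from .estimators import MREstimate
from .gwas_io import HarmonizedSet, SummaryStats
from .instruments import InstrumentConfig, LdInfo


class MRModel:
    """Two-sample MR of one exposure on one outcome."""

    def __init__(self, data: HarmonizedSet):
        self.data = data
        self.selection = None  # populated by from_summary_stats

    @classmethod
    def from_summary_stats(
        cls,
        exposure: SummaryStats,
        outcome: SummaryStats,
        ld: LdInfo | None = None,
        cfg: InstrumentConfig | None = None,
        drop_palindromic: bool = True,
    ) -> "MRModel":
        """Select instruments from the exposure GWAS and harmonize."""
        ld = ld or LdInfo.make_independent()
        selection = instruments.select_instruments(exposure, ld, cfg)
        h = gwas_io.harmonize(
            selection.data, outcome, drop_palindromic=drop_palindromic
        )
        model = cls(h)
        model.selection = selection
        return model

    @property
    def n_snps(self) -> int:
        return self.data.n_snps

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        """One estimator: ivw (kw ``model``), egger, weighted_median
        (kw ``n_boot``, ``seed``), weighted_mode (kw ``phi``, ...)."""
        fns = {
            "ivw": estimators.ivw,
            "egger": estimators.egger,
            "weighted_median": estimators.weighted_median,
            "weighted_mode": estimators.weighted_mode,
        }
        if method not in fns:
            raise ValueError(f"unknown method '{method}'")
        return fns[method](self.data, **kwargs)

    def fit_all(
        self,
        ivw_model: str = "auto",
        phi: float = 1.0,
        n_boot: int = 1000,
        seed: int = 0,
        n_sim_presso: int = 1000,
    ) -> "MRResults":
        ests = estimators.all_estimates(
            self.data, ivw_model=ivw_model, phi=phi, n_boot=n_boot, seed=seed
        )
        het = diagnostics.cochran_q(self.data) if self.n_snps >= 2 else None
        pleio = (
            diagnostics.egger_intercept_test(self.data) if self.n_snps >= 3 else None
        )
        loo = diagnostics.leave_one_out(self.data) if self.n_snps >= 3 else None
        presso = (
            diagnostics.mr_presso(self.data, n_sim=n_sim_presso, seed=seed)
            if self.n_snps >= 4
            else None
        )
        return MRResults(
            model=self,
            estimates=ests,
            heterogeneity=het,
            pleiotropy=pleio,
            leave_one_out=loo,
            presso=presso,
            funnel=diagnostics.funnel_data(self.data),
        )


@dataclass
class MRResults:
    """Fitted estimates plus diagnostics for one exposure/outcome pair."""

    model: MRModel
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    pleiotropy: PleiotropyResult | None
    leave_one_out: pd.DataFrame | None
    presso: PressoResult | None
    funnel: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.pleiotropy is not None and self.pleiotropy.pval < 0.05:
            self.flags.append("egger_intercept_p<0.05")
        if self.presso is not None and self.presso.global_pval < 0.05:
            self.flags.append("presso_global_p<0.05")
        if self.presso is not None and self.presso.outlier_indices:
            self.flags.append(f"presso_outliers={len(self.presso.outlier_indices)}")

    @property
    def primary(self) -> MREstimate:
        """The IVW estimate with the heterogeneity-gated model choice."""
        return self.estimates[0]

    def estimates_frame(self) -> pd.DataFrame:
        return estimators.estimates_table(self.estimates)

    def summary(self) -> str:
        h = self.model.data
        lines = [
            f"Two-sample MR: {h.exposure_id or 'exposure'} -> "
            f"{h.outcome_id or 'outcome'} ({h.n_snps} instruments)",
            self.estimates_frame()
            .loc[:, ["method", "n_snps", "odds_ratio", "or_ci_low", "or_ci_high", "pval"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.heterogeneity is not None:
            q = self.heterogeneity
            lines.append(
                f"Cochran's Q = {q.Q:.3f} (df {q.df}, p = {q.pval:.3g})"
            )
        if self.pleiotropy is not None:
            p = self.pleiotropy
            lines.append(
                f"Egger intercept = {p.egger_intercept:.5f} "
                f"(se {p.intercept_se:.5f}, p = {p.pval:.3g})"
            )
        if self.presso is not None:
            lines.append(
                f"MR-PRESSO global p = {self.presso.global_pval:.3g}, "
                f"{len(self.presso.outlier_indices)} outlier(s)"
            )
        if self.flags:
            lines.append("Flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class MVMRModel:
    """Multivariable MR of several exposures on one outcome."""

    def __init__(self, dataset: mvmr.MvmrDataset):
        self.dataset = dataset

    @classmethod
    def from_summary_stats(
        cls,
        exposures: list[SummaryStats],
        outcome: SummaryStats,
        ld: LdInfo | None = None,
        cfg: InstrumentConfig | None = None,
    ) -> "MVMRModel":
        ld = ld or LdInfo.make_independent()
        return cls(mvmr.assemble_mvmr(exposures, outcome, ld, cfg))

    def fit(self, q_scaling: bool = False) -> mvmr.MvmrEstimate:
        return mvmr.mvmr_ivw(self.dataset, q_scaling=q_scaling)
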
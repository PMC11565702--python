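"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the structure of large-biobank case-control and
biomarker GWAS used in summary-data MR: independent variants with per-allele
instrument effects, sampling noise scaled by allele frequency and study
sample size (se = 1/sqrt(2*maf*(1-maf)*n)), optional horizontal pleiotropy
(balanced, directional, or correlated with instrument strength), planted
gross outliers, and a three-trait mediator chain
(exposure -> mediator -> outcome) with its implied effect decomposition.

Defaults mirror the study conditions this package is exercised under:
sample sizes of 400,000 for the exposure and outcome GWAS (hypothyroidism
n = 405,357; FinnGen osteoporosis n = 399,054) and 115,000 for metabolite
GWAS (the Nightingale circulating-metabolite panel), with half-normal
per-allele instrument effects (sd 0.02) that give selected-instrument
F statistics in the 30-100 range typical of those studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import SummaryStats
from .instruments import LdInfo

_TINY_P = 5e-324

#: non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class PleiotropySpec:
    """Horizontal-pleiotropy regime for the invalid instrument fraction.

    kind:
      * ``none`` — all instruments valid.
      * ``balanced`` — zero-mean normal direct effects (InSIDE holds).
      * ``directional`` — normal direct effects with non-zero mean
        (InSIDE holds; biases IVW, detectable by the Egger intercept).
      * ``correlated`` — direct effects proportional to instrument strength
        plus noise (violates InSIDE).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    strength: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional", "correlated"):
            raise ConfigurationError(f"unknown pleiotropy kind '{self.kind}'")


@dataclass
class MediationChain:
    """True chain parameters: exposure -b1-> mediator -b2-> outcome, plus DE."""

    beta1: float
    beta2: float
    direct_effect: float

    @property
    def indirect_effect(self) -> float:
        return self.beta1 * self.beta2

    @property
    def total_effect(self) -> float:
        return self.direct_effect + self.indirect_effect

    @property
    def proportion(self) -> float:
        return self.indirect_effect / self.total_effect


@dataclass
class LdBlocks:
    """Optional LD structure: consecutive blocks with a common within-block r2."""

    block_size: int = 5
    r2: float = 0.8


@dataclass
class SimulationConfig:
    """Conditions of one synthetic two-sample MR study."""

    seed: int
    n_snps: int = 100
    n_exp: int = 400_000
    n_out: int = 400_000
    n_med: int = 115_000
    theta: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_effect_sd: float = 0.02  # half-normal scale of per-allele effects
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    prop_invalid: float = 0.0
    n_outliers: int = 0
    outlier_magnitude: float = 10.0  # in units of the outcome SE
    mediation_chain: MediationChain | None = None
    n_mediator_snps: int = 50
    ld_blocks: LdBlocks | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not 0 <= self.prop_invalid <= 1:
            raise ConfigurationError("prop_invalid must be in [0,1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.instrument_effect_sd <= 0:
            raise ConfigurationError("instrument_effect_sd must be positive")


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    theta: float
    instrument_ids: list[str]
    gamma: np.ndarray
    pleiotropy_values: np.ndarray
    invalid_indices: list[int]
    outlier_indices: list[int]
    beta1: float | None = None
    beta2: float | None = None
    direct_effect: float | None = None
    indirect_effect: float | None = None
    total_effect: float | None = None
    proportion: float | None = None
    mediator_instrument_ids: list[str] | None = None
    true_mediator_ids: list[str] | None = None
    ld: LdInfo | None = None

    def to_json(self, path=None) -> str:
        payload = {}
        for key, value in dataclasses.asdict(self).items():
            if key == "ld":
                continue
            if isinstance(value, np.ndarray):
                value = value.tolist()
            payload[key] = value
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), _TINY_P)


def _layout(n: int, rng: np.random.Generator, prefix: str, ld_blocks=None):
    """Variant ids, chromosomes, positions and allele pairs.

    Unlinked variants are spaced 20 Mb apart (outside the default 10,000 kb
    clumping window); variants inside an LD block sit 5 kb apart.
    """
    ids = [f"{prefix}{j:06d}" for j in range(n)]
    if ld_blocks is None:
        chrom = [(j % 22) + 1 for j in range(n)]
        pos = [1_000_000 + (j // 22) * 20_000_000 for j in range(n)]
    else:
        size = ld_blocks.block_size
        chrom, pos = [], []
        for j in range(n):
            block, offset = divmod(j, size)
            chrom.append((block % 22) + 1)
            pos.append(1_000_000 + (block // 22) * 20_000_000 + offset * 5_000)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return ids, chrom, pos, ea, oa


def _ld_info(cfg: SimulationConfig, ids: list[str]) -> LdInfo:
    if cfg.ld_blocks is None:
        return LdInfo.make_independent()
    ld = LdInfo()
    size = cfg.ld_blocks.block_size
    for start in range(0, len(ids), size):
        block = ids[start : start + size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.set_r2(block[i], block[j], cfg.ld_blocks.r2)
    return ld


def _draw_pleiotropy(
    cfg: SimulationConfig, gamma: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    n = gamma.size
    alpha = np.zeros(n)
    spec = cfg.pleiotropy
    if spec.kind == "none" or cfg.prop_invalid == 0:
        return alpha, []
    n_invalid = int(round(cfg.prop_invalid * n))
    invalid = rng.choice(n, size=n_invalid, replace=False)
    if spec.kind == "balanced":
        alpha[invalid] = rng.normal(0.0, spec.sd, size=n_invalid)
    elif spec.kind == "directional":
        alpha[invalid] = rng.normal(spec.mean, spec.sd, size=n_invalid)
    elif spec.kind == "correlated":
        alpha[invalid] = spec.strength * gamma[invalid] + rng.normal(
            spec.mean, spec.sd, size=n_invalid
        )
    return alpha, sorted(int(i) for i in invalid)


def _se_from_maf(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _dataset(ids, chrom, pos, ea, oa, eaf, beta, se, n, trait_id) -> SummaryStats:
    return SummaryStats.from_arrays(
        variant_id=ids,
        chromosome=chrom,
        position=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=_wald_p(beta, se),
        n=np.full(len(ids), n, dtype=int),
        trait_id=trait_id,
        sample_size=n,
    )


def simulate_univariable(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SimulationTruth]:
    """One exposure GWAS, one outcome GWAS, and the generating truth.

    Per variant j: maf ~ U(maf_range); true instrument effect
    gamma_j ~ |N(0, instrument_effect_sd^2)|; observed exposure effect
    ~ N(gamma_j, se_exp_j); observed outcome effect
    ~ N(theta*gamma_j + alpha_j, se_out_j) with alpha_j the horizontal
    pleiotropy on the invalid fraction.  Planted outliers add
    ``outlier_magnitude`` outcome SEs to the outcome effect.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    ids, chrom, pos, ea, oa = _layout(n, rng, "rs", cfg.ld_blocks)
    maf = rng.uniform(*cfg.maf_range, size=n)
    gamma = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=n))
    se_exp = _se_from_maf(maf, cfg.n_exp)
    se_out = _se_from_maf(maf, cfg.n_out)

    alpha, invalid = _draw_pleiotropy(cfg, gamma, rng)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.theta * gamma + alpha, se_out)

    outliers: list[int] = []
    if cfg.n_outliers > 0:
        outliers = sorted(
            int(i) for i in rng.choice(n, size=cfg.n_outliers, replace=False)
        )
        beta_out[outliers] += cfg.outlier_magnitude * se_out[outliers]

    exposure = _dataset(
        ids, chrom, pos, ea, oa, maf, beta_exp, se_exp, cfg.n_exp, "sim-exposure"
    )
    outcome = _dataset(
        ids, chrom, pos, ea, oa, maf, beta_out, se_out, cfg.n_out, "sim-outcome"
    )
    truth = SimulationTruth(
        theta=cfg.theta,
        instrument_ids=ids,
        gamma=gamma,
        pleiotropy_values=alpha,
        invalid_indices=invalid,
        outlier_indices=outliers,
        ld=_ld_info(cfg, ids),
    )
    return exposure, outcome, truth


def simulate_mediation_chain(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimulationTruth]:
    """Exposure, mediator and outcome GWAS on a known mediation chain.

    The exposure's instruments drive the mediator with slope beta1 and the
    outcome with slope direct_effect + beta1*beta2 (so the implied total
    effect is DE + IE).  The mediator additionally has its own
    ``n_mediator_snps`` instruments, which drive the outcome with slope
    beta2 — these power the step-2 (mediator -> outcome) MR.
    """
    if cfg.mediation_chain is None:
        raise ConfigurationError("mediation_chain must be set")
    chain = cfg.mediation_chain
    rng = np.random.default_rng(cfg.seed)

    n_e, n_m = cfg.n_snps, cfg.n_mediator_snps
    ids_e, chrom_e, pos_e, ea_e, oa_e = _layout(n_e, rng, "rsE", None)
    ids_m, chrom_m, pos_m, ea_m, oa_m = _layout(n_m, rng, "rsM", None)
    # shift mediator variants away from exposure variants on the genome
    pos_m = [p + 10_000_000 for p in pos_m]

    maf_e = rng.uniform(*cfg.maf_range, size=n_e)
    maf_m = rng.uniform(*cfg.maf_range, size=n_m)
    gamma = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=n_e))
    delta = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=n_m))
    alpha, invalid = _draw_pleiotropy(cfg, gamma, rng)

    ids = ids_e + ids_m
    chrom = chrom_e + chrom_m
    pos = pos_e + pos_m
    ea = ea_e + ea_m
    oa = oa_e + oa_m
    maf = np.concatenate([maf_e, maf_m])
    se_exp = _se_from_maf(maf, cfg.n_exp)
    se_med = _se_from_maf(maf, cfg.n_med)
    se_out = _se_from_maf(maf, cfg.n_out)

    true_exp = np.concatenate([gamma, np.zeros(n_m)])
    true_med = np.concatenate([chain.beta1 * gamma, delta])
    true_out = np.concatenate(
        [chain.total_effect * gamma + alpha, chain.beta2 * delta]
    )

    exposure = _dataset(
        ids, chrom, pos, ea, oa, maf,
        rng.normal(true_exp, se_exp), se_exp, cfg.n_exp, "sim-exposure",
    )
    mediator = _dataset(
        ids, chrom, pos, ea, oa, maf,
        rng.normal(true_med, se_med), se_med, cfg.n_med, "sim-mediator",
    )
    outcome = _dataset(
        ids, chrom, pos, ea, oa, maf,
        rng.normal(true_out, se_out), se_out, cfg.n_out, "sim-outcome",
    )
    truth = SimulationTruth(
        theta=chain.total_effect,
        instrument_ids=ids_e,
        gamma=gamma,
        pleiotropy_values=np.concatenate([alpha, np.zeros(n_m)]),
        invalid_indices=invalid,
        outlier_indices=[],
        beta1=chain.beta1,
        beta2=chain.beta2,
        direct_effect=chain.direct_effect,
        indirect_effect=chain.indirect_effect,
        total_effect=chain.total_effect,
        proportion=chain.proportion,
        mediator_instrument_ids=ids_m,
        ld=LdInfo.make_independent(),
    )
    return exposure, mediator, outcome, truth


def simulate_mvmr(cfg: SimulationConfig, direct_effects):
    """A multivariable MR dataset with known per-exposure direct effects.

    Every instrument affects all ``k = len(direct_effects)`` exposures with
    independent half-normal per-allele effects; the outcome effect is the
    weighted sum of the true exposure effects.  Returns the assembled
    :class:`~mrkit.mvmr.MvmrDataset` plus a truth dict.
    """
    from .mvmr import MvmrDataset

    direct = np.asarray(direct_effects, float)
    k = direct.size
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    ids = [f"rs{j:06d}" for j in range(n)]
    maf = rng.uniform(*cfg.maf_range, size=n)
    gamma = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=(n, k)))
    se_exp = np.tile(_se_from_maf(maf, cfg.n_exp)[:, None], (1, k))
    se_out = _se_from_maf(maf, cfg.n_out)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(gamma @ direct, se_out)
    dataset = MvmrDataset(
        ids,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        exposure_ids=[f"sim-exposure-{j}" for j in range(k)],
        outcome_id="sim-outcome",
    )
    return dataset, {"direct_effects": direct, "gamma": gamma}


def simulate_metabolite_panel(
    cfg: SimulationConfig, n_mediators: int, n_true: int
) -> tuple[SummaryStats, list[SummaryStats], SummaryStats, SimulationTruth]:
    """A mediator panel: ``n_true`` mediators on the causal chain, the rest null.

    Null mediators are unaffected by the exposure and have no effect on the
    outcome, but carry their own valid instruments; this supports FDR
    calibration of the two-step screen.  Returns (exposure, mediators,
    outcome, truth).
    """
    if n_true > n_mediators:
        raise ConfigurationError("n_true cannot exceed n_mediators")
    if n_true > 0 and cfg.mediation_chain is None:
        raise ConfigurationError("mediation_chain required when n_true > 0")
    chain = cfg.mediation_chain or MediationChain(0.0, 0.0, cfg.theta)
    rng = np.random.default_rng(cfg.seed)

    n_e, n_m = cfg.n_snps, cfg.n_mediator_snps
    ids_e, chrom_e, pos_e, ea_e, oa_e = _layout(n_e, rng, "rsE", None)
    maf_e = rng.uniform(*cfg.maf_range, size=n_e)
    gamma = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=n_e))
    se_exp_e = _se_from_maf(maf_e, cfg.n_exp)

    exposure = _dataset(
        ids_e, chrom_e, pos_e, ea_e, oa_e, maf_e,
        rng.normal(gamma, se_exp_e), se_exp_e, cfg.n_exp, "sim-exposure",
    )

    true_ids = [f"sim-med-{i:03d}" for i in range(n_true)]
    mediators: list[SummaryStats] = []
    out_ids, out_chrom, out_pos, out_ea, out_oa = (
        list(ids_e), list(chrom_e), list(pos_e), list(ea_e), list(oa_e),
    )
    out_maf = [maf_e]
    out_true = [chain.total_effect * gamma] if n_true > 0 else [cfg.theta * gamma]

    for i in range(n_mediators):
        on_chain = i < n_true
        b1 = chain.beta1 if on_chain else 0.0
        b2 = chain.beta2 if on_chain else 0.0
        ids_m, chrom_m, pos_m, ea_m, oa_m = _layout(n_m, rng, f"rsM{i:03d}x", None)
        pos_m = [p + 10_000_000 + 40_000 * i for p in pos_m]
        maf_m = rng.uniform(*cfg.maf_range, size=n_m)
        delta = np.abs(rng.normal(0.0, cfg.instrument_effect_sd, size=n_m))

        ids = ids_e + ids_m
        maf = np.concatenate([maf_e, maf_m])
        se_med = _se_from_maf(maf, cfg.n_med)
        true_med = np.concatenate([b1 * gamma, delta])
        mediators.append(
            _dataset(
                ids, chrom_e + chrom_m, pos_e + pos_m, ea_e + ea_m, oa_e + oa_m,
                maf, rng.normal(true_med, se_med), se_med, cfg.n_med,
                f"sim-med-{i:03d}",
            )
        )
        out_ids += ids_m
        out_chrom += chrom_m
        out_pos += pos_m
        out_ea += ea_m
        out_oa += oa_m
        out_maf.append(maf_m)
        out_true.append(b2 * delta)

    maf_all = np.concatenate(out_maf)
    se_out = _se_from_maf(maf_all, cfg.n_out)
    outcome = _dataset(
        out_ids, out_chrom, out_pos, out_ea, out_oa, maf_all,
        rng.normal(np.concatenate(out_true), se_out), se_out, cfg.n_out,
        "sim-outcome",
    )
    truth = SimulationTruth(
        theta=chain.total_effect if n_true > 0 else cfg.theta,
        instrument_ids=ids_e,
        gamma=gamma,
        pleiotropy_values=np.zeros(n_e),
        invalid_indices=[],
        outlier_indices=[],
        beta1=chain.beta1 if n_true > 0 else None,
        beta2=chain.beta2 if n_true > 0 else None,
        direct_effect=chain.direct_effect if n_true > 0 else None,
        indirect_effect=chain.indirect_effect if n_true > 0 else None,
        total_effect=chain.total_effect if n_true > 0 else None,
        proportion=chain.proportion if n_true > 0 else None,
        true_mediator_ids=true_ids,
        ld=LdInfo.make_independent(),
    )
    return exposure, mediators, outcome, truth
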
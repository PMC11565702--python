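"""Instrument selection: significance filtering, LD clumping, F-statistics.

A valid instrument must (1) reach genome-wide significance in the exposure
GWAS, (2) be approximately independent of the other instruments (greedy LD
clumping within a physical window), and (3) be strong enough that weak-
instrument bias is negligible (per-variant F = beta^2/se^2 above a cutoff,
conventionally 10).

LD is an explicit input here — either a pairwise r-squared lookup or a
declared "independent" mode for pre-pruned panels — so that selection is
fully reproducible without a genotype reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, MissingLdError, NoInstrumentsError
from .gwas_io import SummaryStats


@dataclass
class InstrumentConfig:
    """Thresholds of the three instrument-selection filters."""

    p_threshold: float = 5e-8
    clump_kb: int = 10_000
    clump_r2: float = 0.001
    f_min: float = 10.0

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must be in (0,1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in [0,1]")
        if self.clump_kb < 0:
            raise ConfigurationError("clump_kb must be >= 0")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be >= 0")


class LdInfo:
    """Pairwise r-squared lookup, or a declared independent panel.

    In independent mode every pair is treated as unlinked (r2 = 0) and
    clumping removes only exact positional duplicates.
    """

    def __init__(self, pairs: dict | None = None, independent: bool = False):
        self.independent = independent
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set_r2(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ConfigurationError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float | None:
        """Symmetric lookup; None when the pair is unknown."""
        if a == b:
            return 1.0
        if self.independent:
            return 0.0
        return self._r2.get(self._key(a, b))

    @classmethod
    def make_independent(cls) -> "LdInfo":
        return cls(independent=True)

    @classmethod
    def from_pairs(cls, triples) -> "LdInfo":
        """From an iterable of (variant_a, variant_b, r2)."""
        ld = cls()
        for a, b, r2 in triples:
            ld.set_r2(a, b, float(r2))
        return ld

    @classmethod
    def read_tsv(cls, path) -> "LdInfo":
        """3-column TSV: variant_a, variant_b, r2 (header required)."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise ConfigurationError(f"{path}: expected 3 columns (a, b, r2)")
        return cls.from_pairs(df.iloc[:, :3].itertuples(index=False))

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "LdInfo":
        """Square r2 matrix with variant ids as index and columns."""
        if list(matrix.index) != list(matrix.columns):
            raise ConfigurationError("LD matrix index and columns must match")
        ld = cls()
        ids = list(matrix.index)
        values = matrix.to_numpy(float)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                ld.set_r2(a, ids[j], values[i, j])
        return ld


def filter_significance(data: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Retain records with pval strictly below the threshold, order kept."""
    keep = data.df["pval"] < p_threshold
    return SummaryStats(
        data.df.loc[keep].copy(),
        trait_id=data.trait_id,
        trait_label=data.trait_label,
        sample_size=data.sample_size,
    )


def compute_f_statistics(data: SummaryStats) -> pd.DataFrame:
    """Per-variant instrument strength F = beta^2 / se^2."""
    beta = data.df["beta"].to_numpy(float)
    se = data.df["se"].to_numpy(float)
    return pd.DataFrame(
        {"variant_id": data.df["variant_id"].to_numpy(), "F": beta**2 / se**2}
    )


def clump(
    data: SummaryStats,
    ld: LdInfo,
    clump_kb: int = 10_000,
    clump_r2: float = 0.001,
    missing_ld: str = "linked",
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken by variant_id) as an index and removes all remaining variants on
    the same chromosome within ``clump_kb`` kilobases whose r2 with the index
    exceeds ``clump_r2``.  An unknown r2 for a same-window pair is treated as
    linked by default (``missing_ld="linked"``) or raises
    (``missing_ld="error"``).  The index variants are returned in selection
    (p-value) order, so the result is independent of input row order.
    """
    if missing_ld not in ("linked", "error"):
        raise ConfigurationError("missing_ld must be 'linked' or 'error'")
    df = data.df
    order = df.sort_values(["pval", "variant_id"], kind="mergesort").index.to_numpy()

    if ld.independent:
        # only exact positional duplicates are removed; vectorized fast path
        ranked = df.loc[order]
        keep = ~ranked.duplicated(subset=["chromosome", "position"], keep="first")
        return SummaryStats(
            ranked.loc[keep].copy(),
            trait_id=data.trait_id,
            trait_label=data.trait_label,
            sample_size=data.sample_size,
        )

    chrom = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy(dtype=float)
    vid = df["variant_id"].to_numpy()

    alive = dict.fromkeys(order.tolist())  # insertion-ordered "set"
    selected: list[int] = []
    window = clump_kb * 1000
    while alive:
        idx = next(iter(alive))
        del alive[idx]
        selected.append(idx)
        to_remove = []
        for j in alive:
            if chrom[j] != chrom[idx]:
                continue
            same_window = (
                np.isfinite(pos[idx])
                and np.isfinite(pos[j])
                and abs(pos[idx] - pos[j]) <= window
            )
            if not same_window:
                continue
            r2 = ld.r2(vid[idx], vid[j])
            if r2 is None:
                if missing_ld == "error":
                    raise MissingLdError(
                        f"r2 unknown for same-window pair ({vid[idx]}, {vid[j]})"
                    )
                r2 = 1.0
            if r2 > clump_r2:
                to_remove.append(j)
        for j in to_remove:
            del alive[j]

    return SummaryStats(
        df.loc[selected].copy(),
        trait_id=data.trait_id,
        trait_label=data.trait_label,
        sample_size=data.sample_size,
    )


@dataclass
class SelectionResult:
    """Selected instruments plus per-stage attrition counts."""

    data: SummaryStats
    stage_counts: dict[str, int] = field(default_factory=dict)
    f_stats: pd.DataFrame | None = None

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "count": list(self.stage_counts.values())}
        )


def select_instruments(
    data: SummaryStats,
    ld: LdInfo,
    cfg: InstrumentConfig | None = None,
) -> SelectionResult:
    """Significance filter -> LD clump -> F filter, with stage counts.

    Raises :class:`NoInstrumentsError` naming the stage that emptied the set.
    """
    cfg = cfg or InstrumentConfig()
    counts = {"input": data.n_records}

    sig = filter_significance(data, cfg.p_threshold)
    counts["significance"] = sig.n_records
    if sig.n_records == 0:
        raise NoInstrumentsError("significance")

    clumped = clump(sig, ld, cfg.clump_kb, cfg.clump_r2)
    counts["clump"] = clumped.n_records
    if clumped.n_records == 0:
        raise NoInstrumentsError("clump")

    f_table = compute_f_statistics(clumped)
    strong = clumped.df.loc[(f_table["F"] > cfg.f_min).to_numpy()].copy()
    counts["f_filter"] = len(strong)
    if strong.empty:
        raise NoInstrumentsError("f_filter")

    selected = SummaryStats(
        strong,
        trait_id=data.trait_id,
        trait_label=data.trait_label,
        sample_size=data.sample_size,
    )
    return SelectionResult(data=selected, stage_counts=counts, f_stats=f_table)
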
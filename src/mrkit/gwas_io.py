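"""Reading, writing and harmonizing GWAS summary statistics.

A GWAS summary-statistics dataset is held as a :class:`SummaryStats`: a
pandas DataFrame in canonical column order plus trait metadata.  Effects
(``beta``) are per-effect-allele estimates on the linear or log-odds scale;
``se`` is their standard error; ``eaf`` the effect-allele frequency.

Harmonization aligns an outcome dataset onto the exposure's effect-allele
frame: swapped alleles flip the outcome beta sign (and complement the
frequency), palindromic variants (A/T or C/G) whose strand cannot be
resolved are removed, and irreconcilable allele pairs are dropped as
mismatches.  Every removal is recorded with its reason.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyDatasetError,
    EmptyOverlapError,
)

logger = logging.getLogger(__name__)

#: Canonical column order of the on-disk TSV format.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Columns that must be present (eaf and n may be absent / missing).
MANDATORY_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G single-base pairs (strand-ambiguous across datasets)."""
    return len(ea) == 1 and len(oa) == 1 and oa == ea.translate(_COMPLEMENT)


@dataclass
class SummaryStats:
    """One GWAS's per-variant association statistics.

    Parameters
    ----------
    df : DataFrame with the canonical columns (variant_id unique).
    trait_id, trait_label : identifiers for the phenotype.
    sample_size : overall GWAS sample size when known (per-variant ``n``
        may differ).
    n_invalid : rows dropped during validation at construction time.
    """

    df: pd.DataFrame
    trait_id: str = ""
    trait_label: str = ""
    sample_size: int | None = None
    n_invalid: int = 0

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"missing canonical columns: {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise ConfigurationError(
                f"duplicate variant_id values: {sorted(set(dups))[:5]} ..."
            )

    @property
    def n_records(self) -> int:
        return len(self.df)

    def subset(self, variant_ids) -> "SummaryStats":
        """Rows for the given ids, original order preserved."""
        keep = self.df["variant_id"].isin(set(variant_ids))
        return SummaryStats(
            self.df.loc[keep].copy(),
            trait_id=self.trait_id,
            trait_label=self.trait_label,
            sample_size=self.sample_size,
        )

    @classmethod
    def from_arrays(
        cls,
        variant_id,
        chromosome,
        position,
        effect_allele,
        other_allele,
        beta,
        se,
        pval,
        eaf=None,
        n=None,
        trait_id: str = "",
        trait_label: str = "",
        sample_size: int | None = None,
    ) -> "SummaryStats":
        m = len(variant_id)
        df = pd.DataFrame(
            {
                "variant_id": variant_id,
                "chromosome": np.asarray(chromosome).astype(str),
                "position": pd.array(position, dtype="Int64"),
                "effect_allele": effect_allele,
                "other_allele": other_allele,
                "eaf": np.full(m, np.nan) if eaf is None else np.asarray(eaf, float),
                "beta": np.asarray(beta, float),
                "se": np.asarray(se, float),
                "pval": np.asarray(pval, float),
                "n": pd.array([None] * m if n is None else n, dtype="Int64"),
            }
        )
        return cls(
            df, trait_id=trait_id, trait_label=trait_label, sample_size=sample_size
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int, dict]:
    """Drop rows violating per-variant invariants; return tally by reason."""
    tally: dict[str, int] = {}
    ok = pd.Series(True, index=df.index)

    def mark(bad: pd.Series, reason: str):
        bad = bad & ok
        if bad.any():
            tally[reason] = int(bad.sum())
            ok[bad] = False

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)
    mark(~ea.str.match(_ALLELE_RE) | ~oa.str.match(_ALLELE_RE), "bad_allele")
    mark(ea == oa, "identical_alleles")
    mark(~np.isfinite(df["beta"]), "bad_beta")
    mark(~(df["se"] > 0), "bad_se")
    mark(~((df["pval"] > 0) & (df["pval"] <= 1)), "bad_pval")
    eaf = df["eaf"]
    mark(eaf.notna() & ~((eaf >= 0) & (eaf <= 1)), "bad_eaf")
    mark(df["position"].notna() & (df["position"] < 0), "bad_position")
    mark(df["variant_id"].duplicated(), "duplicate_variant")
    return df.loc[ok], int((~ok).sum()), tally


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str = "",
    trait_label: str = "",
    sample_size: int | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistics file.

    ``column_map`` maps canonical field names to the file's column names
    (identity for unmapped fields).  The delimiter (tab or comma) is
    auto-detected from the header line.  Rows violating the per-variant
    invariants (se>0, p in (0,1], distinct ACGT alleles, eaf in [0,1]) are
    dropped, counted in ``SummaryStats.n_invalid`` and logged.
    """
    column_map = column_map or {}
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(
        path, sep=sep, na_values=["NA", ""], float_precision="round_trip"
    )

    rename = {}
    for canonical in CANONICAL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"{path}: mandatory column '{canonical}' "
                f"(file column '{src}') not found"
            )
    df = raw.rename(columns=rename)
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    df = df[CANONICAL_COLUMNS]
    df = df.astype(
        {
            "variant_id": str,
            "chromosome": str,
            "effect_allele": str,
            "other_allele": str,
            "eaf": float,
            "beta": float,
            "se": float,
            "pval": float,
        }
    )
    df["position"] = pd.array(df["position"], dtype="Int64")
    df["n"] = pd.array(np.floor(pd.to_numeric(df["n"], errors="coerce")), dtype="Int64")

    df, n_invalid, tally = _validate_rows(df)
    if n_invalid:
        logger.warning("%s: dropped %d invalid rows (%s)", path, n_invalid, tally)
    if df.empty:
        raise EmptyDatasetError(f"{path}: no valid rows after validation")
    return SummaryStats(
        df.reset_index(drop=True),
        trait_id=trait_id,
        trait_label=trait_label,
        sample_size=sample_size,
        n_invalid=n_invalid,
    )


def write_summary_stats(data: SummaryStats, path) -> None:
    """Write the canonical tab-separated format (missing values as ``NA``).

    ``read_summary_stats(write(x))`` reproduces ``x`` field-for-field, and a
    second write of the re-read data is byte-identical.
    """
    try:
        data.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise OSError(f"failed writing summary stats to {path}: {exc}") from exc


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a shared effect-allele frame."""

    variant_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_id: str = ""
    outcome_id: str = ""
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.beta_exp = np.asarray(self.beta_exp, float)
        self.se_exp = np.asarray(self.se_exp, float)
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        lengths = {
            len(self.variant_ids),
            self.beta_exp.size,
            self.se_exp.size,
            self.beta_out.size,
            self.se_out.size,
        }
        if lengths != {len(self.variant_ids)} or len(self.variant_ids) < 1:
            raise ConfigurationError("harmonized vectors must share one length >= 1")
        if (self.se_exp <= 0).any() or (self.se_out <= 0).any():
            raise ConfigurationError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def subset(self, index) -> "HarmonizedSet":
        index = np.asarray(index)
        return HarmonizedSet(
            [self.variant_ids[i] for i in np.atleast_1d(index)],
            self.beta_exp[index],
            self.se_exp[index],
            self.beta_out[index],
            self.se_out[index],
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
        )

    def drop_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.drop_log, columns=["variant_id", "reason"])


def align_alleles(ref_ea, ref_oa, ea, oa, beta, eaf):
    """Align one record onto a reference effect/other allele pair.

    Returns ``(status, beta, eaf)`` with status one of ``"ok"`` (as-is),
    ``"flipped"`` (alleles swapped: beta negated, eaf complemented) or
    ``"mismatch"``.  Strand (complement-base) rescue is deliberately not
    attempted; complement-coded records surface as mismatches.
    """
    if ea == ref_ea and oa == ref_oa:
        return "ok", beta, eaf
    if ea == ref_oa and oa == ref_ea:
        return "flipped", -beta, (np.nan if eaf is None or np.isnan(eaf) else 1 - eaf)
    return "mismatch", beta, eaf


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    drop_palindromic: bool = True,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele frame.

    Variants are matched by ``variant_id``.  Outcome records whose alleles
    are swapped relative to the exposure have their beta negated and eaf
    complemented.  Palindromic variants (A/T, C/G) are dropped when
    ``drop_palindromic`` is set; with the relaxation off they are still
    dropped when either allele frequency is missing or within
    ``palindromic_eaf_window`` of 0.5, and otherwise oriented by frequency
    concordance.  Irreconcilable allele pairs are dropped as ``mismatch``.
    """
    merged = exposure.df.merge(
        outcome.df, on="variant_id", how="inner", suffixes=("_exp", "_out")
    )
    if merged.empty:
        raise EmptyOverlapError(
            f"no shared variants between exposure '{exposure.trait_id}' "
            f"and outcome '{outcome.trait_id}'"
        )

    ea_e = merged["effect_allele_exp"].to_numpy()
    oa_e = merged["other_allele_exp"].to_numpy()
    ea_o = merged["effect_allele_out"].to_numpy()
    oa_o = merged["other_allele_out"].to_numpy()
    eaf_e = merged["eaf_exp"].to_numpy(float)
    eaf_o = merged["eaf_out"].to_numpy(float)
    beta_o = merged["beta_out"].to_numpy(float).copy()

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    palindromic = np.array(
        [_is_palindromic(a, b) for a, b in zip(ea_e, oa_e)], dtype=bool
    )

    mismatch = ~same & ~swapped  # palindromic strand flips read as same/swapped

    if drop_palindromic:
        drop_pal = palindromic & ~mismatch
    else:
        with np.errstate(invalid="ignore"):
            ambiguous = (
                np.isnan(eaf_e)
                | np.isnan(eaf_o)
                | (np.abs(eaf_e - 0.5) <= palindromic_eaf_window)
                | (np.abs(eaf_o - 0.5) <= palindromic_eaf_window)
            )
        drop_pal = palindromic & ambiguous & ~mismatch
        # retained palindromes: orient by frequency concordance
        flip_pal = (
            palindromic
            & ~ambiguous
            & ~mismatch
            & ((eaf_e - 0.5) * (eaf_o - 0.5) < 0)
        )
        beta_o[flip_pal] = -beta_o[flip_pal]

    beta_o[~palindromic & swapped] = -beta_o[~palindromic & swapped]
    keep = ~drop_pal & ~mismatch

    drop_log = [
        (vid, "palindromic")
        for vid in merged.loc[drop_pal, "variant_id"]
    ] + [(vid, "mismatch") for vid in merged.loc[mismatch, "variant_id"]]

    kept_ids = merged.loc[keep, "variant_id"].tolist()
    bexp = merged.loc[keep, "beta_exp"].to_numpy(float)
    sexp = merged.loc[keep, "se_exp"].to_numpy(float)
    bout = beta_o[keep]
    sout = merged.loc[keep, "se_out"].to_numpy(float)

    if not kept_ids:
        raise EmptyOverlapError(
            f"harmonization of '{exposure.trait_id}' vs '{outcome.trait_id}' "
            f"retained no variants ({len(drop_log)} dropped)"
        )
    return HarmonizedSet(
        kept_ids,
        np.array(bexp),
        np.array(sexp),
        np.array(bout),
        np.array(sout),
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        drop_log=drop_log,
    )
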
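"""Exception hierarchy for mrkit."""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """Invalid configuration: missing columns, bad thresholds, unknown specs."""


class EmptyDatasetError(MrkitError):
    """A summary-statistics file yielded zero valid rows."""


class EmptyOverlapError(MrkitError):
    """Exposure and outcome share no variants."""


class NoInstrumentsError(MrkitError):
    """Instrument selection emptied the candidate set.

    ``stage`` names the filter that removed the last variant
    ("significance", "clump" or "f_filter").
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments remain after stage '{stage}'")


class InsufficientInstrumentsError(MrkitError):
    """An estimator was given fewer SNPs than its minimum."""


class DegenerateInstrumentError(MrkitError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class MissingLdError(MrkitError):
    """Pairwise r2 unavailable for a same-window variant pair in strict mode."""


class UnderIdentifiedError(MrkitError):
    """Multivariable MR with n_snps <= number of exposures."""


class CollinearExposuresError(MrkitError):
    """Rank-deficient multivariable design matrix."""

    def __init__(self, columns, message: str | None = None):
        self.columns = list(columns)
        super().__init__(
            message or f"collinear exposure columns: {', '.join(self.columns)}"
        )


class DegenerateCorrectionError(MrkitError):
    """MR-PRESSO flagged (almost) every instrument; no corrected estimate."""
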
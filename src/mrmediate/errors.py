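"""Exception hierarchy for mrmediate."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """A configuration (column map, scenario, plan) is invalid or incomplete."""


class EmptyInputError(MRMediateError):
    """No valid records survived reading/validation."""


class EmptyOverlapError(MRMediateError):
    """Exposure and outcome summary statistics share no variants."""


class LDCoverageError(MRMediateError):
    """The supplied LD matrix does not cover all required variants."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"LD matrix is missing {len(self.missing)} required variant(s): "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


class InsufficientInstrumentsError(MRMediateError):
    """Fewer instruments than the estimator's minimum."""

    def __init__(self, needed, available, context=""):
        self.needed = needed
        self.available = available
        msg = f"need at least {needed} instruments, got {available}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class DegenerateInstrumentError(MRMediateError):
    """All exposure effects are zero (or a single Wald ratio has bx = 0)."""


class CollinearityError(MRMediateError):
    """The exposure-beta matrix is rank deficient."""

    def __init__(self, exposure_ids):
        self.exposure_ids = list(exposure_ids)
        super().__init__(
            "exposure beta matrix is rank deficient; offending exposures: "
            + ", ".join(self.exposure_ids)
        )


class GridCoverageError(MRMediateError):
    """The candidate-effect grid does not span all ratio estimates."""


class UndefinedProportionError(MRMediateError):
    """Total effect too close to zero for a proportion mediated."""
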
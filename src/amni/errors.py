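"""Exception hierarchy for the amni package."""


class AmniError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AmniError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateInputError(AmniError, ValueError):
    """An input is structurally valid but numerically degenerate
    (e.g. a zero-variance ROI time series)."""


class ContractViolationError(AmniError, ValueError):
    """Internal shape/consistency contract between stages was violated."""


class DataError(AmniError, ValueError):
    """A cohort record is unusable (missing modality, missing file, bad label)."""


class FormatError(AmniError, ValueError):
    """A file on disk could not be parsed into the expected structure."""


class ProtocolError(AmniError, ValueError):
    """The evaluation protocol cannot be carried out on the given cohort."""


class DegenerateStatisticError(AmniError, ValueError):
    """A test statistic is undefined for the given data
    (e.g. zero variance of paired differences)."""


class ConfigError(AmniError, ValueError):
    """A run configuration is invalid or inconsistent."""
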
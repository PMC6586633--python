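"""Exception types shared across the package."""


class PrmQuantError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PrmQuantError):
    """Inconsistent inputs: e.g. a panel peptide missing from the simulation truth."""


class UndefinedSimilarityError(PrmQuantError, ValueError):
    """Spectral similarity requested against an all-zero intensity vector."""


class UndefinedRatioError(PrmQuantError, ValueError):
    """Light/heavy ratio requested when every heavy area is zero."""


class InsufficientDataError(PrmQuantError, ValueError):
    """Too few points/levels to fit (e.g. < 3 calibration levels)."""


class SingularFitError(PrmQuantError, ValueError):
    """Degenerate regression input (zero variance in the predictor)."""


class SchemaError(PrmQuantError, ValueError):
    """A delimited input file is missing required columns or has malformed rows."""


class UnsupportedContentError(PrmQuantError, ValueError):
    """A recognized container holds no usable content (e.g. mzML without chromatograms)."""
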
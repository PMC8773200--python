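"""Exception hierarchy.

All package errors derive from :class:`Il10PepError` so callers (and the CLI)
can distinguish user/data problems (:class:`ValidationError`,
:class:`ConfigError`, :class:`ParseError`) from runtime failures.
"""


class Il10PepError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(Il10PepError):
    """Input data violates a documented invariant (bad residue, bad label...)."""


class ParseError(Il10PepError):
    """A file could not be parsed as its declared format."""


class ConfigError(Il10PepError):
    """A configuration object or argument is invalid."""


class DescriptorError(Il10PepError):
    """A descriptor is undefined for the given peptide (e.g. lag >= length)."""


class ResamplingError(Il10PepError):
    """SMOTE preconditions not met (minority class too small)."""


class SelectionError(Il10PepError):
    """Feature selection cannot produce a non-empty subset."""


class MetricError(Il10PepError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class SplitError(Il10PepError):
    """A train/test split cannot satisfy its stratification contract."""


class CrossValidationError(Il10PepError):
    """A cross-validation fold is degenerate (e.g. single-class fold)."""


class ModelError(Il10PepError):
    """A trained model is incompatible with the data it is asked to score."""
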
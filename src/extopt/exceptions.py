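"""Exception hierarchy for extopt.

All package errors derive from :class:`ExtoptError` so callers can catch
one base class; the CLI maps validation errors to exit code 2 and numerical
failures to exit code 3.
"""


class ExtoptError(Exception):
    """Base class for all extopt errors."""


class InvalidDesignError(ExtoptError):
    """Design construction parameters are invalid (e.g. k < 2, no center runs)."""


class ConfigError(ExtoptError):
    """Configuration is incomplete or inconsistent."""


class ModelSpecError(ExtoptError):
    """Model term list is malformed (duplicate terms, bad indices)."""


class SingularFitError(ExtoptError):
    """The model matrix is rank-deficient; message names the collinear columns."""


class AssayError(ExtoptError):
    """Invalid assay reading (e.g. non-positive control absorbance)."""


class CalibrationError(ExtoptError):
    """Degenerate calibration input or zero-slope curve."""


class SchemaError(ExtoptError):
    """A tabular input file violates its schema; message carries coordinates."""


class InputError(ExtoptError, ValueError):
    """A scalar argument is outside its documented domain."""
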
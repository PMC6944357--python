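"""Exception hierarchy shared across the package."""


class RestconnError(Exception):
    """Base class for all package errors."""


class FormatError(RestconnError):
    """A delimited input file violates the expected layout."""


class AtlasLookupError(RestconnError):
    """A network member label does not exist in the atlas."""


class ParameterError(RestconnError):
    """A numeric argument is outside its valid domain."""


class DegenerateInputError(RestconnError):
    """Input data cannot support the requested computation (e.g. a constant
    time series has no defined correlation)."""


class AlignmentError(RestconnError):
    """Two objects that must share a label order do not."""


class UndefinedMetricError(RestconnError):
    """The requested graph metric is undefined on this graph (e.g. the
    characteristic path length of an edgeless graph)."""


class ScopeError(RestconnError):
    """A network scope is too small for the requested analysis."""
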
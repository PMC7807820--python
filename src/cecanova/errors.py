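"""Exception hierarchy shared across the package."""


class CecanovaError(Exception):
    """Base class for all package errors."""


class FormatError(CecanovaError):
    """A file does not conform to the expected tabular dialect."""


class ConsistencyError(CecanovaError):
    """Metadata violates a design constraint (e.g. batch/farm mapping)."""


class AlignmentError(CecanovaError):
    """Sample or feature identifiers do not match between two objects."""


class LookupError_(CecanovaError):
    """An identifier referenced by one object is missing from another."""


class EmptyResultError(CecanovaError):
    """A filtering step removed everything."""


class ParameterError(CecanovaError):
    """A parameter lies outside its stated domain."""


class ContrastError(CecanovaError):
    """A requested contrast is not estimable under the observed design."""


class DegenerateFitError(CecanovaError):
    """A model fit has no residual degrees of freedom."""
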
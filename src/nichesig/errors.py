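"""Exception types shared across the pipeline."""


class NicheSigError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NicheSigError, ValueError):
    """An argument or configuration value violates its contract."""


class ParseError(NicheSigError, ValueError):
    """An input file does not conform to its declared format."""


class InsufficientDataError(NicheSigError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateDataError(NicheSigError, ValueError):
    """The data admit no informative answer (e.g. all values identical)."""


class EmptyComparisonError(NicheSigError, ValueError):
    """Two score vectors share no genes, so no comparison is possible."""
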
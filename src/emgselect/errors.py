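"""Exception hierarchy shared across the pipeline stages."""


class EmgSelectError(Exception):
    """Base class for all package errors."""


class ParameterError(EmgSelectError, ValueError):
    """An argument or configuration value violates a precondition."""


class FormatError(EmgSelectError, ValueError):
    """A file on disk does not match the expected delimited-text layout."""


class ShapeError(EmgSelectError, ValueError):
    """Array/matrix dimensions are inconsistent between inputs."""


class DataError(EmgSelectError, ValueError):
    """Input data are structurally valid but unusable (too short, single class, ...)."""
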
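"""Exception hierarchy shared across the package."""


class MultiOptosisError(Exception):
    """Base class for all package-specific errors."""


class VocabularyError(MultiOptosisError, ValueError):
    """A token falls outside a closed vocabulary (RCD form, layer, cell type...)."""


class ValidationError(MultiOptosisError, ValueError):
    """A value violates a structural invariant."""


class AlignmentError(MultiOptosisError, ValueError):
    """Sample identifiers do not line up between two inputs."""


class SizeError(MultiOptosisError, ValueError):
    """Too few samples, events or rows to carry out an operation."""


class ParameterError(MultiOptosisError, ValueError):
    """A numeric parameter is outside its admissible range."""


class IdentifierParseError(MultiOptosisError, ValueError):
    """A signature identifier string does not match the canonical grammar."""


class UnmappedArrayError(MultiOptosisError, KeyError):
    """A 4-letter endpoint array has no code in the loaded mapping table."""


class UnmappedCodeError(MultiOptosisError, KeyError):
    """An integer code has no 4-letter endpoint array in the loaded mapping table."""


class ConfigurationError(MultiOptosisError, ValueError):
    """A generator or pipeline configuration is inconsistent."""


class RankConfigurationError(MultiOptosisError, ValueError):
    """A signature component value is missing from the rank map."""
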
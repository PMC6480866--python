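"""Exception types shared across the pipeline."""


class OitnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OitnetError):
    """A study or run configuration is invalid or incomplete."""


class ConstantVariableError(OitnetError):
    """A relative-scale feature has zero range and cannot be min-max scaled."""


class EmptyIntersectionError(OitnetError):
    """Merging experiments left no shared feature."""


class InsufficientSupportError(OitnetError):
    """A feature has too few distinct values for the requested level count."""


class ImpossibleEvidenceError(OitnetError):
    """The asserted evidence has probability zero under the fitted network."""
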
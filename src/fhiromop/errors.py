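"""Exception hierarchy shared across the package."""


class FhirOmopError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FhirOmopError):
    """Input text is not well-formed FHIR JSON (or lacks resourceType)."""


class UnsupportedResourceError(FhirOmopError):
    """resourceType is syntactically valid but not one of the supported types."""


class ValidityError(FhirOmopError):
    """A resource violates a FHIR-mandatory constraint; names the offending field."""


class TransformError(FhirOmopError):
    """A transformation rule cannot be applied to the given source."""


class AmbiguityError(FhirOmopError):
    """Record linkage is ambiguous (e.g. two systolic rows share an event key)."""


class DanglingReferenceError(FhirOmopError):
    """A foreign key cannot be resolved within the rowset (strict mode)."""


class ConfigError(FhirOmopError):
    """Invalid run configuration."""
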
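"""Exception hierarchy.

All errors raised by the package derive from :class:`BeefCarbonError` so
callers (and the CLI) can distinguish user-input problems from bugs.
"""


class BeefCarbonError(Exception):
    """Base class for all package errors."""


class ValidationError(BeefCarbonError):
    """A record or configuration violates a domain invariant."""


class RegistryError(BeefCarbonError, KeyError):
    """An emission-factor set (or other registered resource) is unknown."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class FactorLookupError(BeefCarbonError, KeyError):
    """A required factor (category, concentrate type, manure system) is missing."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class DomainError(BeefCarbonError, ValueError):
    """An operation received an argument outside its mathematical domain."""


class FootprintUndefinedError(BeefCarbonError):
    """Live-weight gain is non-positive, so a per-LWG footprint is undefined."""


class ApplicabilityError(BeefCarbonError):
    """A mitigation measure does not apply to the farm system at hand."""


class SchemaError(BeefCarbonError):
    """An input file is missing a mandatory column or field."""


class ParseError(BeefCarbonError):
    """An input file holds a value that cannot be coerced to its type."""
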
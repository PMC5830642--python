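"""Exception hierarchy."""

from __future__ import annotations

__all__ = [
    "SymObsError",
    "ModelParseError",
    "ModelSchemaError",
    "UnsupportedModelError",
    "ConfigError",
    "ContractError",
]


class SymObsError(Exception):
    """Base class for all package errors."""


class ModelParseError(SymObsError):
    """An expression or document could not be parsed."""


class ModelSchemaError(SymObsError):
    """A model document violates the schema (duplicates, bad sizes, ...)."""


class UnsupportedModelError(SymObsError):
    """The vector field is not rational in the state variables."""


class ConfigError(SymObsError):
    """A measurement configuration is invalid for the target system."""


class ContractError(SymObsError):
    """An operation was called with inconsistent dimensions or arguments."""
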
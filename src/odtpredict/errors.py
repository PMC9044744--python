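"""Exception hierarchy shared across the package."""


class OdtError(Exception):
    """Base class for all package errors."""


class SchemaError(OdtError):
    """A table is missing a mandatory column or declares an invalid layout."""


class ParseError(OdtError):
    """A cell could not be parsed; message names the offending row/column."""


class ContractError(OdtError, ValueError):
    """A caller violated an operation precondition."""


class DomainError(OdtError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class MergeKeyError(OdtError, KeyError):
    """A join key (API name) is missing or duplicated."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class SelectionError(OdtError):
    """Feature selection produced an unusable result (e.g. empty feature set)."""
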
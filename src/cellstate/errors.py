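"""Exception hierarchy."""


class CellStateError(Exception):
    """Base class for all package errors."""


class ContractError(CellStateError):
    """A caller violated an operation precondition."""


class ParseError(CellStateError):
    """An input file could not be parsed."""


class ConfigError(CellStateError):
    """Invalid model or generator configuration."""
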
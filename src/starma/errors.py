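"""Exception types shared across the package."""


class StarmaError(Exception):
    """Base class for package errors."""


class ConfigurationError(StarmaError, ValueError):
    """A configuration value violates an architectural constraint."""


class ContractError(StarmaError, ValueError):
    """Inputs violate an operation's shape/consistency contract."""


class DegenerateInputError(StarmaError, ValueError):
    """Input too small for the requested operation."""


class InputError(StarmaError, ValueError):
    """Invalid data input (labels out of range, empty matrices, ...)."""
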
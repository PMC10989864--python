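"""Exception hierarchy shared across the package."""


class RbgnnError(Exception):
    """Base class for all package errors."""


class ParseError(RbgnnError):
    """A SMILES string could not be parsed into a molecular graph."""


class ContractError(RbgnnError):
    """An operation was called with arguments violating its contract."""


class TrainingError(RbgnnError):
    """Training failed (degenerate data, numerical divergence)."""


class ConfigError(RbgnnError):
    """A configuration value is invalid or unsatisfiable."""


class FormatError(RbgnnError):
    """An input file does not match the expected schema."""
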
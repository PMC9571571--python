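"""Exception hierarchy shared across the pipeline stages."""


class DrugsieveError(Exception):
    """Base class for all package errors."""


class InputError(DrugsieveError, ValueError):
    """Caller supplied an empty or otherwise invalid input."""


class ContractError(DrugsieveError, ValueError):
    """A value violates an interface contract (e.g. wrong embedding width)."""


class SchemaError(DrugsieveError, ValueError):
    """A serialized corpus file does not match the expected JSON schema."""


class ParseError(DrugsieveError, ValueError):
    """A tabular or JSON input file could not be parsed."""


class ChemParseError(DrugsieveError, ValueError):
    """A SMILES string could not be parsed into a molecule."""


class ServiceError(DrugsieveError, RuntimeError):
    """A remote service (e.g. PubMed) failed; the call may be retried."""


class DivergenceError(DrugsieveError, RuntimeError):
    """Training produced a non-finite loss; carries the offending config."""

    def __init__(self, message: str, config=None):
        super().__init__(message)
        self.config = config
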
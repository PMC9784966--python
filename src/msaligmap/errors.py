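"""Exception hierarchy.

Every error category named in the module contracts gets its own class so the
CLI can map failures to exit codes and messages with mode context.
"""


class MSALigMapError(Exception):
    """Base class for all package errors."""


class ParseError(MSALigMapError):
    """Malformed input text (PDB, DSSP, FASTA, residue lists)."""


class LookupError_(MSALigMapError):
    """A requested chain/record/partner does not exist."""


class EntityTypeError(MSALigMapError):
    """An operation was applied to the wrong kind of chain."""


class ValidationError(MSALigMapError):
    """An identifier or configuration value fails its grammar."""


class AvailabilityError(MSALigMapError):
    """A required file is absent and offline mode forbids fetching."""


class NetworkError(MSALigMapError):
    """A download failed; carries the HTTP status when known."""


class EnvironmentError_(MSALigMapError):
    """A required external executable is missing."""


class ToolError(MSALigMapError):
    """An external tool exited non-zero; carries captured stderr."""


class ContractError(MSALigMapError):
    """An internal precondition was violated by the caller."""


class ConfigurationError(MSALigMapError):
    """A run configuration cannot produce any analysis."""
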
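"""Exception hierarchy shared across the package."""


class LoopcraftError(Exception):
    """Base class for all package errors."""


class FormatError(LoopcraftError):
    """Malformed input file (FASTA, alignment, PDB, plate CSV)."""


class ValidationError(LoopcraftError):
    """A variant or table contradicts its reference (e.g. wrong ref residue)."""


class ResidueLookupError(LoopcraftError, LookupError):
    """A requested residue, chain or alignment row does not exist."""


class DesignError(LoopcraftError):
    """A primer or library design cannot satisfy its constraints."""
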
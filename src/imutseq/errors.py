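"""Exception hierarchy shared across the package."""


class ImutseqError(Exception):
    """Base class for all package errors."""


class FormatError(ImutseqError, ValueError):
    """Malformed input text (TSV, FASTQ, pileup, config)."""


class PoolValidationError(ImutseqError, ValueError):
    """A primer pool or locus violates one of its invariants."""


class PoolConsistencyError(ImutseqError, RuntimeError):
    """Internal inconsistency: two pool primers matched one read prefix."""


class DomainError(ImutseqError, ValueError):
    """An argument is outside the operation's domain."""


class ContractError(ImutseqError, RuntimeError):
    """A user-supplied callable violated its contract (e.g. fitness range)."""
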
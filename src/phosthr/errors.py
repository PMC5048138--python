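"""Exception types shared across the package."""


class PhosthrError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(PhosthrError):
    """A file violates the expected syntax (FASTA, TSV, CSV)."""


class ConsistencyError(PhosthrError):
    """Cross-file contents disagree (e.g. annotation residue vs sequence)."""


class ParameterError(PhosthrError):
    """An argument violates an operation's precondition."""
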
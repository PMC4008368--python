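class TewickError(Exception):
    """Base class for all package errors."""


class InputError(TewickError):
    """A data file is malformed or inconsistent (bad FASTA, bad table, bad sequence)."""


class ConfigError(TewickError):
    """The decision-rules configuration is invalid."""
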
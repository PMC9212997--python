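"""Exception types shared across the package."""


class CodonBiasError(Exception):
    """Base class for all package errors."""


class FastaParseError(CodonBiasError):
    """Structurally malformed FASTA (e.g. sequence data before a header)."""


class HeaderError(CodonBiasError):
    """A FASTA header does not carry the fields the dialect requires."""


class DataError(CodonBiasError):
    """Invalid or inconsistent tabular/membership/config data."""
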
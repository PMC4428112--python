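"""Exception hierarchy shared across the package."""


class DiscrimerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DiscrimerError, ValueError):
    """Invalid parameter combination (bad k, empty target set, unknown label...)."""


class AmbiguousBaseError(DiscrimerError, ValueError):
    """A k-mer contains a base outside {A, C, G, T}.

    Callers scanning a sequence should treat this as "skip the window";
    it is only raised when a single k-mer is encoded directly.
    """


class SequenceFormatError(DiscrimerError, ValueError):
    """Malformed FASTA/FASTQ/k-mer-distribution/targets input.

    The message names the 1-based line number of the offending record.
    """

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class IndexFormatError(DiscrimerError):
    """The file is not an index file, or its format version is unsupported."""


class IndexCorruptedError(DiscrimerError):
    """The index file is recognised but truncated or internally inconsistent."""
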
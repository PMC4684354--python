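"""Exception hierarchy with stable CLI exit codes per error class."""


class RibowaveError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(RibowaveError):
    """Malformed input file (FASTA/TSV/SAM parse or validation failure)."""

    exit_code = 3


class MissingInputError(RibowaveError):
    """A declared input file does not exist."""

    exit_code = 4


class ParameterError(RibowaveError):
    """A parameter outside its documented range."""

    exit_code = 5
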
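"""Exception hierarchy shared across the toolkit."""


class AsprimeError(Exception):
    """Base class for all toolkit errors."""


class FastaParseError(AsprimeError):
    """Malformed FASTA input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AlignmentError(AsprimeError):
    """Species alignment violates an invariant (ragged, unlabeled, too few species)."""


class DesignError(AsprimeError):
    """Primer design cannot satisfy its contract (short flank, no usable site)."""


class LadderError(DesignError):
    """No tail assignment can separate the product-size ladder."""


class SaturationError(AsprimeError):
    """Kimura two-parameter distance undefined: log argument non-positive."""


class PanelSchemaError(AsprimeError):
    """Panel JSON fails schema validation; carries the failing path."""

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")
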
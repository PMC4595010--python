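"""Exception hierarchy for the sharpmir pipeline."""


class SharpmirError(Exception):
    """Base class for all pipeline errors."""


class ParseError(SharpmirError):
    """Malformed FASTA/FASTQ input; carries an approximate line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FixtureError(SharpmirError):
    """Packaged fixture tables are missing, duplicated, or inconsistent."""


class StructureError(SharpmirError):
    """Invalid dot-bracket structure; carries the offending position (1-based)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class StarInferenceError(SharpmirError):
    """The star strand cannot be inferred from the hairpin geometry."""


class ConfigError(SharpmirError):
    """Invalid pipeline configuration."""
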
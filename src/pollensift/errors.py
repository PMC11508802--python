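"""Typed exceptions raised across the pipeline."""


class PollensiftError(Exception):
    """Base class for all pipeline errors."""


class InvalidSequenceError(PollensiftError, ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class EmptyInputError(PollensiftError, ValueError):
    """An operation that requires at least one element received none."""


class TaxonomyLookupError(PollensiftError, KeyError):
    """A sequence id has no taxonomy annotation, or a hit references an
    unknown reference id."""


class HitTableParseError(PollensiftError, ValueError):
    """A tabular hit file is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


class SimulationError(PollensiftError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
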
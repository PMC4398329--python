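"""Exception hierarchy shared across the package."""


class PlastomeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PlastomeError):
    """A file is structurally not in the expected format (e.g. empty FASTA)."""


class SequenceParseError(PlastomeError):
    """A sequence contains characters outside the {A,C,G,T,N,U} alphabet."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class CoordinateError(PlastomeError):
    """A feature coordinate falls outside the sequence."""


class UndefinedValueError(PlastomeError):
    """A statistic is undefined for the given input (empty/all-N sequence)."""


class InvalidStructureError(PlastomeError):
    """A quadripartite partition cannot be formed from the given IR pair."""


class NoAlignmentError(PlastomeError):
    """Transcript/gene pair too divergent or unanchorable."""


class FixtureError(PlastomeError):
    """A packaged data table failed its consistency checks."""


class PlanError(PlastomeError):
    """A synthetic-genome plan is internally inconsistent (collisions etc.)."""


class ConfigError(PlastomeError):
    """Pipeline configuration is missing required inputs."""
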
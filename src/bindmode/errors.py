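"""Exception hierarchy for the bindmode toolkit."""


class BindmodeError(Exception):
    """Base class for all bindmode errors."""


class FormatError(BindmodeError):
    """Unreadable or malformed input file."""


class AnnotationError(BindmodeError):
    """Missing or inconsistent chemical annotation (element, donor H, ring...)."""


class TopologyError(BindmodeError):
    """Topology/trajectory mismatch, e.g. atom-count disagreement."""


class SelectionError(BindmodeError):
    """Empty selection where a non-empty one is required."""


class ParseError(BindmodeError):
    """Selection-expression syntax error; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class GeometryError(BindmodeError):
    """Degenerate geometric input (zero-length arm, singular box, < 3 points)."""


class StatisticsError(BindmodeError):
    """Statistic undefined for the given input (zero frames, single frame...)."""


class AlignmentError(BindmodeError):
    """Frame-aligned traces disagree in length or timestamps."""


class ConfigError(BindmodeError):
    """Invalid configuration value."""
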
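"""Exception hierarchy shared across the package."""


class PdmslabError(Exception):
    """Base class for all package errors."""


class ParameterError(PdmslabError, ValueError):
    """Invalid user-supplied parameter."""


class UnknownKindError(PdmslabError, KeyError):
    """Lookup of a site kind that was never registered."""


class TopologyError(PdmslabError, IndexError):
    """Bonded term references a site that does not exist."""


class SingularityError(PdmslabError):
    """Two interacting sites are (numerically) on top of each other."""


class PackingError(PdmslabError):
    """Random packing could not place the requested molecules."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class IntegrationError(PdmslabError):
    """Non-finite forces or coordinates during time integration."""


class ConstraintError(PdmslabError):
    """SHAKE/RATTLE failed to converge."""


class StabilityError(PdmslabError):
    """Thermostat/barostat divergence (runaway temperature)."""


class AnalysisError(PdmslabError):
    """Trajectory analysis could not be performed on this input."""


class FitError(PdmslabError):
    """Regression window too short or otherwise unusable."""


class ParseError(PdmslabError):
    """Malformed structured-text input file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
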
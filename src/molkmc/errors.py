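"""Exception hierarchy.

All package-specific failures derive from :class:`MolkmcError` so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class MolkmcError(Exception):
    """Base class for all molkmc errors."""


class TopologyParseError(MolkmcError):
    """Malformed topology file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AtomReferenceError(MolkmcError):
    """A term or operation references an atom index that does not exist."""


class UnsupportedElementError(MolkmcError):
    """Element missing from the valence table."""


class RecipeError(MolkmcError):
    """Recipe construction or application failure."""


class ParameterizationError(MolkmcError):
    """A bonded term required by the force field lacks parameters."""


class DivergenceError(MolkmcError):
    """Non-finite force during sampling; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite force at integration step {step}")


class EmptyEnsembleError(MolkmcError):
    """An operation requiring at least one sample received none."""


class ShapeError(MolkmcError):
    """Coordinate frame does not match the topology's atom count."""


class ConfigurationError(MolkmcError):
    """Invalid or inconsistent run configuration."""


class CheckpointError(MolkmcError):
    """Unreadable or corrupt checkpoint file."""


class EmptySelectionError(MolkmcError):
    """No chosen events fall inside the considered label set."""
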
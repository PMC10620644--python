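"""Exception hierarchy shared across the toolkit."""


class OximeScreenError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(OximeScreenError, KeyError):
    """Unknown substituent id or malformed registry."""


class StructureError(OximeScreenError, ValueError):
    """A chemically invalid graft or unparseable structure."""


class SmilesParseError(OximeScreenError, ValueError):
    """Input SMILES could not be parsed."""


class SelectionError(OximeScreenError, LookupError):
    """An atom-selector role matched zero or multiple atoms.

    ``role`` names the offending selector slot.
    """

    def __init__(self, role: str, message: str = ""):
        self.role = role
        super().__init__(message or f"atom selection failed for role {role!r}")


class DegenerateGeometryError(OximeScreenError, ValueError):
    """Coincident points make distance/angle undefined."""


class SchemaError(OximeScreenError, KeyError):
    """A required table column is missing."""


class ReferenceLookupError(OximeScreenError, KeyError):
    """Reference code absent from an energy table."""


class SizeError(OximeScreenError, ValueError):
    """Input too small for the requested operation."""


class NumericError(OximeScreenError, ValueError):
    """Non-finite values where finite ones are required."""


class PropagationError(OximeScreenError, RuntimeError):
    """Trajectory propagation failed; carries the cycle index."""

    def __init__(self, cycle: int, message: str = ""):
        self.cycle = cycle
        super().__init__(message or f"propagation failed in cycle {cycle}")


class DegeneracyError(OximeScreenError, ValueError):
    """No usable connected component in a transition count graph."""


class CalibrationError(OximeScreenError, ValueError):
    """Toy-potential calibration target is infeasible."""


class GenerationError(OximeScreenError, ValueError):
    """Synthetic-fixture constraints are mutually unsatisfiable."""
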
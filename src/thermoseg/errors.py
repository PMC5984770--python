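"""Exception hierarchy for thermoseg."""


class ThermosegError(Exception):
    """Base class for all package errors."""


class PDBParseError(ThermosegError):
    """A PDB record could not be parsed."""


class EmptyStructureError(ThermosegError):
    """A file yielded no standard residues."""


class TrajectoryShapeError(ThermosegError):
    """Models of a multi-model file disagree in atom count, or an atom
    mapping between trajectory and reference failed."""


class ChainLookupError(ThermosegError, KeyError):
    """A requested chain, residue or cluster id does not exist."""


class DegenerateGeometryError(ThermosegError):
    """Too few or rank-deficient points for a rigid superposition."""


class ValidationError(ThermosegError, ValueError):
    """An input violates a documented precondition."""


class InsufficientDataError(ThermosegError):
    """Not enough data for the requested statistic (e.g. < 2 full blocks)."""


class SyntheticSpecError(ValidationError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigurationError(ThermosegError):
    """A pipeline configuration is incomplete or inconsistent."""
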
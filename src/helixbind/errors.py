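"""Exception hierarchy shared across the package."""


class HelixbindError(Exception):
    """Base class for all package errors."""


class StructureParseError(HelixbindError):
    """Malformed structure text (names the offending line when known)."""


class ModelNotFoundError(HelixbindError):
    """Requested model number is absent from the file."""


class SelectionError(HelixbindError):
    """A residue/atom selection could not be resolved; lists absentees."""


class DimensionError(HelixbindError):
    """Coordinate arrays have mismatching or insufficient dimensions."""


class DegenerateGeometryError(HelixbindError):
    """Point sets are rank deficient (collinear/coincident)."""


class RegisterError(HelixbindError):
    """Register offset pushes a mapped position outside a helix."""


class NoFeasibleRegisterError(HelixbindError):
    """Register scan window contains no feasible offset."""


class CollisionError(HelixbindError):
    """Two source positions map to one destination position."""


class PoolError(HelixbindError):
    """Invalid sequence pool (unequal lengths, duplicates, bad boundary)."""


class DataError(HelixbindError):
    """Invalid assay data (non-positive OD, empty controls, ...)."""


class DegenerateControlsError(DataError):
    """Positive and negative control means coincide."""


class AlignmentError(HelixbindError):
    """Time grids of sensograms to be combined do not match."""


class FitError(HelixbindError):
    """Optimization failed to converge; carries diagnostics in args."""


class DegenerateFitError(FitError):
    """Input signal is flat/uninformative; no fit is defined."""


class InsufficientDataError(HelixbindError):
    """Not enough qualifying observations for the requested estimate."""
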
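"""Exception hierarchy for the package."""


class PlaquePropError(Exception):
    """Base class for all package errors."""


class GeometryError(PlaquePropError, ValueError):
    """Invalid geometric input (degenerate contour, bad scale factor...)."""


class InvalidContourError(GeometryError):
    """A contour violates its invariants (too few points, zero area...)."""


class LoftError(GeometryError):
    """Contour stacks cannot be lofted (mismatched point counts)."""


class RecipeError(PlaquePropError, ValueError):
    """A synthetic-data recipe is inconsistent."""


class ProfileError(PlaquePropError, ValueError):
    """A hemodynamic profile is unusable (non-positive radius...)."""


class StatsError(PlaquePropError, ValueError):
    """A statistical operation received invalid input."""


class FormatError(PlaquePropError, ValueError):
    """A file could not be parsed against the documented schema."""


class SimulationError(PlaquePropError, RuntimeError):
    """A simulation could not be completed."""
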
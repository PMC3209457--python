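"""Exception hierarchy for motifdyn.

All domain errors derive from :class:`MotifDynError` so callers can catch
package failures with a single except clause while I/O errors propagate as
the builtin ``OSError`` family.
"""


class MotifDynError(Exception):
    """Base class for all motifdyn domain errors."""


class StructureError(MotifDynError):
    """A structure violates its invariants (empty, unordered, duplicates...)."""


class SelectionError(MotifDynError):
    """A residue selection does not resolve cleanly against a structure."""


class ShapeError(MotifDynError):
    """Coordinate sets have incompatible shapes."""


class DegeneracyError(MotifDynError):
    """Geometry or spectrum is degenerate (collinear points, floppy network)."""


class ConnectivityError(MotifDynError):
    """The elastic-network contact graph is disconnected at the given cutoff."""


class StabilityError(MotifDynError):
    """The Langevin integrator produced a divergent step."""


class GenerationError(MotifDynError):
    """Synthetic-structure generation failed (e.g. rejection sampling stalled)."""
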
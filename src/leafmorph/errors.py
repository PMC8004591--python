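"""Exception hierarchy for leafmorph.

All errors raised by the library derive from :class:`LeafMorphError` so
callers can catch one base class at pipeline boundaries.
"""


class LeafMorphError(Exception):
    """Base class for all leafmorph errors."""


class MeshFormatError(LeafMorphError):
    """A mesh file could not be parsed, or violates basic validity
    (zero faces, out-of-range face index, degenerate face)."""


class TopologyError(LeafMorphError):
    """Mesh connectivity violates an operation's requirements
    (non-manifold edge, disconnected submesh, no boundary)."""


class InputError(LeafMorphError):
    """Invalid numerical input to an operation (empty field, too few
    vertices, non-positive trait, mismatched lengths, zero denominator)."""


class GeometryError(LeafMorphError):
    """A geometric computation has no answer on this input (zero-area
    mesh, empty plane slices, no dominant plane, no plant above buffer)."""


class GenerationError(LeafMorphError):
    """The synthetic scene generator could not satisfy the requested
    placement constraints."""
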
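"""Exception and warning hierarchy shared by all modules."""


class PlateFatigueError(ValueError):
    """Base class for all errors raised by this package."""


class MeshFormatError(PlateFatigueError):
    """Input mesh file is unreadable, empty, or not an STL surface mesh."""


class DegenerateMeshError(PlateFatigueError):
    """Mesh has no triangles or is otherwise unusable."""


class GeometryError(PlateFatigueError):
    """Invalid polyline/polygon geometry (open, self-intersecting, empty)."""


class MaterialError(PlateFatigueError):
    """Missing or inconsistent material data."""


class ChartDomainWarning(UserWarning):
    """A stress-concentration chart query fell outside the encoded grid."""


class SlicingWarning(UserWarning):
    """A cutting plane produced an empty, open, or sliver section."""


class OrientationWarning(UserWarning):
    """Plate orientation was ambiguous (near-isotropic bounding box)."""


class ExtrapolationWarning(UserWarning):
    """An S-N curve was evaluated outside its constructed cycle range."""
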
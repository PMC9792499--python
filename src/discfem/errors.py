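"""Exception hierarchy for discfem."""


class DiscfemError(Exception):
    """Base class for all discfem errors."""


class InvalidDeformationError(DiscfemError):
    """Deformation gradient with non-positive determinant."""


class IncompressibilityError(DiscfemError):
    """Poisson ratio at or beyond the incompressible limit (nu >= 0.5)."""


class MaterialInstabilityError(DiscfemError):
    """Loss of rank-one convexity: non-positive acoustic contraction along a
    probed propagation direction."""

    def __init__(self, message, direction=None):
        super().__init__(message)
        self.direction = direction


class MeshingError(DiscfemError):
    """Mesh generation or mesh file parsing failure."""


class UnsupportedElementError(MeshingError):
    """Mesh file contains element types other than linear tetrahedra."""


class ElementInversionError(DiscfemError):
    """An element reached J <= 0 during assembly or time stepping."""

    def __init__(self, message, element=None, step=None):
        super().__init__(message)
        self.element = element
        self.step = step


class SimulationInstabilityError(DiscfemError):
    """Energy blow-up or NaN detected during explicit integration."""


class QuasiStaticError(DiscfemError):
    """The kinetic/internal energy ratio criterion was not met within the
    allowed number of steps."""


class CalibrationError(DiscfemError):
    """Inverse-FEM setup or optimization failure."""
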
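"""Global physical constants for the blood model.

Blood is treated as an incompressible Newtonian fluid throughout; the
defaults are the standard whole-blood values used in aortic CFD.
"""

from dataclasses import dataclass

#: Pressure conversion, Pa per mmHg.
MMHG_TO_PA: float = 133.322


@dataclass(frozen=True)
class PhysicalConstants:
    """Newtonian blood properties.

    Attributes
    ----------
    mu : float
        Dynamic viscosity, Pa s.
    rho : float
        Density, kg/m^3.
    """

    mu: float = 0.004
    rho: float = 1060.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be strictly positive")


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA
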
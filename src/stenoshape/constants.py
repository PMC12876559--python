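"""Fluid constants, unit conversions, and shared exception types.

All quantities are SI internally (m, s, Pa, kg); pressures cross into mmHg
only through the two converters below, which are the single place the
133.322 Pa/mmHg constant lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Pascals per millimetre of mercury.
PA_PER_MMHG = 133.322

#: Default Reynolds-number sweep used for the reference pressure-drop campaign.
DEFAULT_RE_LIST = (0.1, 1.0, 10.0, 50.0, 100.0, 150.0, 200.0, 250.0,
                   300.0, 350.0, 400.0, 450.0, 500.0)


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / PA_PER_MMHG


class StenoshapeError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(StenoshapeError):
    """A synthetic geometry could not be produced (e.g. non-positive radius)."""


class AlignmentError(StenoshapeError):
    """Mesh alignment failed (e.g. empty inlet ring)."""


class FitError(StenoshapeError):
    """A regression or loss-coefficient fit could not be performed."""


class StateError(StenoshapeError):
    """An operation was called on an object in the wrong state."""


@dataclass(frozen=True)
class FluidConstants:
    """Blood rheology and reference vessel dimensions.

    Parameters
    ----------
    rho : float
        Blood density, kg/m^3.
    mu : float
        Dynamic viscosity, Pa*s.
    a0 : float
        Healthy reference lumen radius, m.
    ls : float
        Nominal stenotic lesion length, m (normalises the viscous loss term).
    lext : float
        Total straight non-stenotic length used for the Poiseuille baseline
        subtraction, m.
    p_aorta : float
        Mean aortic pressure used as the FFR denominator, Pa
        (default: 100 mmHg, the mean of typical systolic and diastolic).
    re_list : tuple of float
        Ordered Reynolds numbers of the reference campaign.
    dx_min : float
        Minimum cell size for the explicit-CFL time-step utility, m.
    u_char : float
        Characteristic velocity for the CFL utility, m/s.
    """

    rho: float = 1060.0
    mu: float = 0.0035
    a0: float = 1.5e-3
    ls: float = 1.0e-2
    lext: float = 4.0e-2
    p_aorta: float = mmhg_to_pa(100.0)
    re_list: tuple[float, ...] = field(default=DEFAULT_RE_LIST)
    dx_min: float = 5.0e-5
    u_char: float = 0.55

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "a0", "ls", "lext", "p_aorta",
                     "dx_min", "u_char"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.a0 < self.lext:
            raise ValueError("a0 must be smaller than lext")
        res = tuple(float(r) for r in self.re_list)
        if len(res) == 0 or any(r <= 0 for r in res):
            raise ValueError("re_list entries must be positive")
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("re_list must be strictly increasing")
        object.__setattr__(self, "re_list", res)
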